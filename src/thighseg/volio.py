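"""Volume containers and I/O.

A study volume is a 3-D scalar grid with isotropic-or-not voxel spacing in
millimetres.  NIfTI (``.nii`` / ``.nii.gz``) is the canonical on-disk form for
both grayscale volumes and integer label maps; spacing round-trips through the
header.  Axis convention throughout the package: ``(x, y, z)`` with ``z`` the
slice (axial) axis, 0-based voxel indices, physical distances in mm obtained
by multiplying index offsets by spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GrayVolume",
    "LabelMap",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "rescale_intensities",
    "crop_slab_and_side",
    "sum_volumes",
    "midline_boxes",
]


def _check_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing!r}")
    return sp  # type: ignore[return-value]


@dataclass
class GrayVolume:
    """A 3-D grayscale volume ``g`` with voxel spacing metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensities.
    spacing : (dx, dy, dz)
        Voxel edge lengths in mm; all strictly positive.
    origin : (ox, oy, oz)
        Physical offset of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def with_data(self, data: np.ndarray) -> "GrayVolume":
        return replace(self, data=np.asarray(data))


@dataclass
class LabelMap:
    """An integer region map ``m`` over the same grid as a paired volume.

    ``label_set`` is the ordered list of admissible label ids; every voxel
    value must be a member.  Names are optional cosmetic metadata.
    """

    labels: np.ndarray
    label_set: tuple[int, ...] = (0, 1)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label map must be 3-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.rint(self.labels).astype(np.int32)
            if not np.allclose(lab, self.labels):
                raise ValueError("label map values must be integers")
            self.labels = lab
        self.label_set = tuple(int(l) for l in self.label_set)
        present = set(np.unique(self.labels).tolist())
        if not present.issubset(self.label_set):
            raise ValueError(
                f"voxel labels {sorted(present - set(self.label_set))} not in label_set"
            )
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def binary(self, label: int = 1) -> np.ndarray:
        return self.labels == label

    def with_labels(self, labels: np.ndarray) -> "LabelMap":
        return replace(self, labels=np.asarray(labels))


def binary_map(mask: np.ndarray, spacing: Sequence[float]) -> LabelMap:
    """Wrap a boolean array as a 0/1 LabelMap."""
    return LabelMap(mask.astype(np.uint8), label_set=(0, 1), spacing=tuple(spacing))


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> GrayVolume:
    """Read a 3-D NIfTI volume; spacing comes from the header zooms."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: header has no usable voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return GrayVolume(np.asarray(data), spacing=tuple(float(z) for z in zooms), origin=origin)


def write_volume(v: GrayVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), _affine(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_labelmap(path: str | Path, label_set: Sequence[int] | None = None) -> LabelMap:
    v = read_volume(path)
    lab = np.rint(v.data).astype(np.int32)
    if label_set is None:
        label_set = tuple(int(l) for l in np.unique(lab))
    return LabelMap(lab, label_set=tuple(label_set), spacing=v.spacing)


def write_labelmap(m: LabelMap, path: str | Path) -> None:
    img = nib.Nifti1Image(m.labels.astype(np.int16), _affine(m.spacing, (0, 0, 0)))
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Preprocessing


def rescale_intensities(v: GrayVolume, levels: int = 256) -> GrayVolume:
    """Affinely map intensities onto integer gray levels ``0 .. levels-1``.

    The volume minimum maps to 0 and the maximum to ``levels - 1``; rounding
    is half-up.  A constant volume maps to all zeros.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    data = np.asarray(v.data, dtype=np.float64)
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        return v.with_data(np.zeros_like(data, dtype=np.int32))
    scaled = (data - lo) * (levels - 1) / (hi - lo)
    # half-up rounding: floor(x + 0.5)
    out = np.floor(scaled + 0.5).astype(np.int32)
    return v.with_data(out)


def crop_slab_and_side(
    v: GrayVolume,
    slice_range: tuple[int, int],
    crop_box: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> GrayVolume:
    """Extract axial slices ``[lo, hi)`` restricted to an in-plane box.

    ``crop_box`` is ``((x0, x1), (y0, y1))`` half-open voxel bounds; ``None``
    keeps the full in-plane extent.  Spacing is preserved; the origin is
    shifted so cropped voxels keep their physical coordinates.
    """
    lo, hi = slice_range
    nx, ny, nz = v.shape
    if not (0 <= lo < hi <= nz):
        raise IndexError(f"slice range {slice_range} invalid for {nz} slices")
    if crop_box is None:
        crop_box = ((0, nx), (0, ny))
    (x0, x1), (y0, y1) = crop_box
    if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny):
        raise IndexError(f"crop box {crop_box} outside in-plane extent {(nx, ny)}")
    dx, dy, dz = v.spacing
    ox, oy, oz = v.origin
    return GrayVolume(
        v.data[x0:x1, y0:y1, lo:hi].copy(),
        spacing=v.spacing,
        origin=(ox + x0 * dx, oy + y0 * dy, oz + lo * dz),
    )


def midline_boxes(v: GrayVolume) -> dict[str, tuple[tuple[int, int], tuple[int, int]]]:
    """Split the in-plane field of view at the x midline into left/right boxes."""
    nx, ny, _ = v.shape
    mid = nx // 2
    return {"left": ((0, mid), (0, ny)), "right": ((mid, nx), (0, ny))}


def sum_volumes(a: GrayVolume, b: GrayVolume) -> GrayVolume:
    """Voxel-wise sum of two volumes on an identical grid (the FS+WS image)."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"spacing mismatch {a.spacing} vs {b.spacing}")
    return a.with_data(np.asarray(a.data, dtype=np.float64) + np.asarray(b.data, dtype=np.float64))
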