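"""Synthetic dual-contrast thigh phantom with known ground truth.

The phantom emulates the concentric tissue layout of a mid-thigh axial slab:
background, a subcutaneous fat (SAT) ring, a muscle annulus crossed by thin
radial intermuscular fat (IMAT) streaks, a cortical bone shell and a bright
marrow core.  Three angular sectors partition the muscle annulus into the
knee-extensor, knee-flexor and medial compartments.  Two contrasts are
rendered: fat-suppressed (FS; muscle bright, fat dark) and water-suppressed
(WS; reversed), with optional additive Gaussian noise.  An *atlas family*
applies independent smooth B-spline warps to the shared topology, standing
in for an inter-subject training set.

Defaults: 96 x 96 x 50 grid at 1.5 mm isotropic voxels — a 50-slice central
slab at the acquisition voxel size, at desk scale in-plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .register import ControlGrid, DeformationField, bspline_expand
from .tissues import TissueMasks
from .volio import GrayVolume, LabelMap, binary_map

__all__ = ["PhantomSpec", "PhantomCase", "make_phantom", "make_atlas_family", "TISSUE_CODES", "GROUP_LABELS"]

# tissue codes in the generating map
TISSUE_CODES = {"background": 0, "sat": 1, "muscle": 2, "imat": 3, "cortical": 4, "marrow": 5}
GROUP_LABELS = {"background": 0, "extensor": 1, "flexor": 2, "medial": 3}

_FS_INTENSITY = {0: 5.0, 1: 60.0, 2: 190.0, 3: 60.0, 4: 20.0, 5: 180.0}
_WS_INTENSITY = {0: 5.0, 1: 190.0, 2: 60.0, 3: 190.0, 4: 20.0, 5: 180.0}


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 96, 50)
    spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
    thigh_radius: float = 60.0  # mm
    sat_thickness: float = 10.0  # mm
    bone_radius: float = 12.0  # mm
    marrow_radius: float = 7.0  # mm
    group_start_deg: float = -30.0  # first sector boundary; sectors are 120 deg
    imat_streaks: int = 6
    imat_width_mm: float = 3.0
    imat_margin_mm: float = 4.5
    jitter_mm: float = 0.0  # atlas boundary perturbation scale
    noise_sigma: float = 0.0  # fraction of the 0-255 dynamic range
    seed: int = 0
    fs_intensity: dict = field(default_factory=lambda: dict(_FS_INTENSITY))
    ws_intensity: dict = field(default_factory=lambda: dict(_WS_INTENSITY))

    def __post_init__(self) -> None:
        if self.bone_radius >= self.thigh_radius - self.sat_thickness:
            raise ValueError("bone must fit inside the muscle annulus")
        if self.marrow_radius >= self.bone_radius:
            raise ValueError("marrow core must fit inside the cortical shell")
        if self.noise_sigma < 0 or self.imat_streaks < 0:
            raise ValueError("noise_sigma and imat_streaks must be non-negative")


@dataclass
class PhantomCase:
    fs: GrayVolume
    ws: GrayVolume
    truth_tissues: TissueMasks
    truth_groups: LabelMap
    tissue_codes: np.ndarray  # generating map, kept for analysis


def _code_slice(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """The 2-D tissue-code template shared by all axial slices."""
    nx, ny, _ = spec.shape
    dx, dy, _ = spec.spacing
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    rx = (X - cx) * dx
    ry = (Y - cy) * dy
    r = np.hypot(rx, ry)

    code = np.zeros((nx, ny), dtype=np.int16)
    code[r <= spec.thigh_radius] = TISSUE_CODES["sat"]
    muscle_outer = spec.thigh_radius - spec.sat_thickness
    code[r <= muscle_outer] = TISSUE_CODES["muscle"]
    code[r <= spec.bone_radius] = TISSUE_CODES["cortical"]
    code[r <= spec.marrow_radius] = TISSUE_CODES["marrow"]

    # thin radial IMAT slabs, kept clear of the bone and the SAT ring so the
    # muscle annulus stays connected and streaks stay interior
    r_lo = spec.bone_radius + spec.imat_margin_mm
    r_hi = muscle_outer - spec.imat_margin_mm
    half_w = spec.imat_width_mm / 2.0
    angles = rng.uniform(0.0, 360.0, size=spec.imat_streaks)
    for ang in angles:
        a = np.radians(ang)
        ux, uy = np.cos(a), np.sin(a)
        along = rx * ux + ry * uy
        across = np.abs(-rx * uy + ry * ux)
        streak = (
            (across <= half_w)
            & (along > 0)
            & (r >= r_lo)
            & (r <= r_hi)
            & (code == TISSUE_CODES["muscle"])
        )
        code[streak] = TISSUE_CODES["imat"]
    return code


def _groups_slice(spec: PhantomSpec) -> np.ndarray:
    nx, ny, _ = spec.shape
    dx, dy, _ = spec.spacing
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    theta = np.degrees(np.arctan2((Y - cy) * dy, (X - cx) * dx))
    sector = np.floor(((theta - spec.group_start_deg) % 360.0) / 120.0).astype(np.int16)
    return sector + 1  # 1, 2, 3


def _render(codes: np.ndarray, groups2d_or_3d, spec: PhantomSpec, rng: np.random.Generator) -> PhantomCase:
    """Intensities + truth from a 3-D tissue-code map and group-sector map."""
    fs_lut = np.array([spec.fs_intensity[c] for c in range(6)])
    ws_lut = np.array([spec.ws_intensity[c] for c in range(6)])
    fs = fs_lut[codes].astype(np.float64)
    ws = ws_lut[codes].astype(np.float64)
    if spec.noise_sigma > 0:
        sig = spec.noise_sigma * 255.0
        fs = np.clip(fs + rng.normal(0.0, sig, size=fs.shape), 0.0, 255.0)
        ws = np.clip(ws + rng.normal(0.0, sig, size=ws.shape), 0.0, 255.0)
    sp = spec.spacing
    groups = np.where(codes == TISSUE_CODES["muscle"], groups2d_or_3d, 0).astype(np.int16)
    truth = TissueMasks(
        thigh=binary_map(codes > 0, sp),
        bone=binary_map((codes == 4) | (codes == 5), sp),
        muscle=binary_map(codes == 2, sp),
        sat=binary_map(codes == 1, sp),
        imat=binary_map(codes == 3, sp),
        bone_found=bool(((codes == 4) | (codes == 5)).any()),
    )
    return PhantomCase(
        fs=GrayVolume(fs, spacing=sp),
        ws=GrayVolume(ws, spacing=sp),
        truth_tissues=truth,
        truth_groups=LabelMap(groups, label_set=(0, 1, 2, 3), spacing=sp),
        tissue_codes=codes,
    )


def make_phantom(spec: PhantomSpec | None = None, with_bone: bool = True) -> PhantomCase:
    """Generate one phantom case; deterministic given ``spec.seed``."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    code2d = _code_slice(spec, rng)
    if not with_bone:
        code2d = code2d.copy()
        code2d[(code2d == 4) | (code2d == 5)] = TISSUE_CODES["muscle"]
    groups2d = _groups_slice(spec)
    nz = spec.shape[2]
    codes = np.repeat(code2d[:, :, None], nz, axis=2)
    groups3d = np.repeat(groups2d[:, :, None], nz, axis=2)
    return _render(codes, groups3d, spec, rng)


def _random_warp(spec: PhantomSpec, rng: np.random.Generator, grid_spacing: int = 16) -> DeformationField:
    grid = ControlGrid(spacing_vox=(grid_spacing,) * 3, shape=spec.shape)
    max_vox = spec.jitter_mm / float(np.mean(spec.spacing))
    grid.displacements[:] = rng.uniform(-max_vox, max_vox, size=grid.displacements.shape)
    return bspline_expand(grid)


def _warp_nn(arr: np.ndarray, fld: DeformationField) -> np.ndarray:
    from scipy import ndimage

    idx = np.indices(arr.shape, dtype=np.float64) + np.moveaxis(fld.disp, -1, 0)
    return ndimage.map_coordinates(arr, idx, order=0, cval=0)


def make_atlas_family(spec: PhantomSpec | None = None, n: int = 6) -> list[PhantomCase]:
    """n phantoms sharing topology, each under an independent smooth warp of
    scale ``jitter_mm``; seeds derive from ``spec.seed``."""
    spec = spec or PhantomSpec()
    if n < 1:
        raise ValueError("need n >= 1 atlas members")
    base_rng = np.random.default_rng(spec.seed)
    code2d = _code_slice(spec, base_rng)
    groups2d = _groups_slice(spec)
    nz = spec.shape[2]
    codes = np.repeat(code2d[:, :, None], nz, axis=2)
    groups3d = np.repeat(groups2d[:, :, None], nz, axis=2)
    children = np.random.SeedSequence(spec.seed).spawn(n)
    out = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        if spec.jitter_mm > 0:
            fld = _random_warp(spec, rng)
            w_codes = _warp_nn(codes, fld)
            w_groups = _warp_nn(groups3d, fld)
        else:
            w_codes, w_groups = codes, groups3d
        out.append(_render(w_codes, w_groups, spec, rng))
    return out
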