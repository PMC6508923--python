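"""Whole-tissue extraction from dual-contrast volumes.

Composes LCDG binarizations of the FS, WS and FS+WS volumes into binary
masks of the whole thigh, bone (cortical + marrow), total muscle, SAT and
IMAT.  The FS+WS sum is bright wherever either contrast is bright, so its
light class is the whole thigh; the FS light class within the thigh is
muscle; the WS light class within the thigh (after bone removal) is fat,
split into SAT/IMAT by the muscle envelope.

Histogram domains: the FS+WS fit uses the full volume (the thigh is not yet
known); the FS and WS fits are restricted to the thigh mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, convex_hull_image

from . import lcdg
from .volio import GrayVolume, LabelMap, binary_map, rescale_intensities, sum_volumes

__all__ = ["TissueMasks", "segment_thigh_and_bone", "segment_muscle", "segment_fat_and_split", "segment_tissues"]

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
MIN_COMPONENT_VOX = 1000


@dataclass
class TissueMasks:
    thigh: LabelMap
    bone: LabelMap
    muscle: LabelMap
    sat: LabelMap
    imat: LabelMap
    bone_found: bool = True
    fat_found: bool = True

    def check_invariants(self) -> None:
        """Disjointness and containment: the four tissues partition (a subset
        of) the thigh."""
        masks = [self.muscle, self.sat, self.imat, self.bone]
        arrays = [m.labels > 0 for m in masks]
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                if np.any(arrays[i] & arrays[j]):
                    raise AssertionError(f"tissue masks {i} and {j} overlap")
        union = arrays[0] | arrays[1] | arrays[2] | arrays[3]
        if np.any(union & ~(self.thigh.labels > 0)):
            raise AssertionError("tissue voxels outside the thigh mask")


def _fill_holes_slicewise(mask: np.ndarray) -> np.ndarray:
    """2-D hole filling per axial slice (handles cavities open along z)."""
    out = np.empty_like(mask)
    for k in range(mask.shape[2]):
        out[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k])
    return out


def _largest_component(mask: np.ndarray, min_size: int) -> np.ndarray:
    lab, n = ndimage.label(mask, structure=STRUCT_26)
    if n == 0:
        raise ValueError("no connected component found")
    sizes = np.bincount(lab.ravel())[1:]
    if sizes.max() < min_size:
        raise ValueError(f"largest component ({sizes.max()} voxels) below minimum {min_size}")
    return lab == (int(np.argmax(sizes)) + 1)


def _light_mask(v: GrayVolume, mask: np.ndarray | None = None, levels: int = 256,
                n_add: int = 4, n_sub: int = 4) -> np.ndarray:
    vq = rescale_intensities(v, levels)
    model = lcdg.fit_volume(vq, mask=mask, levels=levels, n_add=n_add, n_sub=n_sub)
    return lcdg.binarize(vq, model).labels > 0


def segment_thigh_and_bone(
    fs: GrayVolume, ws: GrayVolume, min_size: int = MIN_COMPONENT_VOX
) -> tuple[LabelMap, LabelMap, bool]:
    """Whole-thigh and bone masks from the FS+WS sum.

    thigh: largest connected light component, holes filled slice-wise.
    bone: the dark cavity enclosed inside the thigh (cortical shell) united
    with the bright marrow core it encloses, morphologically closed.
    Returns (thigh, bone, bone_found).
    """
    total = sum_volumes(fs, ws)
    light = _light_mask(total)  # full-volume histogram: thigh unknown yet
    thigh = _fill_holes_slicewise(_largest_component(light, min_size))

    # cortical bone: dark components strictly inside the thigh (not touching
    # its boundary); marrow: the cavity the shell encloses
    dark_inside = thigh & ~light
    # border_value=1: the slab's end slices are not an enclosure boundary
    boundary = thigh & ~ndimage.binary_erosion(thigh, structure=STRUCT_26, border_value=1)
    lab, n = ndimage.label(dark_inside, structure=STRUCT_26)
    bone_found = False
    bone = np.zeros_like(thigh)
    best_size = 0
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() < 100 or np.any(comp & boundary):
            continue
        if comp.sum() > best_size:
            best_size = comp.sum()
            cortical = comp
            bone_found = True
    if bone_found:
        filled = _fill_holes_slicewise(cortical)
        pad = np.pad(filled, 4)  # closing must not erode at the slab ends
        bone = ndimage.binary_closing(pad, structure=ball(3))[4:-4, 4:-4, 4:-4] & thigh
    spacing = fs.spacing
    return binary_map(thigh, spacing), binary_map(bone, spacing), bone_found


def segment_muscle(fs: GrayVolume, thigh: LabelMap, bone: LabelMap | None = None) -> LabelMap:
    """Total muscle: light class of the FS volume within the thigh, bone removed."""
    t = thigh.labels > 0
    light = _light_mask(fs, mask=t)
    muscle = light & t
    if bone is not None:
        muscle &= ~(bone.labels > 0)
    return binary_map(muscle, fs.spacing)


def muscle_envelope(muscle: np.ndarray) -> np.ndarray:
    """Filled convex envelope of the muscle mask, slice-wise — the operative
    fascia proxy separating SAT (outside) from IMAT (inside)."""
    out = np.zeros_like(muscle)
    for k in range(muscle.shape[2]):
        sl = muscle[:, :, k]
        if sl.any():
            # hull of voxel centers: a voxel joins the envelope only if its
            # center is inside, so a digitized disk maps onto itself
            out[:, :, k] = convex_hull_image(sl, offset_coordinates=False)
    return out


def segment_fat_and_split(
    ws: GrayVolume, thigh: LabelMap, muscle: LabelMap, bone: LabelMap | None = None
) -> tuple[LabelMap, LabelMap, bool]:
    """Fat from the WS volume, split into SAT / IMAT by the muscle envelope.

    Returns (sat, imat, fat_found).
    """
    t = thigh.labels > 0
    light = _light_mask(ws, mask=t)
    fat = light & t
    if bone is not None:
        fat &= ~(bone.labels > 0)
    fat &= ~(muscle.labels > 0)
    if not fat.any():
        z = binary_map(fat, ws.spacing)
        return z, z, False
    env = muscle_envelope(muscle.labels > 0)
    imat = fat & env
    sat = fat & ~env
    return binary_map(sat, ws.spacing), binary_map(imat, ws.spacing), True


def segment_tissues(fs: GrayVolume, ws: GrayVolume, min_size: int = MIN_COMPONENT_VOX) -> TissueMasks:
    """Full step-1 pipeline: thigh, bone, muscle, SAT, IMAT."""
    thigh, bone, bone_found = segment_thigh_and_bone(fs, ws, min_size=min_size)
    muscle = segment_muscle(fs, thigh, bone)
    sat, imat, fat_found = segment_fat_and_split(ws, thigh, muscle, bone)
    return TissueMasks(
        thigh=thigh, bone=bone, muscle=muscle, sat=sat, imat=imat,
        bone_found=bone_found, fat_found=fat_found,
    )
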