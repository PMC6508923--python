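"""Joint muscle-group segmentation: shape x spatial x intensity ICM.

The three muscle compartments are segmented by maximizing, voxel by voxel in
raster order, the product of (i) the atlas shape prior, (ii) the Potts
spatial conditional and (iii) the per-group LCDG intensity likelihood —
the factorization P(g, m) = P(g|m) P_sp(m) P_V(m).  Each sweep first
re-estimates the Potts potential from the current map and re-fits each
group's intensity density; sweeps stop when the changed-voxel fraction
drops below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import lcdg
from .mgrf import estimate_potentials
from .shapeprior import ShapePrior, build_prior
from .register import RegistrationConfig
from .tissues import TissueMasks, segment_tissues
from .volio import GrayVolume, LabelMap, rescale_intensities

__all__ = [
    "FusionConfig",
    "SegmentationResult",
    "estimate_class_densities",
    "init_map",
    "icm_refine",
    "segment_groups",
]

LOG_FLOOR = 1e-12


@dataclass
class FusionConfig:
    max_sweeps: int = 20
    tol_frac: float = 1e-4
    levels: int = 256
    n_add: int = 2  # per-group intensity models are near-unimodal
    n_sub: int = 2
    shape_exp: float = 1.0
    spatial_exp: float = 1.0
    intensity_exp: float = 1.0
    refit_models: bool = True  # freeze models when False (diagnostic mode)


@dataclass
class SegmentationResult:
    map: LabelMap
    iterations: int
    energy_trace: list = field(default_factory=list)
    converged: bool = True
    v_eq_trace: list = field(default_factory=list)


def estimate_class_densities(
    fs_levels: np.ndarray,
    labels: np.ndarray,
    label_set: tuple[int, ...],
    levels: int = 256,
    n_add: int = 2,
    n_sub: int = 2,
    fallback: np.ndarray | None = None,
) -> np.ndarray:
    """Per-label conditional gray-level densities P(g|l), shape (L, Q).

    Non-background labels get an LCDG fit restricted to their current
    voxels; background (and any empty or near-degenerate label, which falls
    back to its previous density or uniform) gets a uniform density.
    """
    L = len(label_set)
    out = np.full((L, levels), 1.0 / levels)
    for i, lab in enumerate(label_set):
        if lab == 0:
            continue
        vals = fs_levels[labels == lab]
        if vals.size < 50 or len(np.unique(vals)) < 2:
            if fallback is not None:
                out[i] = fallback[i]
            continue
        counts = np.bincount(vals.astype(np.int64), minlength=levels)
        h = lcdg.Histogram(counts=counts, empirical=counts / counts.sum())
        try:
            model = lcdg.fit_lcdg(h, n_add=n_add, n_sub=n_sub)
            out[i] = model.total_density()
        except ValueError:
            out[i] = h.empirical if fallback is None else fallback[i]
    return out


def _log_terms(prior: ShapePrior, class_dens: np.ndarray, cfg: FusionConfig):
    log_prior = cfg.shape_exp * np.log(np.clip(prior.probs, LOG_FLOOR, None))
    log_int = cfg.intensity_exp * np.log(np.clip(class_dens, LOG_FLOOR, None))
    return np.ascontiguousarray(log_prior), np.ascontiguousarray(log_int)


def init_map(
    prior: ShapePrior,
    class_dens: np.ndarray,
    fs_levels: np.ndarray,
    mask: np.ndarray,
    cfg: FusionConfig | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> LabelMap:
    """Initial region map: per-voxel argmax of shape prior x intensity
    likelihood inside the muscle mask; background elsewhere."""
    cfg = cfg or FusionConfig(levels=class_dens.shape[1])
    log_prior, log_int = _log_terms(prior, class_dens, cfg)
    score = log_prior + np.moveaxis(log_int[:, fs_levels], 0, -1)
    idx = np.argmax(score, axis=-1)
    lut = np.array(prior.label_set, dtype=np.int16)
    out = np.where(np.asarray(mask) > 0, lut[idx], 0).astype(np.int16)
    return LabelMap(out, label_set=prior.label_set, spacing=spacing)


@njit(cache=True)
def _icm_voxel_sweep(lab_idx, mask, log_prior, log_int, gray, v_eq):
    """One raster-order ICM sweep over masked voxels (in place); returns the
    number of changed voxels.  Scores: log prior + log intensity +
    2 * v_eq * (#equal 26-neighbors).  Neighbors outside the domain mask are
    excluded, mirroring the potential estimator's pair counting."""
    nx, ny, nz = lab_idx.shape
    L = log_prior.shape[3]
    changed = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                cur = lab_idx[x, y, z]
                best_l = cur
                best_s = -1e300
                for l in range(L):
                    n_eq = 0
                    for ddx in range(-1, 2):
                        xx = x + ddx
                        if xx < 0 or xx >= nx:
                            continue
                        for ddy in range(-1, 2):
                            yy = y + ddy
                            if yy < 0 or yy >= ny:
                                continue
                            for ddz in range(-1, 2):
                                if ddx == 0 and ddy == 0 and ddz == 0:
                                    continue
                                zz = z + ddz
                                if zz < 0 or zz >= nz:
                                    continue
                                if mask[xx, yy, zz] and lab_idx[xx, yy, zz] == l:
                                    n_eq += 1
                    s = (
                        log_prior[x, y, z, l]
                        + log_int[l, gray[x, y, z]]
                        + 2.0 * v_eq * n_eq
                    )
                    # ascending l with strict '>' keeps the lowest label id on ties
                    if s > best_s:
                        best_s = s
                        best_l = l
                if best_l != cur:
                    lab_idx[x, y, z] = best_l
                    changed += 1
    return changed


def _joint_objective(lab_idx, mask, log_prior, log_int, gray, v_eq):
    """Joint log-score: unary terms over masked voxels + each 26-neighbor
    pair potential counted once (within the mask)."""
    m = mask > 0
    unary = float(
        np.sum(np.take_along_axis(log_prior, lab_idx[..., None], axis=-1)[..., 0][m])
        + np.sum(log_int[lab_idx[m], gray[m]])
    )
    pair = 0.0
    for off in _half_offsets():
        a, b = _pair_slices(off)
        both = m[a] & m[b]
        eq = (lab_idx[a] == lab_idx[b]) & both
        pair += v_eq * (2.0 * int(np.count_nonzero(eq)) - int(np.count_nonzero(both)))
    return unary + pair


def _half_offsets():
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) > (0, 0, 0):
                    offs.append((dx, dy, dz))
    return offs


def _pair_slices(off):
    a, b = [], []
    for d in off:
        if d == 0:
            a.append(slice(None))
            b.append(slice(None))
        else:
            a.append(slice(0, -d))
            b.append(slice(d, None))
    return tuple(a), tuple(b)


def icm_refine(
    init: LabelMap,
    prior: ShapePrior,
    fs: GrayVolume,
    mask: np.ndarray,
    cfg: FusionConfig | None = None,
) -> SegmentationResult:
    """Refine the region map by ICM sweeps with map-adaptive models.

    Per sweep: re-estimate the Potts potential from the current map,
    re-fit per-group LCDG intensity densities, then raster-update every
    masked voxel to its highest-probability label.
    """
    cfg = cfg or FusionConfig()
    label_set = prior.label_set
    lut = np.full(int(max(label_set)) + 1, -1, dtype=np.int16)
    for i, lab in enumerate(label_set):
        lut[lab] = i
    lab_idx = lut[init.labels].astype(np.int16)
    msk = (np.asarray(mask) > 0).astype(np.uint8) > 0
    fs_q = rescale_intensities(fs, cfg.levels)
    gray = np.ascontiguousarray(fs_q.data.astype(np.int64))

    class_dens = estimate_class_densities(
        gray, init.labels, label_set, levels=cfg.levels, n_add=cfg.n_add, n_sub=cfg.n_sub
    )
    log_prior, log_int = _log_terms(prior, class_dens, cfg)
    trace, v_trace = [], []
    n_mask = int(np.count_nonzero(msk))
    converged = False
    sweep = 0
    inv_lut = np.array(label_set, dtype=np.int16)
    for sweep in range(1, cfg.max_sweeps + 1):
        potts = estimate_potentials(inv_lut[lab_idx], mask=msk)
        v_eq = cfg.spatial_exp * potts.v_eq
        if cfg.refit_models and sweep > 1:
            class_dens = estimate_class_densities(
                gray, inv_lut[lab_idx], label_set,
                levels=cfg.levels, n_add=cfg.n_add, n_sub=cfg.n_sub, fallback=class_dens,
            )
            log_prior, log_int = _log_terms(prior, class_dens, cfg)
        changed = _icm_voxel_sweep(lab_idx, msk, log_prior, log_int, gray, v_eq)
        trace.append(_joint_objective(lab_idx, msk, log_prior, log_int, gray, v_eq))
        v_trace.append(potts.v_eq)
        if changed <= cfg.tol_frac * n_mask:
            converged = True
            break
    out = inv_lut[lab_idx]
    out[~msk] = 0
    return SegmentationResult(
        map=LabelMap(out.astype(np.int16), label_set=label_set, spacing=init.spacing),
        iterations=sweep,
        energy_trace=trace,
        converged=converged,
        v_eq_trace=v_trace,
    )


def segment_groups(
    fs: GrayVolume,
    ws: GrayVolume,
    atlases: list[tuple[GrayVolume, LabelMap]],
    cfg: FusionConfig | None = None,
    reg_cfg: RegistrationConfig | None = None,
    tissue_masks: TissueMasks | None = None,
) -> tuple[TissueMasks, SegmentationResult]:
    """End-to-end: tissues -> gate/register -> prior -> init -> ICM.

    ``atlases`` pairs each training FS volume with its 4-label group map.
    """
    if not atlases:
        raise ValueError("segment_groups: atlas set is empty")
    cfg = cfg or FusionConfig()
    if tissue_masks is None:
        tissue_masks = segment_tissues(fs, ws)
    mask = tissue_masks.muscle.labels > 0
    try:
        prior, _ = build_prior(
            fs, atlases, mask=mask, gate_mask=tissue_masks.thigh.labels, reg_cfg=reg_cfg
        )
    except ValueError as err:
        raise ValueError(f"build_prior: {err}") from err
    fs_q = rescale_intensities(fs, cfg.levels)
    gray = fs_q.data.astype(np.int64)
    init_labels = prior.argmax_map(spacing=fs.spacing)
    class_dens = estimate_class_densities(
        gray, init_labels.labels, prior.label_set,
        levels=cfg.levels, n_add=cfg.n_add, n_sub=cfg.n_sub,
    )
    init = init_map(prior, class_dens, gray, mask, cfg, spacing=fs.spacing)
    result = icm_refine(init, prior, fs, mask, cfg)
    return tissue_masks, result


def assign_imat_to_groups(groups: LabelMap, imat: LabelMap) -> LabelMap:
    """Optional post-step: give each IMAT voxel the label of its nearest
    group voxel (for compartment-volume-with-IMAT reporting)."""
    from scipy import ndimage

    lab = groups.labels.copy()
    imat_m = imat.labels > 0
    has_lab = lab > 0
    if not has_lab.any():
        return groups
    idx = ndimage.distance_transform_edt(
        ~has_lab, return_distances=False, return_indices=True
    )
    nearest = lab[tuple(idx)]
    lab[imat_m & ~has_lab] = nearest[imat_m & ~has_lab]
    return LabelMap(lab, label_set=groups.label_set, spacing=groups.spacing)
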