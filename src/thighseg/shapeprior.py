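"""Atlas-based probabilistic shape prior.

Each gated atlas is registered to the target and its 4-label map (background
plus three muscle groups) transported nearest-neighbor; the prior is the
voxel-wise, Laplace-smoothed vote count over warped atlases, restricted to
the target's muscle mask (outside it the background label has probability 1).
The prior of a whole map is the product of its voxel-wise probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .register import RegistrationConfig, atlas_gate, bspline_expand, register, warp_labels
from .volio import GrayVolume, LabelMap, rescale_intensities

__all__ = ["ShapePrior", "build_prior", "prior_from_maps", "prior_log_prob"]

LAPLACE_ALPHA = 0.5


@dataclass
class ShapePrior:
    probs: np.ndarray  # (nx, ny, nz, L)
    label_set: tuple[int, ...]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probs.shape[:3]

    def argmax_map(self, spacing=(1.0, 1.0, 1.0)) -> LabelMap:
        idx = np.argmax(self.probs, axis=-1)
        lut = np.array(self.label_set)
        return LabelMap(lut[idx].astype(np.int16), label_set=self.label_set, spacing=spacing)


def prior_from_maps(
    warped_maps: list[LabelMap],
    label_set: tuple[int, ...],
    mask: np.ndarray | None = None,
    alpha: float = LAPLACE_ALPHA,
) -> ShapePrior:
    """Vote-count prior from already-registered label maps.

    probs[v, l] = (votes_l(v) + alpha) / (n + alpha * L) inside the mask;
    outside it background gets probability 1.
    """
    if not warped_maps:
        raise ValueError("no atlases to vote; lower the gate or add atlases")
    shape = warped_maps[0].shape
    L = len(label_set)
    votes = np.zeros(shape + (L,), dtype=np.float64)
    for m in warped_maps:
        if m.shape != shape:
            raise ValueError("atlas maps on different grids")
        for i, lab in enumerate(label_set):
            votes[..., i] += m.labels == lab
    n = len(warped_maps)
    probs = (votes + alpha) / (n + alpha * L)
    if mask is not None:
        msk = np.asarray(mask) > 0
        bg = int(np.argwhere(np.array(label_set) == 0)[0, 0]) if 0 in label_set else 0
        outside = ~msk
        probs[outside] = 0.0
        probs[(*np.nonzero(outside), bg)] = 1.0
    probs /= probs.sum(axis=-1, keepdims=True)
    return ShapePrior(probs=probs, label_set=tuple(label_set))


def build_prior(
    target: GrayVolume,
    atlases: list[tuple[GrayVolume, LabelMap]],
    mask: np.ndarray | None = None,
    gate_mask: np.ndarray | None = None,
    alpha: float = LAPLACE_ALPHA,
    gate_threshold: float = 0.5,
    reg_cfg: RegistrationConfig | None = None,
) -> tuple[ShapePrior, list[int]]:
    """Gate, register and fuse atlases into a shape prior for the target.

    Correlation gating uses rescaled intensities (within ``gate_mask`` when
    given); selected atlases are registered to the target and their maps
    warped nearest-neighbor before voting.  Returns the prior and the indices
    of the selected atlases.
    """
    tgt_q = rescale_intensities(target).data
    selected: list[int] = []
    warped: list[LabelMap] = []
    label_set: tuple[int, ...] | None = None
    for i, (vol, lmap) in enumerate(atlases):
        cnd_q = rescale_intensities(vol).data
        _, ok = atlas_gate(tgt_q, cnd_q, mask=gate_mask, threshold=gate_threshold)
        if not ok:
            continue
        fld = register(target, vol, reg_cfg)
        warped.append(warp_labels(lmap, fld))
        selected.append(i)
        label_set = lmap.label_set
    if not warped:
        raise ValueError(
            "zero atlases passed the correlation gate; lower the gate or add atlases"
        )
    prior = prior_from_maps(warped, label_set, mask=mask, alpha=alpha)
    return prior, selected


def prior_log_prob(prior: ShapePrior, m: LabelMap) -> float:
    """log P_sp(m) = sum over voxels of log p_sp(m(v)); -inf on a
    zero-probability assignment."""
    if m.shape != prior.shape:
        raise ValueError("map grid does not match prior grid")
    index = {lab: i for i, lab in enumerate(prior.label_set)}
    lut = np.full(int(max(prior.label_set)) + 1, -1, dtype=np.int64)
    for lab, i in index.items():
        lut[lab] = i
    idx = lut[m.labels]
    if (idx < 0).any():
        raise ValueError("map contains labels outside the prior's label set")
    p = np.take_along_axis(prior.probs, idx[..., None], axis=-1)[..., 0]
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(p)))
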