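"""Second-order spatial model: Potts MGRF on the 26-neighborhood.

The pairwise Gibbs potential is bi-valued — ``v_eq`` for equal neighboring
labels, ``v_ne = -v_eq`` otherwise — with the analytic maximum-likelihood
estimate ``v_eq = 2 f_eq - 1`` where ``f_eq`` is the relative frequency of
equal labels over neighboring voxel pairs.  The partition function is never
evaluated: segmentation only needs the voxel-wise conditionals
``p(l | neighbors) ∝ exp(Σ_n V(l, m_n))``, which require local normalization
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volio import LabelMap

__all__ = ["PottsModel", "NEIGHBORHOOD_26", "estimate_potentials", "spatial_probs", "neighbor_equal_counts"]

NEIGHBORHOOD_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

# one offset per unordered pair direction
_HALF_OFFSETS = tuple(o for o in NEIGHBORHOOD_26 if o > (0, 0, 0))


@dataclass(frozen=True)
class PottsModel:
    v_eq: float
    label_set: tuple[int, ...]
    f_eq: float = float("nan")
    neighborhood: tuple = NEIGHBORHOOD_26

    @property
    def v_ne(self) -> float:
        return -self.v_eq


def _labels_and_mask(m: LabelMap | np.ndarray, mask):
    lab = m.labels if isinstance(m, LabelMap) else np.asarray(m)
    if mask is None:
        msk = np.ones(lab.shape, dtype=bool)
    else:
        msk = mask.labels > 0 if isinstance(mask, LabelMap) else np.asarray(mask) > 0
    return lab, msk


def _shift_slices(offset):
    """Paired slices (a, b) so that lab[a] and lab[b] are neighbors at +offset."""
    a, b = [], []
    for d in offset:
        if d == 0:
            a.append(slice(None))
            b.append(slice(None))
        elif d > 0:
            a.append(slice(0, -d))
            b.append(slice(d, None))
        else:
            a.append(slice(-d, None))
            b.append(slice(0, d))
    return tuple(a), tuple(b)


def estimate_potentials(
    m: LabelMap | np.ndarray, mask: LabelMap | np.ndarray | None = None
) -> PottsModel:
    """Analytic ML potential estimate from a region map.

    Counts each unordered 26-neighbor pair once; pairs crossing the grid (or
    domain-mask) boundary are excluded.
    """
    lab, msk = _labels_and_mask(m, mask)
    eq = 0
    total = 0
    for off in _HALF_OFFSETS:
        a, b = _shift_slices(off)
        valid = msk[a] & msk[b]
        total += int(np.count_nonzero(valid))
        eq += int(np.count_nonzero((lab[a] == lab[b]) & valid))
    if total == 0:
        raise ValueError("no valid neighboring voxel pairs in the domain")
    f_eq = eq / total
    label_set = (
        m.label_set if isinstance(m, LabelMap) else tuple(int(l) for l in np.unique(lab))
    )
    return PottsModel(v_eq=2.0 * f_eq - 1.0, label_set=tuple(label_set), f_eq=f_eq)


def neighbor_equal_counts(
    lab: np.ndarray, label_set, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel count of 26-neighbors carrying each label.

    Returns ``(counts, n_neighbors)`` with ``counts`` of shape
    ``lab.shape + (L,)``; neighbors outside the grid (or outside ``mask``)
    are not counted.
    """
    lab = np.asarray(lab)
    L = len(label_set)
    counts = np.zeros(lab.shape + (L,), dtype=np.int16)
    n_nb = np.zeros(lab.shape, dtype=np.int16)
    lut = np.full(int(max(label_set)) + 1, -1, dtype=np.int16)
    for i, l in enumerate(label_set):
        lut[int(l)] = i
    lab_idx = lut[lab]
    valid = np.ones(lab.shape, dtype=bool) if mask is None else np.asarray(mask) > 0
    for off in NEIGHBORHOOD_26:
        a, b = _shift_slices(off)
        v = valid[b]
        n_nb[a] += v
        lb = lab_idx[b]
        for i in range(L):
            counts[(*a, i)] += (lb == i) & v
    return counts, n_nb


def spatial_probs(
    m: LabelMap | np.ndarray,
    model: PottsModel,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Voxel-wise conditional label probabilities under the Potts model.

    ``p(l) ∝ exp(v_eq * n_eq(l) + v_ne * (n_nb - n_eq(l)))``, normalized over
    the label set at each voxel.  Shape: ``m.shape + (L,)``.
    """
    lab = m.labels if isinstance(m, LabelMap) else np.asarray(m)
    counts, n_nb = neighbor_equal_counts(lab, model.label_set, mask=mask)
    # energy(l) = v_eq*n_eq - v_eq*(n_nb - n_eq) = 2 v_eq n_eq - v_eq n_nb;
    # the second term is label-independent and cancels in normalization.
    energy = 2.0 * model.v_eq * counts.astype(np.float64)
    energy -= energy.max(axis=-1, keepdims=True)
    p = np.exp(energy)
    return p / p.sum(axis=-1, keepdims=True)
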