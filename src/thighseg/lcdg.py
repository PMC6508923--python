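"""Linear Combination of Discrete Gaussians (LCDG) gray-level modeling.

The empirical gray-level distribution of a (masked) volume over ``Q`` levels
is approximated by a *signed* mixture: two dominant discrete Gaussians (one
per tissue class, dark and light) plus small additive and subtractive
"deviation" components that absorb what the bi-modal dominant fit misses.
From the fitted model we derive the two conditional class densities, their
per-level posteriors ``P1``/``P2`` (dark / light tissue) and a deterministic
binarization threshold.

A *discrete Gaussian* (DG) over levels ``0..Q-1`` integrates a normal density
over unit bins, with the two end bins absorbing the tails, so each component
sums exactly to one.

Fitting pipeline (deterministic given the histogram and settings):

1. dominant 2-component fit: count-weighted EM on the histogram, initialized
   from quantile means;
2. deviation signal = empirical − dominant; its positive part is fitted by an
   ``n_add``-component EM, the absolute negative part by ``n_sub`` components;
3. joint refinement of all signed weights by coordinate-wise proportional
   re-fitting, minimizing the L1 distance between the (clipped, renormalized)
   total density and the empirical one — the L1 trace is non-increasing by
   construction, so the final model is never worse than the dominant-only fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .volio import GrayVolume, LabelMap, binary_map

__all__ = [
    "DiscreteGaussian",
    "Histogram",
    "LCDGModel",
    "dg_density",
    "empirical_histogram",
    "init_dominant_modes",
    "fit_lcdg",
    "class_posteriors",
    "binarize",
]

SIGMA_FLOOR = 0.5  # gray levels; prevents spike collapse on discrete data
PRUNE_WEIGHT = 1e-4


@dataclass(frozen=True)
class DiscreteGaussian:
    """One DG component: signed weight, mean and sigma in gray-level units."""

    weight: float
    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class Histogram:
    counts: np.ndarray
    empirical: np.ndarray

    @property
    def levels(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class LCDGModel:
    """Fitted LCDG: dominant pair, signed deviations, class densities, threshold."""

    dominant: list
    additive: list
    subtractive: list
    class_densities: tuple  # (dark, light) per-level vectors
    class_weights: tuple  # mixing priors (pi1, pi2)
    threshold: int
    levels: int
    l1_trace: list = field(default_factory=list)
    converged: bool = True

    def total_density(self) -> np.ndarray:
        return _total_density(self.dominant + self.additive, self.subtractive, self.levels)


def dg_density(mean: float, sigma: float, levels: int) -> np.ndarray:
    """Discrete Gaussian over ``0..levels-1``: unit-bin integrals, tails folded
    into the end bins.  Sums to 1 exactly."""
    edges = np.arange(levels + 1, dtype=np.float64) - 0.5
    cdf = norm.cdf(edges, loc=mean, scale=sigma)
    cdf[0] = 0.0
    cdf[-1] = 1.0
    return np.diff(cdf)


def _components_matrix(comps, levels: int) -> np.ndarray:
    if not comps:
        return np.zeros((0, levels))
    return np.stack([dg_density(c.mean, c.sigma, levels) for c in comps])


def _total_density(additive, subtractive, levels: int) -> np.ndarray:
    """Signed sum of components, clipped at zero and renormalized."""
    p = np.zeros(levels)
    for c in additive:
        p += c.weight * dg_density(c.mean, c.sigma, levels)
    for c in subtractive:
        p -= abs(c.weight) * dg_density(c.mean, c.sigma, levels)
    p = np.clip(p, 0.0, None)
    s = p.sum()
    if s <= 0:
        raise ValueError("signed density is non-positive everywhere; cannot repair")
    return p / s


# ---------------------------------------------------------------------------
# Histogram


def empirical_histogram(
    v: GrayVolume, mask: LabelMap | np.ndarray | None = None, levels: int = 256
) -> Histogram:
    """Histogram of gray levels over the volume (optionally within a mask)."""
    data = np.asarray(v.data)
    if mask is not None:
        m = mask.labels > 0 if isinstance(mask, LabelMap) else np.asarray(mask) > 0
        if m.shape != data.shape:
            raise ValueError("mask shape does not match volume")
        if not m.any():
            raise ValueError("empty mask: no voxels to histogram")
        data = data[m]
    vals = np.rint(data).astype(np.int64).ravel()
    if vals.min() < 0 or vals.max() > levels - 1:
        raise ValueError(
            f"volume has levels outside [0, {levels - 1}]; rescale_intensities first"
        )
    counts = np.bincount(vals, minlength=levels)
    return Histogram(counts=counts, empirical=counts / counts.sum())


# ---------------------------------------------------------------------------
# Dominant two-mode fit


def _em_mixture(
    weights: np.ndarray,
    k: int,
    init_means: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
    sigma_cap: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted EM for a k-component DG mixture on histogram weights.

    ``weights`` is any non-negative per-level mass (counts or a deviation
    signal); it is normalized internally.  Returns (pi, means, sigmas).
    ``sigma_cap`` bounds component widths (used for deviation fits, whose
    components model local mode-shape corrections, not global structure).
    """
    levels = len(weights)
    q = np.arange(levels, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    w = w / w.sum()
    pi = np.full(k, 1.0 / k)
    means = np.asarray(init_means, dtype=np.float64).copy()
    glob_var = max(np.sum(w * (q - np.sum(w * q)) ** 2), SIGMA_FLOOR**2)
    sigmas = np.full(k, np.sqrt(glob_var) / max(k, 1))
    sigmas = np.maximum(sigmas, SIGMA_FLOOR)
    prev_ll = -np.inf
    for _ in range(max_iter):
        dens = np.stack([dg_density(means[j], sigmas[j], levels) for j in range(k)])
        mix = pi[:, None] * dens  # (k, Q)
        tot = mix.sum(axis=0)
        tot = np.where(tot <= 0, 1e-300, tot)
        ll = float(np.sum(w * np.log(tot)))
        resp = mix / tot  # (k, Q)
        mass = resp @ w
        mass = np.where(mass <= 0, 1e-300, mass)
        pi = mass / mass.sum()
        means = (resp * q) @ w / mass
        var = np.einsum("kq,q->k", resp * (q[None, :] - means[:, None]) ** 2, w) / mass
        sigmas = np.maximum(np.sqrt(np.maximum(var, 0.0)), SIGMA_FLOOR)
        if sigma_cap is not None:
            sigmas = np.minimum(sigmas, sigma_cap)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    order = np.argsort(means)
    return pi[order], means[order], sigmas[order]


def _quantile_means(h_weights: np.ndarray, k: int) -> np.ndarray:
    """Quantile-based EM initialization: means at the (2j+1)/2k quantiles."""
    w = np.asarray(h_weights, dtype=np.float64)
    cdf = np.cumsum(w / w.sum())
    qs = (2 * np.arange(k) + 1) / (2 * k)
    return np.array([float(np.searchsorted(cdf, t)) for t in qs])


def init_dominant_modes(h: Histogram) -> tuple[list, np.ndarray]:
    """Two-component non-negative mixture fit of the empirical distribution.

    Returns the two dominant DGs (means ascending, weights folded in) and
    their mixing weights.  This is the initial bi-modal approximation from
    which the deviation components are later derived.
    """
    occupied = np.count_nonzero(h.counts)
    if occupied < 2:
        raise ValueError(
            "histogram has a single occupied level; a bi-modal distribution is required"
        )
    pi, means, sigmas = _em_mixture(h.counts.astype(float), 2, _quantile_means(h.counts, 2))
    comps = [DiscreteGaussian(float(pi[j]), float(means[j]), float(sigmas[j])) for j in range(2)]
    return comps, pi


# ---------------------------------------------------------------------------
# Full LCDG fit


def _fit_deviation(signal: np.ndarray, k: int, sigma_cap: float | None = None) -> list:
    """Fit k DGs to a non-negative deviation signal; weights carry its mass."""
    mass = float(signal.sum())
    if k == 0 or mass <= 1e-12 or np.count_nonzero(signal) == 0:
        return []
    k_eff = min(k, int(np.count_nonzero(signal)))
    pi, means, sigmas = _em_mixture(
        signal, k_eff, _quantile_means(signal, k_eff), max_iter=100, sigma_cap=sigma_cap
    )
    return [
        DiscreteGaussian(float(mass * pi[j]), float(means[j]), float(sigmas[j]))
        for j in range(k_eff)
    ]


def _l1(p: np.ndarray, emp: np.ndarray) -> float:
    return float(np.abs(p - emp).sum())


def fit_lcdg(
    h: Histogram,
    n_add: int = 4,
    n_sub: int = 4,
    max_iter: int = 50,
    tol: float = 1e-7,
) -> LCDGModel:
    """Fit the full signed LCDG model to a histogram.

    The returned model's total density is a proper distribution and its L1
    distance to the empirical histogram never exceeds the dominant-only
    fit's.  ``max_iter`` bounds the weight-refinement sweeps; ``tol`` is the
    L1-improvement stopping threshold.
    """
    dominant, _ = init_dominant_modes(h)
    emp = h.empirical
    levels = h.levels
    dom_density = _total_density(dominant, [], levels)
    l1_dom = _l1(dom_density, emp)
    trace = [l1_dom]

    deviation = emp - dom_density
    sigma_cap = max(c.sigma for c in dominant)
    additive = _fit_deviation(np.clip(deviation, 0, None), n_add, sigma_cap)
    subtractive = _fit_deviation(np.clip(-deviation, 0, None), n_sub, sigma_cap)

    # Joint refinement: coordinate-wise proportional re-fitting of all signed
    # weights, accepting a step only when it lowers L1 (monotone trace).
    comps = list(dominant) + list(additive) + list(subtractive)
    signs = np.array([1.0] * (2 + len(additive)) + [-1.0] * len(subtractive))
    w = np.array([abs(c.weight) for c in comps], dtype=np.float64)
    mat = _components_matrix(comps, levels)  # (n, Q)

    def density_of(wv: np.ndarray) -> np.ndarray:
        p = np.clip((signs * wv) @ mat, 0.0, None)
        s = p.sum()
        if s <= 0:
            raise ValueError("signed density collapsed to zero during refinement")
        return p / s

    best_w = w.copy()
    best_l1 = _l1(density_of(w), emp) if len(comps) > 2 else l1_dom
    if best_l1 > l1_dom:  # deviation fit made things worse: start from zeroed deviations
        w0 = w.copy()
        w0[2:] = 0.0
        best_w, best_l1 = w0, l1_dom
    trace.append(best_l1)

    converged = True
    if len(comps) > 2:
        steps = (0.5, 0.25, 0.1, 0.05, 0.02, 0.01)
        it = 0
        for it in range(max_iter):
            improved = False
            for j in range(len(comps)):
                base = max(best_w[j], 0.02)
                for s in steps:
                    for direction in (+1.0, -1.0):
                        cand = best_w.copy()
                        cand[j] = max(0.0, cand[j] + direction * s * base)
                        try:
                            l1c = _l1(density_of(cand), emp)
                        except ValueError:
                            continue
                        if l1c < best_l1 - 1e-15:
                            best_w, best_l1 = cand, l1c
                            improved = True
            trace.append(best_l1)
            if not improved or (len(trace) > 2 and trace[-2] - trace[-1] < tol):
                break
        converged = it < max_iter - 1

    w = best_w
    refined = [
        DiscreteGaussian(float(signs[j] * w[j]), comps[j].mean, comps[j].sigma)
        for j in range(len(comps))
    ]
    dominant = refined[:2]
    additive = [
        c for j, c in enumerate(refined[2:], 2) if signs[j] > 0 and abs(c.weight) >= PRUNE_WEIGHT
    ]
    subtractive = [
        c for j, c in enumerate(refined[2:], 2) if signs[j] < 0 and abs(c.weight) >= PRUNE_WEIGHT
    ]

    class_densities, class_weights = _class_split(dominant, additive, subtractive, levels)
    threshold = _threshold_from_model(class_densities, class_weights)
    return LCDGModel(
        dominant=dominant,
        additive=additive,
        subtractive=subtractive,
        class_densities=class_densities,
        class_weights=class_weights,
        threshold=threshold,
        levels=levels,
        l1_trace=trace,
        converged=converged,
    )


def _class_split(dominant, additive, subtractive, levels: int):
    """Build the two conditional class densities.

    Each deviation component is assigned to the dominant mode whose mean is
    nearest; the class density is the clipped, renormalized signed sum of its
    dominant DG and its assigned deviations.  Class priors are the clipped
    class masses, renormalized over the two classes.
    """
    mu = [dominant[0].mean, dominant[1].mean]
    groups: list[list] = [[dominant[0]], [dominant[1]]]
    for c in additive + subtractive:
        groups[int(abs(c.mean - mu[0]) > abs(c.mean - mu[1]))].append(c)
    densities, masses = [], []
    for g in groups:
        p = np.zeros(levels)
        for c in g:
            p += c.weight * dg_density(c.mean, c.sigma, levels)
        p = np.clip(p, 0.0, None)
        mass = p.sum()
        if mass <= 0:
            p = dg_density(g[0].mean, g[0].sigma, levels)
            mass = max(abs(g[0].weight), 1e-12)
        densities.append(p / p.sum())
        masses.append(mass)
    tot = masses[0] + masses[1]
    return (densities[0], densities[1]), (masses[0] / tot, masses[1] / tot)


def _posterior_vectors(class_densities, class_weights):
    j1 = class_weights[0] * class_densities[0]
    j2 = class_weights[1] * class_densities[1]
    tot = j1 + j2
    safe = np.where(tot <= 0, 1.0, tot)
    p1 = np.where(tot <= 0, 0.5, j1 / safe)
    return p1, 1.0 - p1


def _threshold_from_model(class_densities, class_weights) -> int:
    """Bayes-error-minimizing cut under the fitted model.

    err(t) = pi2 * sum_{q<t} p2(q) + pi1 * sum_{q>=t} p1(q), minimized over
    all candidate levels t in 0..Q.  On smooth fits this is the level where
    the class posteriors cross (P2 >= P1 above it); when the minimum is flat
    (well-separated classes leave a zero-density gap), the middle of the
    tying range is taken, which keeps both classes clear of the cut.
    """
    (p1, p2), (w1, w2) = class_densities, class_weights
    q = len(p1)
    miss_light = np.concatenate([[0.0], np.cumsum(w2 * p2)])  # light below t
    miss_dark = w1 * p1.sum() - np.concatenate([[0.0], np.cumsum(w1 * p1)])  # dark at/above t
    err = miss_light + miss_dark
    ties = np.flatnonzero(err <= err.min() + 1e-12)
    return int(ties[len(ties) // 2])


def class_posteriors(model: LCDGModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-level posteriors (P1 dark, P2 light); they sum to one at each level."""
    return _posterior_vectors(model.class_densities, model.class_weights)


def binarize(v: GrayVolume, model: LCDGModel) -> LabelMap:
    """Label voxels light (1) where level >= model.threshold, dark (0) below.

    Equivalent to the per-voxel posterior rule P2 >= P1 by the threshold's
    construction.
    """
    data = np.rint(np.asarray(v.data)).astype(np.int64)
    if data.max() > model.levels - 1 or data.min() < 0:
        raise ValueError("volume not rescaled to the model's gray-level range")
    return binary_map(data >= model.threshold, v.spacing)


def fit_volume(
    v: GrayVolume,
    mask: np.ndarray | None = None,
    levels: int = 256,
    n_add: int = 4,
    n_sub: int = 4,
) -> LCDGModel:
    """Convenience: histogram a (masked) volume and fit the LCDG model."""
    h = empirical_histogram(v, mask=mask, levels=levels)
    return fit_lcdg(h, n_add=n_add, n_sub=n_sub)


# ---------------------------------------------------------------------------
# Serialization (plain text key-value)


def save_model(model: LCDGModel, path) -> None:
    lines = [f"levels {model.levels}", f"threshold {model.threshold}"]
    for kind, comps in (
        ("dominant", model.dominant),
        ("additive", model.additive),
        ("subtractive", model.subtractive),
    ):
        for c in comps:
            lines.append(f"{kind} {c.weight!r} {c.mean!r} {c.sigma!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> LCDGModel:
    levels, threshold = 256, 0
    comps = {"dominant": [], "additive": [], "subtractive": []}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "levels":
                levels = int(parts[1])
            elif parts[0] == "threshold":
                threshold = int(parts[1])
            elif parts[0] in comps:
                comps[parts[0]].append(
                    DiscreteGaussian(float(parts[1]), float(parts[2]), float(parts[3]))
                )
    class_densities, class_weights = _class_split(
        comps["dominant"], comps["additive"], comps["subtractive"], levels
    )
    return LCDGModel(
        dominant=comps["dominant"],
        additive=comps["additive"],
        subtractive=comps["subtractive"],
        class_densities=class_densities,
        class_weights=class_weights,
        threshold=threshold,
        levels=levels,
    )
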