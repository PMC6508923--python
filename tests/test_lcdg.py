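import numpy as np
import pytest
from scipy.stats import norm

from thighseg import lcdg
from thighseg.volio import GrayVolume


def hist_from_values(x, levels=256):
    counts = np.bincount(np.asarray(x, dtype=np.int64), minlength=levels)
    return lcdg.Histogram(counts=counts, empirical=counts / counts.sum())


def two_gaussian_sample(mu1, mu2, sigma, n, seed):
    rng = np.random.default_rng(seed)
    x = np.concatenate(
        [rng.normal(mu1, sigma, n // 2), rng.normal(mu2, sigma, n - n // 2)]
    )
    return np.clip(np.rint(x), 0, 255).astype(np.int64)


def true_bayes_threshold(mu1, mu2, sigma, levels=256):
    """Brute-force Bayes-error-minimizing cut under the generating mixture."""
    t = np.arange(levels + 1) - 0.5
    err = 0.5 * (1 - norm.cdf(t, mu1, sigma)) + 0.5 * norm.cdf(t, mu2, sigma)
    return int(np.argmin(err))


def test_histogram_counts_and_mask():
    v = GrayVolume(np.full((4, 4, 4), 7.0))
    h = lcdg.empirical_histogram(v)
    assert h.counts[7] == 64 and h.empirical[7] == 1.0
    data = np.zeros((4, 4, 4))
    data[:2] = 50.0
    data[2:] = 200.0
    h2 = lcdg.empirical_histogram(GrayVolume(data))
    assert h2.empirical[50] == h2.empirical[200] == 0.5
    with pytest.raises(ValueError):
        lcdg.empirical_histogram(v, mask=np.zeros((4, 4, 4), dtype=bool))


def test_phantom_fs_histogram_is_bimodal(clean_phantom):
    from thighseg.volio import rescale_intensities

    fs = rescale_intensities(clean_phantom.fs)
    thigh = clean_phantom.truth_tissues.thigh.labels
    h = lcdg.empirical_histogram(fs, mask=thigh)
    peaks = np.argsort(h.empirical)[-2:]
    assert abs(int(peaks.max()) - int(peaks.min())) > 50  # fat dark, muscle bright


def test_dominant_mode_recovery():
    x = two_gaussian_sample(64, 192, 10, 100_000, seed=42)
    comps, pi = lcdg.init_dominant_modes(hist_from_values(x))
    assert comps[0].mean == pytest.approx(64, abs=3)
    assert comps[1].mean == pytest.approx(192, abs=3)
    assert pi[0] == pytest.approx(0.5, abs=0.05)
    assert pi[1] == pytest.approx(0.5, abs=0.05)


def test_dominant_modes_on_two_spikes():
    counts = np.zeros(256, dtype=int)
    counts[40] = 500
    counts[200] = 500
    comps, _ = lcdg.init_dominant_modes(
        lcdg.Histogram(counts=counts, empirical=counts / counts.sum())
    )
    assert comps[0].mean == pytest.approx(40, abs=0.5)
    assert comps[1].mean == pytest.approx(200, abs=0.5)
    assert comps[0].sigma == pytest.approx(lcdg.SIGMA_FLOOR)


def test_dominant_modes_reject_single_level():
    counts = np.zeros(256, dtype=int)
    counts[9] = 100
    with pytest.raises(ValueError, match="bi-modal"):
        lcdg.init_dominant_modes(lcdg.Histogram(counts=counts, empirical=counts / 100))


def test_exact_mixture_leaves_no_deviations():
    """A histogram that IS a two-DG mixture needs no deviation components."""
    p = 0.5 * lcdg.dg_density(64, 10, 256) + 0.5 * lcdg.dg_density(192, 10, 256)
    counts = np.rint(p * 1e7).astype(int)
    h = lcdg.Histogram(counts=counts, empirical=counts / counts.sum())
    model = lcdg.fit_lcdg(h)
    for c in model.additive + model.subtractive:
        assert abs(c.weight) <= 0.02
    dom_only = lcdg.fit_lcdg(h, n_add=0, n_sub=0)
    l1_model = np.abs(model.total_density() - h.empirical).sum()
    l1_dom = np.abs(dom_only.total_density() - h.empirical).sum()
    assert l1_model <= l1_dom + 1e-12


def test_zero_deviations_reduce_to_dominant_fit():
    x = two_gaussian_sample(64, 192, 10, 20_000, seed=7)
    h = hist_from_values(x)
    model = lcdg.fit_lcdg(h, n_add=0, n_sub=0)
    assert model.additive == [] and model.subtractive == []
    dom, _ = lcdg.init_dominant_modes(h)
    assert [c.mean for c in model.dominant] == [c.mean for c in dom]


def test_skewed_mixture_fits_better_than_dominant_only():
    """Each mode is itself a 2-component sub-mixture; the deviation terms
    must reduce the L1 error below the bi-modal fit."""
    rng = np.random.default_rng(11)
    x = np.concatenate(
        [
            rng.normal(55, 8, 30_000),
            rng.normal(75, 14, 20_000),
            rng.normal(180, 7, 30_000),
            rng.normal(200, 15, 20_000),
        ]
    )
    h = hist_from_values(np.clip(np.rint(x), 0, 255).astype(int))
    model = lcdg.fit_lcdg(h)
    dom_only = lcdg.fit_lcdg(h, n_add=0, n_sub=0)
    l1_model = np.abs(model.total_density() - h.empirical).sum()
    l1_dom = np.abs(dom_only.total_density() - h.empirical).sum()
    assert l1_model < l1_dom


def test_model_density_is_proper_and_trace_monotone():
    x = two_gaussian_sample(80, 170, 12, 50_000, seed=3)
    model = lcdg.fit_lcdg(hist_from_values(x))
    tot = model.total_density()
    assert tot.min() >= 0
    assert tot.sum() == pytest.approx(1.0, abs=1e-6)
    for d in model.class_densities:
        assert d.min() >= 0
        assert d.sum() == pytest.approx(1.0, abs=1e-6)
    assert all(b <= a + 1e-12 for a, b in zip(model.l1_trace, model.l1_trace[1:]))
    assert 0 <= model.threshold < model.levels


def test_posteriors_sum_to_one_and_favor_light_with_level():
    x = two_gaussian_sample(64, 192, 10, 100_000, seed=5)
    model = lcdg.fit_lcdg(hist_from_values(x))
    p1, p2 = lcdg.class_posteriors(model)
    np.testing.assert_allclose(p1 + p2, 1.0, atol=1e-9)
    assert p1[64] > 0.99  # dark-class mean is confidently dark
    assert p2[192] > 0.99
    core = slice(40, 220)  # both class densities unimodal and ordered here
    assert np.all(np.diff(p2[core]) >= -1e-9)


def test_threshold_near_bayes_optimal_and_binarize():
    x = two_gaussian_sample(64, 192, 10, 100_000, seed=9)
    model = lcdg.fit_lcdg(hist_from_values(x))
    oracle = true_bayes_threshold(64, 192, 10)
    assert abs(oracle - 128) <= 1  # equal sigmas: cut at the midpoint
    assert abs(model.threshold - 128) <= 3
    # binarize == thresholding, and misclassification near-optimal
    v = GrayVolume(x.reshape(50, 40, 50).astype(float))
    lab = lcdg.binarize(v, model)
    np.testing.assert_array_equal(lab.labels > 0, v.data >= model.threshold)
    truth = np.zeros(100_000, dtype=bool)
    truth[50_000:] = True
    err_model = np.mean((x >= model.threshold) != truth)
    err_oracle = np.mean((x >= oracle) != truth)
    assert err_model <= 1.2 * err_oracle


def test_binarize_all_dark():
    model = lcdg.fit_lcdg(hist_from_values(two_gaussian_sample(64, 192, 10, 10_000, 1)))
    v = GrayVolume(np.zeros((3, 3, 3)))
    assert not lcdg.binarize(v, model).labels.any()


def test_binarize_matches_threshold_on_random_volumes():
    model = lcdg.fit_lcdg(hist_from_values(two_gaussian_sample(64, 192, 10, 10_000, 2)))
    rng = np.random.default_rng(12)
    for _ in range(5):
        v = GrayVolume(rng.integers(0, 256, size=(9, 8, 7)).astype(float))
        lab = lcdg.binarize(v, model)
        np.testing.assert_array_equal(lab.labels > 0, v.data >= model.threshold)


def test_model_text_roundtrip(tmp_path):
    model = lcdg.fit_lcdg(hist_from_values(two_gaussian_sample(60, 196, 12, 20_000, 4)))
    path = tmp_path / "model.txt"
    lcdg.save_model(model, path)
    back = lcdg.load_model(path)
    assert back.threshold == model.threshold
    assert back.levels == model.levels
    assert len(back.dominant) == 2
    assert [c.mean for c in back.dominant] == [c.mean for c in model.dominant]
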