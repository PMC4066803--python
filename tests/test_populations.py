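"""PoDNano deconvolution, mixtures, percent formation and the arithmetic
deconvolutions."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadpop.populations import (
    ConditionSummary,
    InsufficientDataError,
    Mixture,
    deconvolve_gt_hq,
    fit_gaussian_mixture,
    gq_gt_total,
    gt_hq_split,
    hq_total,
    percent_formation,
    podnano,
    quadruplex_total,
    random_force_deconvolution,
)

TRUE_WEIGHTS = np.array([17.3, 13.2, 12.2]) / 42.7
TRUE_MEANS = np.array([1.8, 3.8, 6.0])
TRUE_SDS = np.array([0.2, 0.5, 0.6])


def _three_component_sample(n, seed):
    rng = np.random.default_rng(seed)
    comp = rng.choice(3, size=n, p=TRUE_WEIGHTS)
    return rng.normal(TRUE_MEANS[comp], TRUE_SDS[comp])


class TestPodnano:
    def test_three_component_recovery(self):
        values = _three_component_sample(400, 21)
        pm = podnano(values, n_boot=500, seed=1)
        assert len(pm.peaks) == 3
        for peak, truth in zip(pm.peaks, TRUE_MEANS):
            assert abs(peak.center - truth) < 0.2

    def test_single_population(self):
        rng = np.random.default_rng(22)
        pm = podnano(rng.normal(5.5, 0.2, 300), n_boot=500, seed=1)
        assert len(pm.peaks) == 1
        assert pm.peaks[0].center == pytest.approx(5.5, abs=0.1)

    def test_degenerate_sample(self):
        pm = podnano(np.full(50, 3.3), n_boot=100, seed=1)
        assert len(pm.peaks) == 1
        assert pm.peaks[0].center == pytest.approx(3.3, abs=0.01)

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            podnano(np.arange(19), n_boot=10)

    def test_peak_count_stability(self):
        """The retained peak count equals the generator's component count in
        at least 95% of seeded runs at n = 400."""
        hits = 0
        for s in range(20):
            values = _three_component_sample(400, 1000 + s)
            pm = podnano(values, n_boot=200, seed=s)
            hits += len(pm.peaks) == 3
        assert hits >= 19

    def test_bootstrap_ci_ordering(self):
        pm = podnano(_three_component_sample(400, 23), n_boot=300, seed=2)
        for p in pm.peaks:
            assert p.ci_low <= p.center + 0.5
            assert p.ci_low < p.ci_high
            assert 0.5 <= p.support <= 1.0


class TestGaussianMixture:
    def test_three_component_recovery(self):
        values = _three_component_sample(600, 31)
        mix = fit_gaussian_mixture(values, 3, init_means=TRUE_MEANS)
        for m, truth, sd in zip(mix.means, TRUE_MEANS, TRUE_SDS):
            se = sd / np.sqrt(len(values) / 3)
            assert abs(m - truth) < 2 * max(se, 0.05) + 0.05

    def test_single_component_is_sample_moments(self):
        rng = np.random.default_rng(32)
        v = rng.normal(10.0, 1.5, 500)
        mix = fit_gaussian_mixture(v, 1)
        assert mix.means[0] == pytest.approx(v.mean(), abs=1e-6)
        assert mix.sds[0] == pytest.approx(v.std(), rel=1e-3)

    def test_permutation_invariance(self):
        values = _three_component_sample(300, 33)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(values)
        a = fit_gaussian_mixture(values, 3, init_means=TRUE_MEANS)
        b = fit_gaussian_mixture(shuffled, 3, init_means=TRUE_MEANS)
        assert np.allclose(a.means, b.means, atol=1e-6)
        assert np.allclose(a.weights, b.weights, atol=1e-6)

    def test_degenerate_component_floored(self):
        v = np.concatenate([np.full(30, 2.0), np.random.default_rng(1).normal(6, 0.5, 30)])
        with pytest.warns(UserWarning, match="degenerate"):
            mix = fit_gaussian_mixture(v, 2)
        assert np.all(mix.sds >= 0.05)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_gaussian_mixture(np.arange(10), 3)


class TestPercentFormation:
    def test_no_events_all_none(self):
        mix = Mixture(np.array([1.0]), np.array([6.0]), np.array([0.5]))
        summary = percent_formation([], 100, mix, "mutant")
        assert summary.percent["none"] == 100.0
        assert summary.n_events == 0

    def test_sums_to_exactly_100(self):
        mix = Mixture(
            np.array([0.4, 0.3, 0.3]), TRUE_MEANS.copy(), TRUE_SDS.copy()
        )
        for seed in range(5):
            values = _three_component_sample(137, seed)
            s = percent_formation(values, 400, mix, "transcription")
            assert sum(s.percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_outlier_goes_unassigned(self):
        mix = Mixture(np.array([1.0]), np.array([6.0]), np.array([0.2]))
        with pytest.warns(UserWarning, match="unassigned"):
            s = percent_formation([6.0, 6.1, 25.0], 10, mix, "no_transcription")
        assert s.n_unassigned == 1

    def test_event_excess_rejected(self):
        mix = Mixture(np.array([1.0]), np.array([6.0]), np.array([0.2]))
        with pytest.raises(ValueError):
            percent_formation([6.0] * 5, 4, mix, "deaza")


class TestGtHqDeconvolution:
    def test_published_worked_example(self):
        """The printed inputs reproduce the printed GT and 3G-HQ split."""
        assert gt_hq_split(12.2, 8.1, 25.9, 13.2) == (3.8, 9.4)

    def test_zero_ratio(self):
        assert gt_hq_split(12.2, 0.0, 25.9, 13.2) == (0.0, 13.2)

    def test_clipping_warns(self):
        with pytest.warns(UserWarning, match="clipping"):
            gt, hq = gt_hq_split(30.0, 20.0, 10.0, 10.0)
        assert hq == 0.0
        assert gt == 60.0

    def test_zero_gq_denominator(self):
        with pytest.raises(ZeroDivisionError):
            gt_hq_split(12.2, 8.1, 0.0, 13.2)

    def test_summary_level_deconvolution(self):
        tr = ConditionSummary(
            "transcription",
            {"2G-HQ": 17.3, "3G-HQ": 13.2, "GT": 0.0, "GQ": 12.2, "none": 57.3},
            1000, 427, middle_unresolved=True,
        )
        dz = ConditionSummary(
            "deaza",
            {"2G-HQ": 0.0, "3G-HQ": 0.0, "GT": 8.1, "GQ": 25.9, "none": 66.0},
            1000, 340,
        )
        out = deconvolve_gt_hq(tr, dz)
        assert out.percent["GT"] == 3.8
        assert out.percent["3G-HQ"] == 9.4
        assert not out.middle_unresolved
        assert hq_total(out) == 26.7
        assert gq_gt_total(out) == 16.0
        assert quadruplex_total(out) == 43


class TestRandomForceDeconvolution:
    def test_separated_populations_pure_labels(self):
        rng = np.random.default_rng(41)
        f = np.concatenate([rng.normal(20, 1, 250), rng.normal(40, 1, 250)])
        truth = np.repeat([0, 1], 250)
        fd = random_force_deconvolution(f, seed=3)
        purity = (fd.labels == truth).mean()
        assert purity >= 0.99

    def test_identical_components_split_evenly(self):
        rng = np.random.default_rng(42)
        f = rng.normal(30, 1.5, 600)
        fd = random_force_deconvolution(f, seed=3)
        frac = (fd.labels == 0).mean()
        assert 0.35 < frac < 0.65

    def test_published_weights_recover_centers(self):
        """Normal(31, 1) + Normal(25, 2) at the published population weights:
        class means come back within 1 pN at n = 500."""
        rng = np.random.default_rng(43)
        w_hq = 26.7 / 42.7
        n_hq = int(round(500 * w_hq))
        f = np.concatenate(
            [rng.normal(31, 1, n_hq), rng.normal(25, 2, 500 - n_hq)]
        )
        fd = random_force_deconvolution(f, seed=4)
        assert fd.class_means[1] == pytest.approx(31.0, abs=1.0)
        assert fd.class_means[0] == pytest.approx(25.0, abs=1.0)

    def test_too_few(self):
        with pytest.raises(InsufficientDataError):
            random_force_deconvolution(np.arange(10))


@settings(deadline=None, max_examples=30)
@given(
    n_events=st.integers(0, 50),
    n_extra=st.integers(0, 200),
    seed=st.integers(0, 10_000),
)
def test_percent_rows_always_sum_to_100(n_events, n_extra, seed):
    """Percent-formation rows sum to 100.0 for arbitrary event subsets."""
    mix = Mixture(np.array([0.5, 0.5]), np.array([3.5, 6.0]), np.array([0.5, 0.5]))
    rng = np.random.default_rng(seed)
    values = rng.normal(rng.choice([3.5, 6.0], size=n_events), 0.4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        s = percent_formation(values, n_events + n_extra + 1, mix, "no_transcription")
    assert sum(s.percent.values()) == pytest.approx(100.0, abs=1e-9)
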