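"""Agreement statistics: Bland-Altman coverage, variance components
against the balanced ANOVA closed form and an independent mixed-model
fit, ICC parameter recovery."""

import warnings

import numpy as np
import pytest

from equigait import agreement as ag
from equigait.signals import TimeSeries


def make_pm(rng, n_subj=10, n_per=100, bias=0.5, sd=2.0, between=0.0):
    subj = np.repeat(np.arange(n_subj), n_per)
    u = rng.normal(0, np.sqrt(between), n_subj)[subj] if between > 0 else 0.0
    d = bias + u + rng.normal(0, sd, n_subj * n_per)
    a = rng.normal(10, 3, n_subj * n_per)
    return ag.PairedMeasurements(a, a - d, subj), d


class TestResidualStats:
    def test_identical_signals(self, rng):
        x = TimeSeries(rng.normal(size=500), 200.0)
        assert ag.residual_stats(x, x) == (0.0, 0.0, 0.0)

    def test_constant_offset(self, rng):
        x = rng.normal(size=500)
        a = TimeSeries(x, 200.0)
        b = TimeSeries(x + 2.0, 200.0)
        rmse, mean, sd = ag.residual_stats(a, b)
        assert rmse == pytest.approx(2.0)
        assert mean == pytest.approx(-2.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_known_white_residual(self, rng):
        x = rng.normal(size=200000)
        a = TimeSeries(x, 200.0)
        b = TimeSeries(x + rng.normal(0, 1.85e-3, len(x)) * 1000, 200.0)
        rmse, mean, sd = ag.residual_stats(b, a)
        assert rmse == pytest.approx(1.85, rel=0.02)
        assert mean == pytest.approx(0.0, abs=0.02)

    def test_gaps_excluded_pairwise(self, rng):
        x = rng.normal(size=100)
        mask = np.zeros(100, dtype=bool)
        mask[:50] = True
        a = TimeSeries(x, 200.0, gap_mask=mask)
        b = TimeSeries(np.where(mask, 99.0, x), 200.0)
        assert ag.residual_stats(a, b)[0] == 0.0

    def test_no_overlap_raises(self, rng):
        mask = np.ones(10, dtype=bool)
        a = TimeSeries(np.zeros(10), 200.0, gap_mask=mask)
        with pytest.raises(ValueError):
            ag.residual_stats(a, TimeSeries(np.zeros(10), 200.0))


class TestBlandAltman:
    def test_perfect_agreement(self, rng):
        a = rng.normal(size=100)
        pm = ag.PairedMeasurements(a, a.copy(), np.repeat([0, 1], 50))
        rep = ag.bland_altman(pm)
        assert rep.bias == 0.0
        assert rep.loa_upper == rep.loa_lower == 0.0

    def test_coverage_of_limits(self, rng):
        pm, d = make_pm(rng, n_subj=10, n_per=1000)
        rep = ag.bland_altman(pm)
        frac = np.mean((d >= rep.loa_lower) & (d <= rep.loa_upper))
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_antisymmetry_in_arguments(self, rng):
        pm, _ = make_pm(rng, n_subj=5, n_per=50)
        fwd = ag.bland_altman(pm)
        rev = ag.bland_altman(ag.PairedMeasurements(pm.value_b, pm.value_a,
                                                    pm.subject_id))
        assert rev.bias == pytest.approx(-fwd.bias)
        assert rev.loa_upper == pytest.approx(-fwd.loa_lower)
        assert rev.loa_lower == pytest.approx(-fwd.loa_upper)

    def test_trial_means_narrow_the_limits(self, rng):
        subj = np.repeat(np.arange(6), 200)
        trial = np.tile(np.repeat(np.arange(4), 50), 6)
        d = rng.normal(0.0, 3.0, len(subj))
        a = rng.normal(20, 5, len(subj))
        pm = ag.PairedMeasurements(a, a - d, subj, trial_id=trial)
        per = ag.bland_altman(pm, level="per_stride")
        tm = ag.bland_altman(pm, level="trial_mean")
        assert (tm.loa_upper - tm.loa_lower) < 0.5 * (per.loa_upper - per.loa_lower)

    def test_single_subject_falls_back_with_warning(self, rng):
        a = rng.normal(size=30)
        pm = ag.PairedMeasurements(a, a + rng.normal(size=30), np.zeros(30))
        with pytest.warns(UserWarning, match="single subject"):
            rep = ag.bland_altman(pm)
        assert rep.loa_lower <= rep.bias <= rep.loa_upper

    def test_between_subject_variance_widens_limits(self, rng):
        pm0, _ = make_pm(rng, between=0.0)
        pm1, _ = make_pm(rng, between=9.0)
        w0 = ag.bland_altman(pm0).sd_diff
        w1 = ag.bland_altman(pm1).sd_diff
        assert w1 > w0 + 0.5  # 10 subjects: the component is noisy but present


class TestVarianceComponents:
    def test_reml_matches_balanced_anova_closed_form(self, rng):
        k, m = 12, 30
        y = (rng.normal(0, 1.5, k)[:, None] + rng.normal(0, 1.0, (k, m))).ravel()
        groups = np.repeat(np.arange(k), m)
        t00, s2 = ag._reml_variance_components(y, groups, np.bincount(groups))
        means = y.reshape(k, m).mean(axis=1)
        msb = m * np.var(means, ddof=1)
        msw = np.sum((y.reshape(k, m) - means[:, None]) ** 2) / (k * (m - 1))
        assert t00 == pytest.approx((msb - msw) / m, abs=1e-6)
        assert s2 == pytest.approx(msw, abs=1e-6)

    def test_reml_matches_statsmodels_unbalanced(self, rng):
        from statsmodels.regression.mixed_linear_model import MixedLM

        sizes = rng.integers(5, 40, size=12)
        groups = np.repeat(np.arange(12), sizes)
        y = rng.normal(0, 2.0, 12)[groups] + rng.normal(0, 1.0, len(groups))
        t00, s2 = ag._reml_variance_components(y, groups, np.bincount(groups))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, np.ones((len(y), 1)), groups=groups).fit(reml=True)
        assert t00 == pytest.approx(float(np.asarray(res.cov_re)[0, 0]), abs=2e-3)
        assert s2 == pytest.approx(float(res.scale), abs=2e-3)


class TestIcc:
    def test_formula_consistency(self, rng):
        pm, _ = make_pm(rng, n_subj=8, n_per=20, between=4.0)
        rep = ag.icc_mixed(pm)
        expected = rep.t00 / (rep.t00 + rep.sigma2 / rep.nj)
        assert rep.icc == pytest.approx(min(max(expected, 0.0), 1.0))
        assert rep.nj == 20

    def test_zero_between_subject_variance(self, rng):
        subj = np.repeat(np.arange(20), 100)
        y = rng.normal(0, 1.0, 2000)
        pm = ag.PairedMeasurements(y, np.zeros(2000), subj)
        rep = ag.icc_mixed(pm)
        assert rep.icc <= 0.05

    def test_parameter_recovery(self, rng):
        # t00=4, sigma2=1, 20 groups of 50 -> analytic ICC = 4/(4+1/50)
        analytic = 4.0 / (4.0 + 1.0 / 50.0)
        estimates = []
        for _ in range(20):
            y = (rng.normal(0, 2.0, 20)[:, None]
                 + rng.normal(0, 1.0, (20, 50))).ravel()
            pm = ag.PairedMeasurements(y, np.zeros_like(y),
                                       np.repeat(np.arange(20), 50))
            estimates.append(ag.icc_mixed(pm).icc)
        assert abs(np.median(estimates) - analytic) < 0.05

    def test_monotone_in_between_subject_variance(self, rng):
        iccs = []
        for between in (0.5, 2.0, 8.0):
            y = (rng.normal(0, np.sqrt(between), 15)[:, None]
                 + rng.normal(0, 1.0, (15, 40))).ravel()
            pm = ag.PairedMeasurements(y, np.zeros_like(y),
                                       np.repeat(np.arange(15), 40))
            iccs.append(ag.icc_mixed(pm).icc)
        assert iccs[0] < iccs[1] < iccs[2]

    def test_stacked_response_high_when_systems_agree(self, rng):
        subj = np.repeat(np.arange(8), 40)
        level = rng.normal(0, 5.0, 8)[subj]
        a = level + rng.normal(0, 0.3, len(subj))
        b = level + rng.normal(0, 0.3, len(subj))
        rep = ag.icc_mixed(ag.PairedMeasurements(a, b, subj), response="stacked")
        assert rep.icc > 0.9

    def test_requires_two_subjects(self, rng):
        pm = ag.PairedMeasurements(rng.normal(size=10), rng.normal(size=10),
                                   np.zeros(10))
        with pytest.raises(ValueError):
            ag.icc_mixed(pm)
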