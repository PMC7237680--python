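"""KDE likelihood ratios, the regression suite, and the Deming fit."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from blinkengage.rates import scene_rates
from blinkengage.strength import (
    GaussianKDE1D,
    cohort_likelihoods,
    deming_fit,
    group_pdf,
    likelihood_ratio,
    strength_regressions,
)
from blinkengage.synth import CohortParams, simulate_cohort
from blinkengage.types import GROUP_LAND, GROUP_WATER, ValidationError


class TestKDE:
    def test_single_gaussian_closed_form(self):
        pdf = GaussianKDE1D([0.0], bandwidth=1.0)
        assert float(pdf(0.0)) == pytest.approx(1 / math.sqrt(2 * math.pi), abs=1e-12)

    def test_symmetric_sample_symmetric_density(self):
        pdf = group_pdf([-2.0, 2.0])
        for x in (0.5, 1.3, 2.7):
            assert float(pdf(x)) == pytest.approx(float(pdf(-x)), abs=1e-12)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        values = rng.normal(3.0, 2.0, 15)
        pdf = group_pdf(values)
        lo = values.min() - 10 * pdf.bandwidth
        hi = values.max() + 10 * pdf.bandwidth
        total, _ = integrate.quad(lambda x: float(pdf(x)), lo, hi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_zero_bandwidth_rejected(self):
        with pytest.raises(ValidationError, match="bandwidth"):
            group_pdf([1.0, 1.0, 1.0])

    def test_matches_scipy_at_same_bandwidth(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=25)
        h = 1.3 * values.std(ddof=1)
        ours = GaussianKDE1D(values, bandwidth=h)
        ref = stats.gaussian_kde(values, bw_method=1.3)
        for x in (-2.0, 0.0, 0.7, 3.1):
            assert float(ours(x)) == pytest.approx(float(ref(x)[0]), rel=1e-9)


class TestLikelihoodRatio:
    def test_arithmetic(self):
        res = likelihood_ratio(0.0, lambda x: 0.4, lambda x: 0.1)
        assert res.lr == pytest.approx(4.0)
        assert res.log_lr == pytest.approx(math.log(4.0), abs=1e-12)

    def test_equal_densities_indifferent(self):
        res = likelihood_ratio(0.0, lambda x: 0.25, lambda x: 0.25)
        assert res.lr == 1.0 and res.log_lr == 0.0

    def test_floor_guards_zero_density(self):
        res = likelihood_ratio(0.0, lambda x: 0.4, lambda x: 0.0)
        assert np.isfinite(res.lr)
        assert res.lr == pytest.approx(0.4 / 1e-12)


class TestCohortLikelihoods:
    def _cohort_metrics(self, seed=0):
        rng = np.random.default_rng(seed)
        metrics = np.concatenate([rng.normal(-5, 1, 6), rng.normal(5, 1, 5)])
        groups = [GROUP_LAND] * 6 + [GROUP_WATER] * 5
        pids = [f"P{i}" for i in range(11)]
        return pids, metrics, groups

    def test_swap_negates_log_lr_exactly(self):
        pids, metrics, groups = self._cohort_metrics()
        fwd = cohort_likelihoods(pids, metrics, groups)
        rev = cohort_likelihoods(pids, metrics, groups, swap_groups=True)
        for a, b in zip(fwd, rev):
            assert a.log_lr == pytest.approx(-b.log_lr, abs=1e-12)
            assert a.lr > 0 and b.lr > 0

    def test_separated_groups_all_fit_their_own(self):
        # moderate fixed bandwidth keeps densities above the floor even for
        # each group's most extreme member
        pids, metrics, groups = self._cohort_metrics(3)
        for res in cohort_likelihoods(pids, metrics, groups, bandwidth=1.5):
            assert res.lr > 1

    def test_self_exclusion_two_per_group_closed_form(self):
        """With 2 per group, the left-one-out density at a participant's
        metric is a single Gaussian kernel centred on their group partner."""
        metrics = np.array([0.0, 1.0, 10.0, 12.0])
        groups = [GROUP_LAND, GROUP_LAND, GROUP_WATER, GROUP_WATER]
        h = 2.0
        res = cohort_likelihoods(["a", "b", "c", "d"], metrics, groups, bandwidth=h)
        expected_num = stats.norm.pdf(0.0, loc=1.0, scale=h)
        expected_den = (
            stats.norm.pdf(0.0, loc=10.0, scale=h)
            + stats.norm.pdf(0.0, loc=12.0, scale=h)
        ) / 2
        assert res[0].lr == pytest.approx(expected_num / expected_den, rel=1e-9)

    def test_inclusive_mode_inflates_own_fit(self):
        pids, metrics, groups = self._cohort_metrics(5)
        loo = cohort_likelihoods(pids, metrics, groups, bandwidth=1.0)
        inc = cohort_likelihoods(
            pids, metrics, groups, bandwidth=1.0, leave_one_out=False
        )
        assert all(i.lr >= l.lr for i, l in zip(inc, loo))


class TestStrengthRegressions:
    def test_exact_line_unit_r_squared(self):
        x = np.arange(10.0)
        fits = {f.form: f for f in strength_regressions(x, 2 * x + 1)}
        assert fits["linear"].r_squared == pytest.approx(1.0, abs=1e-12)
        assert fits["linear"].coefficients[1] == pytest.approx(2.0, abs=1e-9)

    def test_exact_exponential_recovered(self):
        x = np.linspace(0, 4, 12)
        y = 3.0 * np.exp(0.5 * x)
        fits = {f.form: f for f in strength_regressions(x, y)}
        a, b = fits["exponential"].coefficients
        assert a == pytest.approx(3.0, abs=1e-6)
        assert b == pytest.approx(0.5, abs=1e-6)

    def test_bonferroni_multiplier(self):
        rng = np.random.default_rng(2)
        x = np.arange(12.0)
        y = x + rng.normal(0, 3.0, 12)
        for f in strength_regressions(x, y, n_comparisons=13):
            if np.isfinite(f.p_value):
                assert f.p_bonferroni == pytest.approx(min(1.0, 13 * f.p_value))

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError, match="[Ss]ingular|constant"):
            strength_regressions(np.ones(8), np.arange(8.0))

    def test_one_second_condition_strength_increases_with_blink_rate(self):
        """Low-rate participants get noisy metrics in the fastest-alternation
        video, hence weaker group fit: positive log(LR)-on-bpm slope, holding
        across a majority of replicate cohorts."""
        wins = 0
        n_rep = 11
        for seed in range(n_rep):
            records, schedules, _ = simulate_cohort(CohortParams(seed=500 + seed))
            rates = {r.participant_id: scene_rates(r, schedules) for r in records}
            pids = [r.participant_id for r in records]
            cond = 1.0
            metrics = [rates[p].by_condition[cond].metric for p in pids]
            results = cohort_likelihoods(
                pids, metrics, [r.group for r in records], condition_s=cond
            )
            x = [rates[p].by_condition[cond].bpm_session for p in pids]
            y = [r.log_lr for r in results]
            linear = next(
                f for f in strength_regressions(x, y) if f.form == "linear"
            )
            slope = linear.coefficients[1]
            if slope > 0 and linear.p_bonferroni < 0.05:
                wins += 1
        assert wins > n_rep // 2


class TestDemingFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        slope, intercept = deming_fit(x, 2 * x + 1)
        assert slope == pytest.approx(2.0, abs=1e-9)
        assert intercept == pytest.approx(1.0, abs=1e-9)

    def test_corrects_attenuation_of_ordinary_regression(self):
        rng = np.random.default_rng(7)
        latent = rng.normal(0, 3.0, 2000)
        x = latent + rng.normal(0, 1.0, 2000)
        y = latent + rng.normal(0, 1.0, 2000)
        ols_slope = np.polyfit(x, y, 1)[0]
        dem_slope, _ = deming_fit(x, y, variance_ratio=1.0)
        assert ols_slope < 0.95  # attenuated
        assert dem_slope == pytest.approx(1.0, abs=0.05)

    def test_swap_gives_reciprocal_slope(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=50)
        y = 1.7 * x + rng.normal(0, 0.5, 50)
        s_xy, _ = deming_fit(x, y)
        s_yx, _ = deming_fit(y, x)
        assert s_xy == pytest.approx(1 / s_yx, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            deming_fit([1, 2], [1, 2])
        with pytest.raises(ValidationError):
            deming_fit(np.ones(5), np.ones(5))
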