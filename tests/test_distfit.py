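"""Box-Cox transformation, normal Q-Q fitting, critical values, p-values."""

import numpy as np
import pytest
from scipy import stats

import enrichfit as ef
from enrichfit.distfit import qq_points
from enrichfit.errors import DegenerateDataError


class TestTransform:
    @pytest.mark.parametrize(
        "lam,y,expected",
        [(1.0, 7.0, 6.0), (0.0, np.e, 1.0), (2.0, 3.0, 4.0)],
    )
    def test_known_values(self, lam, y, expected):
        assert ef.boxcox_transform([y], lam)[0] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("lam", [-0.5, 0.0, 0.5, 1.0])
    @pytest.mark.parametrize("y", [0.5, 2.0, 10.0])
    def test_inverse_round_trip(self, lam, y):
        assert ef.inverse_boxcox(ef.boxcox_transform([y], lam)[0], lam) == pytest.approx(
            y, rel=1e-10
        )

    @pytest.mark.parametrize("lam", [-0.5, 0.3, 1.7])
    def test_strictly_increasing(self, lam):
        y = np.linspace(0.01, 20, 500)
        assert np.all(np.diff(ef.boxcox_transform(y, lam)) > 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ef.boxcox_transform([1.0, 0.0], 0.5)


class TestBoxcoxMLE:
    def test_lognormal_data_recover_lambda_zero(self):
        rng = np.random.default_rng(0)
        scores = rng.lognormal(0.0, 0.8, 10_000)
        assert abs(ef.boxcox_mle(scores)) < 0.05

    def test_positive_normal_data_give_lambda_near_one(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(100.0, 5.0, 10_000)
        scores = scores[scores > 0]
        assert ef.boxcox_mle(scores) == pytest.approx(1.0, abs=0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            ef.boxcox_mle(np.full(100, 3.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ef.boxcox_mle(np.array([1.0, -2.0, 3.0] * 10))

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(2)
        scores = rng.gamma(2.0, 3.0, 5_000)
        _, lam_ref = stats.boxcox(scores)
        assert ef.boxcox_mle(scores) == pytest.approx(lam_ref, abs=1e-3)


class TestQQFit:
    def test_exact_normal_quantiles_give_unit_r_squared(self):
        n = 500
        data = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n, loc=3, scale=2)
        assert ef.qq_r_squared(data) == pytest.approx(1.0, abs=1e-12)

    def test_mu_sigma_are_sample_moments(self):
        rng = np.random.default_rng(3)
        data = rng.normal(5, 2, 1000)
        fit = ef.qq_fit(data, lam=1.0)
        assert fit.mu == pytest.approx(data.mean(), rel=1e-12)
        assert fit.sigma == pytest.approx(data.std(ddof=1), rel=1e-12)

    def test_heavy_tails_lower_r_squared(self):
        rng = np.random.default_rng(4)
        heavy = rng.standard_t(2, 5_000)
        normal = rng.normal(0, 1, 5_000)
        assert ef.qq_r_squared(heavy) < ef.qq_r_squared(normal)

    def test_r_squared_affine_invariant(self):
        rng = np.random.default_rng(5)
        data = rng.normal(0, 1, 2_000)
        assert ef.qq_r_squared(3.5 * data - 7) == pytest.approx(
            ef.qq_r_squared(data), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            ef.qq_fit(np.zeros(100), lam=1.0)


class TestCriticalValue:
    @staticmethod
    def unit_fit(lam=1.0):
        return ef.NormalFit(
            lam=lam, mu=0.0, sigma=1.0, r_squared=1.0, alpha=0.05,
            r2_cutoff=0.9, critical_transformed=np.nan, critical_raw=np.nan,
        )

    def test_standard_normal_alpha_05(self):
        ct, _ = ef.critical_value(self.unit_fit(), 0.05)
        assert ct == pytest.approx(1.6449, abs=1e-4)

    def test_alpha_half_gives_mean(self):
        fit = self.unit_fit()
        fit.mu = 2.5
        ct, _ = ef.critical_value(fit, 0.5)
        assert ct == pytest.approx(2.5, abs=1e-12)

    def test_raw_scale_is_inverse_image(self):
        fit = self.unit_fit(lam=0.0)
        ct, craw = ef.critical_value(fit, 0.05)
        assert craw == pytest.approx(np.exp(ct), rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.7])
    def test_alpha_domain(self, alpha):
        with pytest.raises(ValueError):
            ef.critical_value(self.unit_fit(), alpha)


class TestPositionPvalues:
    def test_at_mean_and_critical(self):
        fit = TestCriticalValue.unit_fit()
        p = ef.position_pvalues([0.0, 1.6449], fit)
        assert p[0] == pytest.approx(0.5, abs=1e-12)
        assert p[1] == pytest.approx(0.05, abs=1e-4)

    def test_monotone_decreasing_in_score(self):
        fit = TestCriticalValue.unit_fit()
        t = np.linspace(-3, 3, 100)
        assert np.all(np.diff(ef.position_pvalues(t, fit)) < 0)


class TestPercentileCutoff:
    def test_top_five_of_hundred(self):
        scores = np.arange(1.0, 101.0)
        cutoff, called = ef.percentile_cutoff(scores, 95)
        assert cutoff == 96.0
        assert set(scores[called]) == {96.0, 97.0, 98.0, 99.0, 100.0}

    def test_ceiling_rule_n21(self):
        scores = np.arange(1.0, 22.0)
        _, called = ef.percentile_cutoff(scores, 95)
        assert called.sum() == 2  # ceil(21 * 0.05) = 2

    def test_all_ties_called_with_warning(self):
        with pytest.warns(UserWarning):
            _, called = ef.percentile_cutoff(np.full(50, 2.0), 95)
        assert called.all()

    def test_percentile_domain(self):
        with pytest.raises(ValueError):
            ef.percentile_cutoff(np.arange(1.0, 10.0), 100)


def test_type_one_error_calibration_on_lognormal_null():
    """Pure-null log-normal scores: called fraction within 0.01 of alpha."""
    rng = np.random.default_rng(6)
    scores = rng.lognormal(0.0, 1.0, 100_000)
    lam = ef.boxcox_mle(scores)
    t = ef.boxcox_transform(scores, lam)
    fit = ef.qq_fit(t, lam, alpha=0.05)
    frac = (t >= fit.critical_transformed).mean()
    assert frac == pytest.approx(0.05, abs=0.01)


def test_threshold_equivalence_transformed_vs_raw():
    """Calling on the transformed scale equals calling on the raw scale."""
    rng = np.random.default_rng(7)
    for lam_gen in (-0.4, 0.0, 0.6):
        scores = ef.inverse_boxcox_normal_sample(lam_gen, 5_000, rng)
        lam = ef.boxcox_mle(scores)
        t = ef.boxcox_transform(scores, lam)
        fit = ef.qq_fit(t, lam, alpha=0.05)
        called_t = t >= fit.critical_transformed
        called_raw = scores >= fit.critical_raw
        assert np.array_equal(called_t, called_raw)


def test_qq_points_use_half_offset_plotting_positions():
    theo, _ = qq_points(np.arange(4.0))
    expected = stats.norm.ppf((np.arange(1, 5) - 0.5) / 4)
    assert np.allclose(theo, expected)
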