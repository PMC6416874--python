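"""Analytic power functions: critical values, conditional, approximate, exact."""

import numpy as np
import pytest
from scipy import special, stats

from regpower import (
    ConvergenceError,
    DesignSummary,
    EffectSpec,
    InputError,
    PredictorSpec,
    QuadratureSpec,
    UnsupportedMethodError,
    critical_value,
    power_approx,
    power_conditional,
    power_exact,
)

from conftest import batched_joint_f, stress_grid


def simple_path_power(bi, bs, bi0, bs0, s2, mu, sx2, n, alpha=0.05):
    """Independent simple-regression (p = 1) evaluation of the exact power,
    written entirely in scalar arithmetic: collapse the (Z, K) mixture to
    the noncentral chi-square mixing variable and integrate its density."""
    from scipy.integrate import quad

    bid, bsd = bi - bi0, bs - bs0
    a = bid + bsd * mu
    d = bsd * bsd * sx2
    nu = n - 2
    crit = stats.f.isf(alpha, 2, nu)
    if d == 0:
        lam = n * a * a / s2
        return stats.ncf.sf(crit, 2, nu, lam) if lam > 0 else alpha
    lam = n * a * a / d
    mixing = stats.ncx2(n, lam) if lam > 0 else stats.chi2(n)
    cut = 1e-10
    lo, hi = mixing.ppf(cut), mixing.isf(cut)
    val, _ = quad(
        lambda w: stats.ncf.sf(crit, 2, nu, d * w / s2) * mixing.pdf(w),
        lo, hi, epsabs=2.5e-9, epsrel=0, limit=400,
    )
    # trimmed tails: the F tail probability is monotone in w
    val += cut * stats.ncf.sf(crit, 2, nu, d * lo / s2)
    val += cut * stats.ncf.sf(crit, 2, nu, d * hi / s2)
    return min(1.0, val)


class TestCriticalValue:
    def test_monotone_decreasing_in_alpha(self):
        alphas = [0.001, 0.01, 0.05, 0.2, 0.5, 0.9, 0.999]
        vals = [critical_value(2, 30, a) for a in alphas]
        assert all(v1 > v2 for v1, v2 in zip(vals, vals[1:]))
        assert vals[-1] < 0.1  # alpha -> 1 drives the quantile toward 0

    def test_large_denominator_limit_is_chi_square(self):
        # nu -> inf: F(2, nu) crit -> chi2(2) crit / 2
        assert critical_value(2, 10**7, 0.05) == pytest.approx(
            stats.chi2.isf(0.05, 2) / 2, abs=1e-4
        )

    def test_matches_independent_beta_quantile_route(self):
        # F and Beta quantiles are linked by x = (d1 f / d2) / (1 + d1 f / d2)
        for df1, df2, alpha in [(2, 97, 0.05), (3, 40, 0.01), (2, 10, 0.10)]:
            q = special.betaincinv(df1 / 2, df2 / 2, 1 - alpha)
            expected = df2 * q / (df1 * (1 - q))
            assert critical_value(df1, df2, alpha) == pytest.approx(
                expected, rel=1e-8
            )

    def test_rejects_invalid_arguments(self):
        with pytest.raises(InputError):
            critical_value(0, 10, 0.05)
        with pytest.raises(InputError):
            critical_value(2, 10, 1.5)


class TestConditionalPower:
    def test_null_effect_power_is_exactly_alpha(self):
        eff = EffectSpec.simple(1.0, 2.0, 1.0, 2.0, 1.0)
        res = power_conditional(eff, DesignSummary.simple(0.5, 9.0, 20), 0.05)
        assert res.power == pytest.approx(0.05, abs=1e-14)
        assert res.method == "conditional"

    def test_power_diverges_with_noncentrality(self):
        # Delta = n * b_ID^2 / s2 = 1e4 for this configuration
        eff = EffectSpec.simple(10.0, 1.0, 0.0, 1.0, 0.1)
        res = power_conditional(eff, DesignSummary.simple(0.0, 5.0, 10), 0.05)
        assert res.power > 0.9999

    def test_agrees_with_monte_carlo_at_fixed_design(self):
        """Conditional power is the rejection rate of the joint F test when
        the design is held fixed and only the errors are redrawn."""
        rng = np.random.default_rng(20260929)
        n, reps = 10, 10**6
        eff = EffectSpec.simple(0.3, 0.3, 0.0, 0.0, 1.0)
        x = rng.normal(0.5, 1.0, n)
        x = 0.5 + (x - x.mean()) * np.sqrt(9.0 / ((x - x.mean()) ** 2).sum())
        ds = DesignSummary.from_predictors(x[:, None])
        assert float(ds.scatter[0, 0]) == pytest.approx(9.0)
        assert float(ds.xbar[0]) == pytest.approx(0.5)
        analytic = power_conditional(eff, ds, 0.05).power
        crit = critical_value(2, n - 2, 0.05)
        hits = 0
        chunk = 100_000
        for _ in range(reps // chunk):
            y = (eff.true_coefficients[0] + x * eff.true_coefficients[1]
                 + rng.standard_normal((chunk, n)))
            xs = np.broadcast_to(x[:, None], (chunk, n, 1))
            hits += int(batched_joint_f(xs, y, eff.null_coefficients, crit).sum())
        phat = hits / reps
        se = np.sqrt(phat * (1 - phat) / reps)
        assert abs(phat - analytic) < 3 * se


class TestApproximatePower:
    def test_null_effect_gives_alpha(self):
        eff = EffectSpec.simple(0.0, 1.0, 0.0, 1.0, 1.0)
        res = power_approx(eff, PredictorSpec.simple(0.0, 1.0), 30, 0.05)
        assert res.power == pytest.approx(0.05, abs=1e-14)

    def test_benchmark_cell_value(self):
        # shift-0.3 cell at mu=0, sigma2_x=2, evaluated at the exact N = 53
        eff = EffectSpec.simple(0.3, 1.3, 0.0, 1.0, 1.0)
        res = power_approx(eff, PredictorSpec.simple(0.0, 2.0), 53, 0.05)
        assert res.power == pytest.approx(0.4602, abs=5e-5)

    def test_fetal_attained_power(self, fetal_effect, fetal_predictor):
        res = power_approx(fetal_effect, fetal_predictor, 183, 0.05)
        assert res.power == pytest.approx(0.8010, abs=5e-5)

    def test_refuses_non_normal_family(self, fetal_effect):
        pred = PredictorSpec.simple(24.2, 6.0, family="uniform")
        with pytest.raises(UnsupportedMethodError):
            power_approx(fetal_effect, pred, 100)


class TestExactPower:
    def test_fetal_published_values(self, fetal_effect, fetal_predictor):
        for n, expected in [(173, 0.8001), (183, 0.8236), (227, 0.9010),
                            (239, 0.9161)]:
            res = power_exact(fetal_effect, fetal_predictor, n, 0.05)
            assert res.power == pytest.approx(expected, abs=2e-4)
            assert res.quadrature_diagnostics["estimated_abs_error"] <= 1e-8

    def test_null_effect_gives_alpha_within_tolerance(self):
        eff = EffectSpec.simple(0.0, 1.0, 0.0, 1.0, 1.0)
        res = power_exact(eff, PredictorSpec.simple(0.5, 2.0), 40, 0.05)
        assert res.power == pytest.approx(0.05, abs=1e-6)

    def test_refuses_non_normal_family(self, fetal_effect):
        pred = PredictorSpec.simple(24.2, 6.0, family="gamma")
        with pytest.raises(UnsupportedMethodError):
            power_exact(fetal_effect, pred, 100)

    def test_unreachable_tolerance_raises_rather_than_lies(self, fetal_effect,
                                                           fetal_predictor):
        quad = QuadratureSpec(method="monte_carlo", absolute_tolerance=1e-9,
                              node_counts=(10, 10))
        with pytest.raises(ConvergenceError):
            power_exact(fetal_effect, fetal_predictor, 173, quad=quad)

    def test_intercept_only_shift_equals_approximate(self):
        """With no slope difference the covariance term vanishes and the
        exact and approximate powers coincide identically."""
        eff = EffectSpec.simple(0.4, 1.0, 0.0, 1.0, 1.0)
        pred = PredictorSpec.simple(0.7, 2.0)
        for n in (10, 50, 200):
            pe = power_exact(eff, pred, n).power
            pa = power_approx(eff, pred, n).power
            assert pe == pytest.approx(pa, abs=1e-10)

    def test_multiple_regression_path_reduces_to_simple_path(self):
        """The p = 1 case of the general formulation must equal an
        independently coded scalar simple-regression evaluation."""
        for d, mu, sx2, n in [(0.3, 0.0, 0.5, 99), (0.3, 1.0, 2.0, 28),
                              (0.5, 0.5, 1.0, 20), (0.1, 0.0, 2.0, 150)]:
            eff = EffectSpec([d, 1.0 + d], [0.0, 1.0], 1.0)
            pred = PredictorSpec([mu], [[sx2]])
            general = power_exact(eff, pred, n).power
            simple = simple_path_power(d, 1 + d, 0, 1, 1.0, mu, sx2, n)
            assert general == pytest.approx(simple, abs=1e-10)

    def test_two_predictor_power_brackets_between_marginal_cases(self):
        """p = 2 sanity: adding a second discrepant predictor at fixed n
        changes power smoothly and stays within [alpha, 1]."""
        eff = EffectSpec([0.2, 0.2, 0.2], [0.0, 0.0, 0.0], 1.0)
        pred = PredictorSpec([0.0, 0.0], [[1.0, 0.3], [0.3, 1.0]])
        res = power_exact(eff, pred, 60, 0.05)
        assert 0.05 < res.power < 1.0
        assert res.numerator_df == 3 and res.denominator_df == 57

    def test_monte_carlo_scheme_agrees_loosely(self, fetal_effect,
                                               fetal_predictor):
        quad = QuadratureSpec(method="monte_carlo", absolute_tolerance=5e-3,
                              node_counts=(500, 400), seed=11)
        res = power_exact(fetal_effect, fetal_predictor, 173, quad=quad)
        assert res.power == pytest.approx(0.8001, abs=0.01)


class TestExactPowerProperties:
    def test_approximate_never_exceeds_exact_on_stress_grid(self):
        """Mean substitution discards the covariance contribution to the
        noncentrality, so its power can only fall short (strictly, when the
        slope difference and predictor variance are both nonzero)."""
        for d, mu, sx2, n in stress_grid():
            eff = EffectSpec.simple(d, 1 + d, 0.0, 1.0, 1.0)
            pred = PredictorSpec.simple(mu, sx2)
            pe = power_exact(eff, pred, n).power
            pa = power_approx(eff, pred, n).power
            assert pa <= pe + 1e-12, (d, mu, sx2, n)
            if pe < 1.0 - 1e-9:  # strict until float saturation at 1
                assert pa < pe, (d, mu, sx2, n)

    def test_quadrature_schemes_agree_on_stress_grid(self):
        q2 = QuadratureSpec(method="hermite_x_chisq_2d", absolute_tolerance=1e-6)
        for d, mu, sx2, n in stress_grid():
            eff = EffectSpec.simple(d, 1 + d, 0.0, 1.0, 1.0)
            pred = PredictorSpec.simple(mu, sx2)
            p1 = power_exact(eff, pred, n).power
            p2 = power_exact(eff, pred, n, quad=q2).power
            assert p1 == pytest.approx(p2, abs=1e-7), (d, mu, sx2, n)

    def test_monotone_in_sample_size_effect_and_variance(self):
        for d, mu, sx2 in [(0.1, 0.0, 0.5), (0.3, 0.5, 1.0), (0.5, 1.0, 2.0)]:
            pred = PredictorSpec.simple(mu, sx2)
            eff = EffectSpec.simple(d, 1 + d, 0.0, 1.0, 1.0)
            by_n = [power_exact(eff, pred, n).power for n in (20, 50, 100, 200)]
            # strictly increasing until the power saturates at 1 in float
            assert all(
                a <= b + 1e-10 and (a < b or b > 1.0 - 1e-9)
                for a, b in zip(by_n, by_n[1:])
            )
        # increasing the intercept shift (fixed sign structure) raises power
        by_bid = [
            power_exact(EffectSpec.simple(b, 1.3, 0.0, 1.0, 1.0),
                        PredictorSpec.simple(0.5, 1.0), 50).power
            for b in (0.1, 0.3, 0.6)
        ]
        assert by_bid[0] < by_bid[1] < by_bid[2]
        # more predictor spread makes a slope difference easier to detect
        by_var = [
            power_exact(EffectSpec.simple(0.3, 1.3, 0.0, 1.0, 1.0),
                        PredictorSpec.simple(0.5, v), 50).power
            for v in (0.5, 1.0, 2.0)
        ]
        assert by_var[0] < by_var[1] < by_var[2]

    def test_agrees_with_full_data_generating_monte_carlo(self):
        """End-to-end oracle: simulate the entire process (random predictors
        and errors) and compare rejection rates with the analytic power."""
        from regpower import simulate_power

        configs = [
            (0.3, 0.0, 0.5, 99), (0.3, 1.0, 2.0, 28), (0.5, 0.5, 1.0, 20),
            (0.1, 0.0, 1.0, 120), (0.4, 0.5, 2.0, 30),
        ]
        for i, (d, mu, sx2, n) in enumerate(configs):
            eff = EffectSpec.simple(d, 1 + d, 0.0, 1.0, 1.0)
            pred = PredictorSpec.simple(mu, sx2)
            analytic = power_exact(eff, pred, n).power
            sim = simulate_power(eff, eff.null_coefficients, pred, n,
                                 replicates=200_000, seed=314159 + i)
            se = np.sqrt(analytic * (1 - analytic) / sim.replicates)
            assert abs(sim.empirical_power - analytic) < 3.5 * se, (d, mu, sx2, n)
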