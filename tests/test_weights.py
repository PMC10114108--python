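"""Logistic fitter, stabilized weights, SMDs and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from povmsm.errors import InvalidConfigError, PositivityError, SeparationError
from povmsm.weights import (
    ExposureModelSpec,
    balance_table,
    compute_smd,
    compute_stabilized_weights,
    fit_logistic,
)


def _expit(x):
    return 1 / (1 + np.exp(-x))


class TestFitLogistic:
    def test_intercept_only_closed_form(self, rng):
        y = (rng.random(500) < 0.3).astype(float)
        fit = fit_logistic(np.ones((500, 1)), y, names=["const"])
        pbar = y.mean()
        assert fit.params["const"] == pytest.approx(np.log(pbar / (1 - pbar)),
                                                    abs=1e-8)

    def test_matches_statsmodels_with_weights_and_clusters(self, rng):
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        beta = np.array([-0.5, 0.8, -0.3, 0.2])
        y = (rng.random(n) < _expit(X @ beta)).astype(float)
        w = rng.uniform(0.5, 2.0, size=n)
        groups = rng.integers(0, 400, size=n)
        mine = fit_logistic(X, y, sample_weight=w, clusters=groups,
                            names=["const", "a", "b", "c"])
        ref = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(
            cov_type="cluster", cov_kwds={"groups": groups}
        )
        np.testing.assert_allclose(mine.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(
            mine.bse(cluster=True).to_numpy(), ref.bse, rtol=5e-3
        )

    def test_each_row_own_cluster_equals_heteroscedastic_robust(self, rng):
        n = 800
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < _expit(X @ np.array([0.2, 0.6]))).astype(float)
        mine = fit_logistic(X, y, clusters=np.arange(n), names=["const", "x"])
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        # up to the G/(G-1) finite-cluster factor
        factor = n / (n - 1)
        np.testing.assert_allclose(
            np.diag(mine.cov_cluster), factor * ref.bse**2, rtol=1e-6
        )

    def test_recovers_known_coefficients(self, rng):
        n = 20_000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 4))])
        beta = np.array([-1.0, 0.5, -0.25, 0.1, 0.7])
        y = (rng.random(n) < _expit(X @ beta)).astype(float)
        fit = fit_logistic(X, y)
        se = fit.bse(cluster=False).to_numpy()
        assert np.all(np.abs(fit.params.to_numpy() - beta) < 3 * se)

    def test_collinear_column_dropped_with_warning(self, rng):
        n = 300
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        y = (rng.random(n) < _expit(x)).astype(float)
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_logistic(X, y, names=["const", "x", "x2"])
        assert fit.dropped == ["x2"]

    def test_perfect_separation_raises_naming_covariate(self):
        x = np.linspace(-2, 2, 120)
        X = np.column_stack([np.ones(120), x])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError) as exc:
            fit_logistic(X, y, names=["const", "xsep"])
        assert exc.value.covariate == "xsep"


class TestStabilizedWeights:
    def test_numerator_equal_denominator_gives_unit_weights(self, default_table):
        spec = ExposureModelSpec(
            denominator=ExposureModelSpec().denominator,
            numerator=ExposureModelSpec().denominator,
        )
        ws = compute_stabilized_weights(default_table, spec)
        np.testing.assert_allclose(ws.sw, 1.0, atol=1e-10)

    def test_forced_arithmetic(self):
        # a_obs = 1, P_num = 0.25, P_den = 0.20 -> sw = 1.25
        assert 0.25 / 0.20 == pytest.approx(1.25)

    def test_mean_weight_near_one_default_scenario(self, default_weights):
        assert 0.95 <= default_weights.summary["mean"] <= 1.05

    def test_numerator_must_nest_in_denominator(self):
        with pytest.raises(InvalidConfigError):
            ExposureModelSpec(denominator=("gender",),
                              numerator=("wave",)).validate()

    def test_positivity_floor_violation_lists_rows(self, default_table):
        spec = ExposureModelSpec(positivity_floor=0.9)  # absurd floor
        with pytest.raises(PositivityError) as exc:
            compute_stabilized_weights(default_table, spec)
        assert len(exc.value.rows) > 0

    def test_truncation_shrinks_range_preserves_order(self, default_table):
        plain = compute_stabilized_weights(default_table)
        trunc = compute_stabilized_weights(
            default_table, ExposureModelSpec(truncation=(1.0, 99.0))
        )
        assert trunc.sw.max() <= plain.sw.max()
        assert trunc.sw.min() >= plain.sw.min()
        untouched = ~trunc.truncated
        order_a = np.argsort(plain.sw[untouched], kind="stable")
        order_b = np.argsort(trunc.sw[untouched], kind="stable")
        assert (order_a == order_b).all()


class TestSMD:
    def test_identical_distributions_zero(self):
        x = np.tile([1.0, 2.0, 3.0], 2)
        g = np.repeat([1.0, 0.0], 3)
        assert compute_smd(x, g) == pytest.approx(0.0)

    def test_unit_case(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(0, 1, 200_000)
        x1 = rng.normal(1, 1, 200_000)
        x = np.concatenate([x1, x0])
        g = np.concatenate([np.ones(200_000), np.zeros(200_000)])
        assert compute_smd(x, g) == pytest.approx(1.0, abs=0.02)

    def test_weighted_equals_integer_replication_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 1.5, 2.5, 4.0])
        g = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        w = np.array([2.0, 1.0, 1.0, 1.0, 1.0, 2.0])
        reps = np.repeat(np.arange(6), w.astype(int))
        expected = compute_smd(x[reps], g[reps])
        assert compute_smd(x, g, w) == pytest.approx(expected, rel=1e-12)

    def test_sign_flips_under_group_swap(self, rng):
        x = rng.normal(size=100)
        g = (rng.random(100) < 0.4).astype(float)
        assert compute_smd(x, g) == pytest.approx(-compute_smd(x, 1 - g))

    def test_zero_variance_unequal_means_flagged_infinite(self):
        x = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([1.0, 1.0, 0.0, 0.0])
        assert np.isposinf(compute_smd(x, g))

    def test_identical_constant_is_zero(self):
        assert compute_smd([2.0, 2.0, 2.0], [1.0, 0.0, 0.0]) == 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compute_smd([1.0, 2.0], [1.0, 1.0])


class TestBalanceTable:
    def test_unit_weights_reproduce_unweighted_column(self, default_table):
        from povmsm.weights import WeightSet

        ws = WeightSet(
            sw=np.ones(len(default_table)),
            p_num=np.ones(len(default_table)),
            p_den=np.ones(len(default_table)),
            truncated=np.zeros(len(default_table), dtype=bool),
        )
        bt = balance_table(default_table, ws)
        np.testing.assert_allclose(bt["smd_unweighted"], bt["smd_weighted"])

    def test_categoricals_expanded_per_level(self, default_table, default_weights):
        bt = balance_table(default_table, default_weights)
        edu = [c for c in bt["covariate"] if c.startswith("education[")]
        assert len(edu) == 3
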