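"""Effect estimation: standardization, PAF, bootstrap, transitions, strata."""

import numpy as np
import pandas as pd
import pytest

from povmsm.effects import (
    BootstrapConfig,
    OutcomeModelSpec,
    _pipeline_closure,
    _standardize,
    bootstrap_estimate,
    compute_paf,
    estimate_effect,
    estimate_stratified,
    estimate_transitions,
    resample_persons,
)
from povmsm.errors import InvalidConfigError
from povmsm.weights import ExposureModelSpec, LogitFit, compute_stabilized_weights


def _expit(x):
    return 1 / (1 + np.exp(-x))


class TestPaf:
    @pytest.mark.parametrize(
        "total,unexposed,expected",
        [(25.0, 20.0, 20.0), (20.0, 20.0, 0.0), (20.0, 21.0, -5.0)],
    )
    def test_arithmetic_including_protective(self, total, unexposed, expected):
        assert compute_paf(total, unexposed) == pytest.approx(expected)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(ValueError):
            compute_paf(0.0, 1.0)


def _fit_from(params: dict) -> LogitFit:
    names = list(params)
    return LogitFit(
        params=pd.Series(params), cov=np.eye(len(names)), cov_cluster=None,
        names=names, dropped=[], n_obs=0, n_iter=0, loglik=0.0,
    )


class TestStandardization:
    def test_zero_exposure_coefficient_gives_null_identities(self):
        X = pd.DataFrame({"const": [1.0] * 4, "poverty": [0, 1, 0, 1],
                          "z": [0.0, 1.0, 2.0, 3.0]})
        fit = _fit_from({"const": -1.0, "poverty": 0.0, "z": 0.3})
        m1, m0, mobs = _standardize(fit, X, "poverty", np.ones(4))
        assert m1 == pytest.approx(m0)
        rd, paf = 100 * (m1 - m0), compute_paf(100 * mobs, 100 * m0)
        assert rd == pytest.approx(0.0)
        assert paf == pytest.approx(0.0)

    def test_saturated_model_matches_contingency_table_oracle(self, rng):
        """8-cell fixture: saturated outcome model standardization equals
        the hand-computed sum_w P(Y|A=a,W=w) P(W=w) contrast."""
        n = 4000
        w = (rng.random(n) < 0.4).astype(float)
        a = (rng.random(n) < _expit(-0.5 + 1.2 * w)).astype(float)
        y = (rng.random(n) < _expit(-1.0 + 0.8 * a + 0.9 * w
                                    - 0.6 * a * w)).astype(float)
        df = pd.DataFrame(
            {"person_id": np.arange(n), "poverty": a, "w": w, "aw": a * w,
             "ghq_case": y}
        )
        # hand-computed standardization from the 2x2x2 contingency table
        expected = 0.0
        for wv in (0.0, 1.0):
            pw = (w == wv).mean()
            p1 = y[(a == 1) & (w == wv)].mean()
            p0 = y[(a == 0) & (w == wv)].mean()
            expected += (p1 - p0) * pw
        from povmsm.weights import WeightSet, fit_logistic
        from povmsm.design import build_design

        X = build_design(df, ["poverty", "w", "aw"])
        fit = fit_logistic(X, y)
        # saturated logistic: predictions equal cell frequencies; force the
        # interaction column to follow the exposure in the counterfactuals
        X1 = X.copy(); X1["poverty"] = 1.0; X1["aw"] = X["w"]
        X0 = X.copy(); X0["poverty"] = 0.0; X0["aw"] = 0.0
        m1 = fit.predict(X1).mean()
        m0 = fit.predict(X0).mean()
        assert 100 * (m1 - m0) == pytest.approx(100 * expected, abs=1e-6)


class TestEstimateEffect:
    def test_paf_identity_and_ci_bracketing(self, default_table, default_weights):
        est = estimate_effect(default_table, default_weights)
        assert est.paf == pytest.approx(
            100 * (est.prev_total - est.prev_unexposed) / est.prev_total
        )
        assert est.n_observations == len(default_table)

    def test_marginal_or_recorded(self, default_table, default_weights):
        est = estimate_effect(default_table, default_weights)
        assert "or_marginal" in est.metadata
        assert est.or_ > 0


class TestBootstrap:
    def test_resampling_preserves_person_blocks(self, default_table, rng):
        sample = resample_persons(default_table, rng)
        assert len(sample) > 0
        sizes_orig = default_table.groupby("person_id").size()
        # every resampled person's block size matches some original person
        sizes_new = sample.groupby("person_id").size()
        assert set(sizes_new.unique()) <= set(sizes_orig.unique())

    def test_deterministic_under_seed(self, default_table):
        closure = _pipeline_closure(
            ExposureModelSpec(), OutcomeModelSpec(), "binary", "overall"
        )
        cfg = BootstrapConfig(n_replicates=100, seed=5)
        a = bootstrap_estimate(default_table, closure, cfg)
        b = bootstrap_estimate(default_table, closure, cfg)
        assert a.ci["rd"] == b.ci["rd"]
        assert a.se["paf"] == b.se["paf"]

    def test_replicate_floor_enforced(self):
        with pytest.raises(InvalidConfigError):
            BootstrapConfig(n_replicates=50).validate()

    def test_bootstrap_se_matches_analytic_for_weighted_mean(self, rng):
        """Simple statistic sanity check: cluster bootstrap SE of a mean of
        independent rows is close to the analytic SE."""
        n = 2000
        vals = rng.normal(size=n)
        df = pd.DataFrame({"person_id": np.arange(n), "v": vals})
        from dataclasses import dataclass, field

        from povmsm.effects import EffectEstimate

        def stat(table):
            m = table["v"].mean()
            return EffectEstimate(
                rd=m, or_=1.0, prev_unexposed=50.0, prev_total=50.0, paf=0.0,
                n_individuals=len(table), n_observations=len(table),
            )

        est = bootstrap_estimate(df, stat, BootstrapConfig(n_replicates=400,
                                                           seed=2))
        analytic = vals.std(ddof=1) / np.sqrt(n)
        assert est.se["rd"] == pytest.approx(analytic, rel=0.15)


class TestTransitions:
    def test_no_one_ever_poor_outof_errors_into_runs(self):
        rng = np.random.default_rng(3)
        n = 600
        df = pd.DataFrame(
            {
                "person_id": np.repeat(np.arange(n // 2), 2),
                "poverty": (rng.random(n) < 0.3).astype(float),
                "poverty_lag": 0.0,
                "ghq_case": (rng.random(n) < 0.2).astype(float),
                "gender": (rng.random(n) < 0.5).astype(float),
                "wave": np.tile([2.0, 3.0], n // 2),
            }
        )
        e_spec = ExposureModelSpec(denominator=("gender", "wave"),
                                   numerator=("wave",))
        o_spec = OutcomeModelSpec(covariates=("gender", "wave"))
        with pytest.raises(ValueError):
            estimate_transitions(df, "outof", e_spec, o_spec)
        est = estimate_transitions(df, "into", e_spec, o_spec)
        assert est.estimand == "into"

    def test_transition_weights_recomputed_on_restricted_sample(
        self, default_table
    ):
        est = estimate_transitions(default_table, "into")
        assert est.n_observations == (default_table["poverty_lag"] == 0).sum()


class TestStratified:
    def test_age_boundary_assignment(self, default_table):
        ests = estimate_stratified(default_table, "age-group")
        younger = next(e for e in ests if "younger" in e.stratum)
        older = next(e for e in ests if "older" in e.stratum)
        n_younger = (default_table["age"] <= 40).sum()
        assert younger.n_observations == n_younger
        assert older.n_observations == len(default_table) - n_younger

    def test_gender_strata_cover_table(self, default_table):
        ests = estimate_stratified(default_table, "gender")
        assert sum(e.n_observations for e in ests) == len(default_table)
        assert {e.stratum for e in ests} == {"men", "women"}

    def test_unknown_stratifier_rejected(self, default_table):
        with pytest.raises(ValueError):
            estimate_stratified(default_table, "shoe-size")
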