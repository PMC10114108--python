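"""Double-robust effect estimation: risk differences, odds ratios, PAFs.

The estimator is a weighted outcome regression with g-computation
standardization: a pooled logistic model of the outcome on exposure plus the
full confounder adjustment set is fitted with stabilized IPT weights
(person-clustered), each row's outcome probability is predicted with the
exposure forced to 1 and to 0 (covariates at observed values), and the
weighted averages are contrasted. Consistency holds if either the weight
model or the outcome model is correctly specified.

Reported measures:

* rd              marginal risk difference in percentage points,
* or_             exposure-coefficient odds ratio (a conditional OR; the
                  marginal OR implied by the standardized prevalences is
                  also recorded in ``metadata``),
* prev_unexposed  standardized prevalence with exposure set to 0 (percent),
* prev_total      weighted model-predicted prevalence at observed exposure,
* paf             100 * (prev_total - prev_unexposed) / prev_total.

Uncertainty comes from a person-level (cluster) bootstrap re-running the
entire weighting + estimation pipeline per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .derive import derive_transitions
from .design import build_design
from .errors import InvalidConfigError
from .weights import (
    DEFAULT_ADJUSTMENT_SET,
    ExposureModelSpec,
    WeightSet,
    compute_stabilized_weights,
    fit_logistic,
)


@dataclass(frozen=True)
class OutcomeModelSpec:
    exposure: str = "poverty"
    outcome: str = "ghq_case"
    covariates: tuple[str, ...] = tuple(DEFAULT_ADJUSTMENT_SET)
    cluster: str = "person_id"


@dataclass
class EffectEstimate:
    rd: float                   # percentage points
    or_: float
    prev_unexposed: float       # percent
    prev_total: float           # percent
    paf: float                  # percent
    n_individuals: int
    n_observations: int
    estimand: str = "binary"
    stratum: str = "overall"
    se: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)   # name -> (lo, hi)
    metadata: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "estimand": self.estimand,
            "stratum": self.stratum,
            "rd": self.rd,
            "or": self.or_,
            "prev_unexposed": self.prev_unexposed,
            "prev_total": self.prev_total,
            "paf": self.paf,
            "n_individuals": self.n_individuals,
            "n_observations": self.n_observations,
        }
        for k in ("rd", "or", "prev_unexposed", "paf"):
            key = "or_" if k == "or" else k
            row[f"{k}_se"] = self.se.get(key, np.nan)
            lo, hi = self.ci.get(key, (np.nan, np.nan))
            row[f"{k}_ci_lo"], row[f"{k}_ci_hi"] = lo, hi
        return row


def compute_paf(prev_total: float, prev_unexposed: float) -> float:
    """Population attributable fraction, percent.

    100 * (prev_total - prev_unexposed) / prev_total; negative for a
    protective exposure.
    """
    if prev_total <= 0:
        raise ValueError("prev_total must be positive")
    return 100.0 * (prev_total - prev_unexposed) / prev_total


def _standardize(fit, X: pd.DataFrame, exposure: str, sw: np.ndarray):
    """G-computation contrast from a fitted outcome model."""
    Xn = X[fit.names].to_numpy(dtype=float)
    beta = fit.params.to_numpy()
    eta_obs = Xn @ beta
    if exposure in fit.names:
        j = fit.names.index(exposure)
        delta = (1.0 - Xn[:, j]) * beta[j]
        eta1 = eta_obs + delta
        eta0 = eta_obs - Xn[:, j] * beta[j]
    else:  # exposure dropped (degenerate designs): no contrast
        eta1 = eta0 = eta_obs
    expit = lambda e: 1.0 / (1.0 + np.exp(-np.clip(e, -500, 500)))  # noqa: E731
    wsum = sw.sum()
    mean1 = float((sw * expit(eta1)).sum() / wsum)
    mean0 = float((sw * expit(eta0)).sum() / wsum)
    mean_obs = float((sw * expit(eta_obs)).sum() / wsum)
    return mean1, mean0, mean_obs


def estimate_effect(
    analysis_table: pd.DataFrame,
    weight_set: WeightSet,
    spec: OutcomeModelSpec = OutcomeModelSpec(),
    estimand: str = "binary",
    stratum: str = "overall",
    cluster_covariance: bool = False,
) -> EffectEstimate:
    """Point estimates from the weighted adjusted model.

    Uncertainty comes from :func:`bootstrap_estimate`; with
    ``cluster_covariance=True`` the person-clustered sandwich SE of the
    log odds ratio is additionally recorded in ``se['log_or_analytic']``.
    """
    covs = [c for c in spec.covariates if c != spec.exposure]
    X = build_design(analysis_table, [spec.exposure] + covs)
    y = analysis_table[spec.outcome].to_numpy(dtype=float)
    clusters = analysis_table[spec.cluster].to_numpy() if cluster_covariance \
        else None
    fit = fit_logistic(X, y, sample_weight=weight_set.sw, clusters=clusters)

    mean1, mean0, mean_obs = _standardize(fit, X, spec.exposure, weight_set.sw)
    rd = 100.0 * (mean1 - mean0)
    prev_unexposed = 100.0 * mean0
    prev_total = 100.0 * mean_obs
    paf = compute_paf(prev_total, prev_unexposed)
    or_cond = float(np.exp(fit.params[spec.exposure])) \
        if spec.exposure in fit.params.index else np.nan
    or_marginal = (mean1 / (1 - mean1)) / (mean0 / (1 - mean0))

    est_se = {}
    if cluster_covariance and spec.exposure in fit.names and             fit.cov_cluster is not None:
        j = fit.names.index(spec.exposure)
        est_se["log_or_analytic"] = float(np.sqrt(fit.cov_cluster[j, j]))
    return EffectEstimate(
        rd=rd,
        or_=or_cond,
        se=est_se,
        prev_unexposed=prev_unexposed,
        prev_total=prev_total,
        paf=paf,
        n_individuals=int(analysis_table[spec.cluster].nunique()),
        n_observations=len(analysis_table),
        estimand=estimand,
        stratum=stratum,
        metadata={
            "or_marginal": float(or_marginal),
            "outcome_fit_dropped": fit.dropped,
            "weight_summary": weight_set.summary,
        },
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapConfig:
    n_replicates: int = 500
    seed: int = 0
    ci_method: str = "normal"     # "normal" | "percentile"
    max_failure_fraction: float = 0.10

    def validate(self) -> None:
        if self.n_replicates < 100:
            raise InvalidConfigError("n_replicates must be >= 100 for reported CIs")
        if self.ci_method not in ("normal", "percentile"):
            raise InvalidConfigError(f"unknown ci method {self.ci_method!r}")


_BOOT_FIELDS = ("rd", "or_", "prev_unexposed", "prev_total", "paf")


def resample_persons(
    table: pd.DataFrame, rng: np.random.Generator, cluster: str = "person_id"
) -> pd.DataFrame:
    """Resample persons (all their rows) with replacement, re-labelling ids."""
    ids = table[cluster].to_numpy()
    uniq, inv = np.unique(ids, return_inverse=True)
    order = np.argsort(inv, kind="stable")
    starts = np.searchsorted(inv[order], np.arange(len(uniq)))
    ends = np.append(starts[1:], len(order))
    draws = rng.integers(0, len(uniq), size=len(uniq))
    row_blocks = [order[starts[d]:ends[d]] for d in draws]
    rows = np.concatenate(row_blocks)
    new_ids = np.repeat(np.arange(len(draws)), [len(b) for b in row_blocks])
    out = table.iloc[rows].reset_index(drop=True)
    out[cluster] = new_ids
    return out


def bootstrap_estimate(
    analysis_table: pd.DataFrame,
    pipeline,
    config: BootstrapConfig = BootstrapConfig(),
    cluster: str = "person_id",
) -> EffectEstimate:
    """Cluster bootstrap of a weighting+estimation pipeline closure.

    ``pipeline(table) -> EffectEstimate`` is re-run on person-resampled
    tables; SEs are replicate standard deviations and CIs normal
    (point +- 1.96 se) or percentile. Failed replicates (separation etc.)
    are dropped and counted; more than ``max_failure_fraction`` failing is
    an error.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    point = pipeline(analysis_table)

    draws: dict[str, list[float]] = {k: [] for k in _BOOT_FIELDS}
    n_failed = 0
    for _ in range(config.n_replicates):
        sample = resample_persons(analysis_table, rng, cluster)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = pipeline(sample)
        except Exception:
            n_failed += 1
            continue
        for k in _BOOT_FIELDS:
            draws[k].append(getattr(est, k))
    if n_failed > config.max_failure_fraction * config.n_replicates:
        raise RuntimeError(
            f"{n_failed}/{config.n_replicates} bootstrap replicates failed"
        )

    out = replace(point)
    out.se = {}
    out.ci = {}
    for k in _BOOT_FIELDS:
        arr = np.asarray(draws[k], dtype=float)
        se = float(arr.std(ddof=1))
        out.se[k] = se
        if config.ci_method == "normal":
            centre = getattr(point, k)
            out.ci[k] = (centre - 1.96 * se, centre + 1.96 * se)
        else:
            out.ci[k] = tuple(np.percentile(arr, [2.5, 97.5]))
    out.metadata = dict(point.metadata)
    out.metadata["bootstrap"] = {
        "n_replicates": config.n_replicates,
        "n_failed": n_failed,
        "ci_method": config.ci_method,
    }
    return out


# ---------------------------------------------------------------------------
# transition and stratified estimands
# ---------------------------------------------------------------------------


def _pipeline_closure(exposure_spec, outcome_spec, estimand, stratum):
    def run(table: pd.DataFrame) -> EffectEstimate:
        ws = compute_stabilized_weights(
            table, exposure_spec, exposure=outcome_spec.exposure,
            cluster=outcome_spec.cluster,
        )
        return estimate_effect(table, ws, outcome_spec, estimand, stratum)
    return run


def estimate_transitions(
    analysis_table: pd.DataFrame,
    estimand: str,
    exposure_spec: ExposureModelSpec = ExposureModelSpec(),
    outcome_spec: OutcomeModelSpec = OutcomeModelSpec(),
    bootstrap: BootstrapConfig | None = None,
) -> EffectEstimate:
    """Transition-specific effect (into or out of poverty).

    Restricts to the at-risk reference population, recodes the exposure,
    and recomputes IPTWs on the restricted sample. ``poverty_lag`` is
    constant there and is dropped from both weight models automatically.
    """
    sub = derive_transitions(analysis_table, estimand)
    if len(sub) == 0:
        raise ValueError(f"empty restricted table for estimand {estimand!r}")
    # poverty_lag is constant within the restricted reference population
    exposure_spec = replace(
        exposure_spec,
        denominator=tuple(c for c in exposure_spec.denominator
                          if c != "poverty_lag"),
        numerator=tuple(c for c in exposure_spec.numerator
                        if c != "poverty_lag"),
    )
    o_spec = replace(
        outcome_spec,
        exposure="exposure",
        covariates=tuple(c for c in outcome_spec.covariates
                         if c != "poverty_lag"),
    )
    closure = _pipeline_closure(exposure_spec, o_spec, estimand, "overall")
    if bootstrap is None:
        return closure(sub)
    return bootstrap_estimate(sub, closure, bootstrap, o_spec.cluster)


STRATIFIERS = {
    "gender": [("men", lambda t: t["gender"] == 0),
               ("women", lambda t: t["gender"] == 1)],
    "education": [("low education", lambda t: t["education"] == 0),
                  ("medium education", lambda t: t["education"] == 1),
                  ("high education", lambda t: t["education"] == 2)],
    "age-group": [("younger working-age", lambda t: t["age"] <= 40),
                  ("older working-age", lambda t: t["age"] > 40)],
}


def estimate_stratified(
    analysis_table: pd.DataFrame,
    stratifier: str,
    estimand: str = "binary",
    exposure_spec: ExposureModelSpec = ExposureModelSpec(),
    outcome_spec: OutcomeModelSpec = OutcomeModelSpec(),
    bootstrap: BootstrapConfig | None = None,
) -> list[EffectEstimate]:
    """One effect per stratum, with weights refit within stratum.

    The stratifier is removed from both the weight and outcome covariate
    sets for that run; age-group membership is assigned per row at time t
    (younger 25-40, older 41-64). A stratum whose estimation fails (e.g. a
    single exposure level) is reported as an error entry in the returned
    list's metadata while other strata proceed.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    drop = {"gender": ["gender"], "education": ["education"], "age-group": []}
    e_spec = replace(
        exposure_spec,
        denominator=tuple(c for c in exposure_spec.denominator
                          if c not in drop[stratifier]),
        numerator=tuple(c for c in exposure_spec.numerator
                        if c not in drop[stratifier]),
    )
    o_spec = replace(
        outcome_spec,
        covariates=tuple(c for c in outcome_spec.covariates
                         if c not in drop[stratifier]),
    )
    results: list[EffectEstimate] = []
    for label, mask_fn in STRATIFIERS[stratifier]:
        sub = analysis_table[mask_fn(analysis_table)].reset_index(drop=True)
        closure = _pipeline_closure(e_spec, o_spec, estimand, label)
        try:
            if estimand in ("into", "outof"):
                est = estimate_transitions(sub, estimand, e_spec, o_spec, bootstrap)
                est.stratum = label
            elif bootstrap is None:
                est = closure(sub)
            else:
                est = bootstrap_estimate(sub, closure, bootstrap,
                                         o_spec.cluster)
        except Exception as exc:  # single-level stratum etc.
            est = EffectEstimate(
                rd=np.nan, or_=np.nan, prev_unexposed=np.nan,
                prev_total=np.nan, paf=np.nan, n_individuals=0,
                n_observations=len(sub), estimand=estimand, stratum=label,
                metadata={"error": f"{type(exc).__name__}: {exc}"},
            )
        results.append(est)
    return results


def crude_estimate(
    analysis_table: pd.DataFrame,
    exposure: str = "poverty",
    outcome: str = "ghq_case",
) -> float:
    """Unadjusted, unweighted risk difference in percentage points."""
    a = analysis_table[exposure].to_numpy(dtype=float)
    y = analysis_table[outcome].to_numpy(dtype=float)
    return 100.0 * (y[a == 1].mean() - y[a == 0].mean())
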