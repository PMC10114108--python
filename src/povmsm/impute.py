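"""Multiple imputation by chained equations and Rubin's-rules pooling.

Chained-equations imputation with plain regression draws (no predictive-mean
matching): continuous variables by Bayesian linear regression (posterior
sigma and beta draws plus residual noise), binary variables by logistic
regression with an approximate posterior beta draw and a Bernoulli draw,
ordinal variables by sequential threshold logits. Variables cycle in fixed
order of ascending missingness fraction for a fixed number of iterations,
with a per-variable convergence trace (mean of imputed cells by iteration).

Income-type variables are log-transformed before imputation and
back-transformed after; binary exposure and outcome indicators are
re-derived (dichotomized) from their imputed continuous sources downstream.

Pooling follows Rubin's rules: point = mean of per-dataset estimates,
total variance = within + (1 + 1/m) * between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .weights import fit_logistic

# 22 variables counted for the high-missingness exclusion rule: the 16 raw
# person-wave analysis variables plus the six previous-wave values that the
# lagged adjustment set needs.
ANALYSIS_VARIABLES: tuple[str, ...] = (
    "income", "housing_costs", "n_adults", "n_children", "gender",
    "ethnicity", "education", "employment", "benefits", "tenure", "marital",
    "region", "age", "sf12_pcs", "sf12_mcs", "ghq_case",
    "employment_lag", "benefits_lag", "tenure_lag", "marital_lag",
    "sf12_mcs_lag", "ghq_case_lag",
)

BINARY_VARIABLES = {
    "gender", "ethnicity", "employment", "benefits", "tenure", "marital",
    "ghq_case", "poverty",
}
ORDINAL_VARIABLES = {"education": 3, "region": 4}
COUNT_VARIABLES = {"n_children": (0, 8), "ghq_score": (0, 12)}


@dataclass(frozen=True)
class ImputationSpec:
    m: int = 20
    max_iterations: int = 10
    high_missingness_threshold: int = 9
    analysis_variables: tuple[str, ...] = ANALYSIS_VARIABLES
    predictors: dict | None = None          # variable -> list of predictors
    log_transform: tuple[str, ...] = ("income", "housing_costs")
    interactions: tuple[tuple[str, str], ...] = ()
    variable_models: dict | None = None     # variable -> family override
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise InvalidConfigError("m must be >= 2")
        if not 1 <= self.high_missingness_threshold <= len(self.analysis_variables):
            raise InvalidConfigError(
                "high_missingness_threshold must be in [1, n analysis variables]"
            )


@dataclass
class ImputationStack:
    datasets: list[pd.DataFrame]
    trace: pd.DataFrame                 # dataset, iteration, variable, mean
    exclusion_log: pd.DataFrame

    @property
    def m(self) -> int:
        return len(self.datasets)


@dataclass(frozen=True)
class PooledEstimate:
    point: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    ci: tuple[float, float]
    m: int


# ---------------------------------------------------------------------------
# exclusion
# ---------------------------------------------------------------------------


def _with_lag_columns(panel: pd.DataFrame, variables) -> pd.DataFrame:
    """Attach any `<var>_lag` columns named in ``variables`` that are absent,
    using the previous consecutive wave of the same person (else NaN)."""
    lag_needed = [v for v in variables if v.endswith("_lag")
                  and v not in panel.columns
                  and v.removesuffix("_lag") in panel.columns]
    if not lag_needed:
        return panel
    cur = panel.sort_values(["person_id", "wave"], kind="stable")
    bases = [v.removesuffix("_lag") for v in lag_needed]
    prev = cur[["person_id", "wave"] + bases].copy()
    prev["wave"] = prev["wave"] + 1
    prev = prev.rename(columns={b: f"{b}_lag" for b in bases})
    return panel.merge(prev, on=["person_id", "wave"], how="left")


def exclude_high_missingness(
    panel: pd.DataFrame, spec: ImputationSpec = ImputationSpec()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows missing strictly more than the threshold count of analysis
    variables; returns (kept panel, exclusion log)."""
    spec.validate()
    counted = _with_lag_columns(panel, spec.analysis_variables)
    cols = [v for v in spec.analysis_variables if v in counted.columns]
    n_missing = counted[cols].isna().sum(axis=1)
    drop = n_missing > spec.high_missingness_threshold
    log = pd.DataFrame(
        {
            "person_id": panel.loc[drop.to_numpy(), "person_id"],
            "wave": panel.loc[drop.to_numpy(), "wave"],
            "n_missing": n_missing[drop.to_numpy()],
            "reason": f"missing > {spec.high_missingness_threshold} of {len(cols)}",
        }
    ).reset_index(drop=True)
    kept = panel.loc[~drop.to_numpy()].reset_index(drop=True)
    return kept, log


# ---------------------------------------------------------------------------
# chained equations
# ---------------------------------------------------------------------------


def _family_for(var: str, spec: ImputationSpec) -> str:
    if spec.variable_models and var in spec.variable_models:
        return spec.variable_models[var]
    if var in BINARY_VARIABLES:
        return "binary"
    if var in ORDINAL_VARIABLES:
        return "ordinal"
    if var in COUNT_VARIABLES:
        return "count"
    return "continuous"


def _predictor_matrix(df, predictors, spec, skip):
    cols = [np.ones(len(df))]
    names = ["const"]
    for p in predictors:
        if p == skip:
            continue
        v = df[p].to_numpy(dtype=float)
        if p in spec.log_transform:
            v = np.log(np.maximum(v, 1e-6))
        cols.append(v)
        names.append(p)
    for a, b in spec.interactions:
        if skip in (a, b) or a not in predictors or b not in predictors:
            continue
        va = df[a].to_numpy(dtype=float)
        vb = df[b].to_numpy(dtype=float)
        if a in spec.log_transform:
            va = np.log(np.maximum(va, 1e-6))
        if b in spec.log_transform:
            vb = np.log(np.maximum(vb, 1e-6))
        cols.append(va * vb)
        names.append(f"{a}:{b}")
    return np.column_stack(cols), names


def _draw_continuous(rng, X_obs, y_obs, X_mis):
    """Bayesian linear-regression draw (normal-inverse-chi2 posterior)."""
    n, k = X_obs.shape
    XtX = X_obs.T @ X_obs + 1e-8 * np.eye(k)
    beta_hat = np.linalg.solve(XtX, X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    df_ = max(n - k, 1)
    s2 = float(resid @ resid) / df_
    sigma2 = s2 * df_ / rng.chisquare(df_)
    cov = sigma2 * np.linalg.inv(XtX)
    beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return X_mis @ beta + rng.normal(0.0, np.sqrt(sigma2), size=len(X_mis))


def _draw_binary(rng, X_obs, y_obs, X_mis):
    """Logistic draw with approximate posterior perturbation of beta."""
    try:
        fit = fit_logistic(X_obs, y_obs)
    except Exception:
        p = np.full(len(X_mis), max(min(y_obs.mean(), 1 - 1e-6), 1e-6))
        return (rng.random(len(X_mis)) < p).astype(float)
    kept = [int(n[1:]) if n.startswith("x") else 0 for n in fit.names]
    beta = rng.multivariate_normal(
        fit.params.to_numpy(), fit.cov, method="cholesky"
    )
    eta = X_mis[:, kept] @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    return (rng.random(len(X_mis)) < p).astype(float)


def mice_impute(
    panel: pd.DataFrame, spec: ImputationSpec = ImputationSpec()
) -> ImputationStack:
    """Chained-equations imputation; returns m completed panels plus trace.

    Observed cells are identical across datasets; every dataset is complete
    in the imputed variable set. A variable with missing cells but no
    usable predictors raises ``InvalidConfigError``.
    """
    spec.validate()
    rng_master = np.random.default_rng(spec.seed)

    id_cols = {"person_id", "household_id", "wave"}
    targets = [c for c in panel.columns
               if c not in id_cols and panel[c].isna().any()]
    frac = {v: panel[v].isna().mean() for v in targets}
    order = sorted(targets, key=lambda v: (frac[v], v))

    default_predictors = [
        c for c in panel.columns
        if c not in id_cols and c != "poverty_line" and not panel[c].isna().any()
    ]
    pred_map = {}
    for v in order:
        if spec.predictors and v in spec.predictors:
            pred_map[v] = list(spec.predictors[v])
        else:
            others = [c for c in targets if c != v]
            # ghq_score and ghq_case are the same instrument; never predict
            # one from the other
            pair = {"ghq_score": "ghq_case", "ghq_case": "ghq_score"}
            others = [c for c in others if pair.get(v) != c]
            pred_map[v] = default_predictors + others
        if not pred_map[v]:
            raise InvalidConfigError(f"no predictors available for {v!r}")

    datasets = []
    trace_rows = []
    for d in range(spec.m):
        rng = np.random.default_rng(rng_master.integers(0, 2**31 - 1))
        df = panel.copy()
        # initial fill: random draws from observed values
        for v in order:
            miss = df[v].isna()
            obs = df.loc[~miss, v].to_numpy()
            df.loc[miss, v] = rng.choice(obs, size=int(miss.sum()))

        miss_mask = {v: panel[v].isna().to_numpy() for v in order}
        for it in range(spec.max_iterations):
            for v in order:
                miss = miss_mask[v]
                if not miss.any():
                    continue
                X, _ = _predictor_matrix(df, pred_map[v], spec, skip=v)
                y = df[v].to_numpy(dtype=float)
                fam = _family_for(v, spec)
                X_obs, X_mis = X[~miss], X[miss]
                if fam == "continuous":
                    y_fit = y[~miss]
                    if v in spec.log_transform:
                        y_fit = np.log(np.maximum(y_fit, 1e-6))
                    draw = _draw_continuous(rng, X_obs, y_fit, X_mis)
                    if v in spec.log_transform:
                        draw = np.exp(draw)
                elif fam == "binary":
                    draw = _draw_binary(rng, X_obs, y[~miss], X_mis)
                elif fam == "count":
                    lo, hi = COUNT_VARIABLES.get(v, (0, None))
                    draw = np.rint(_draw_continuous(rng, X_obs, y[~miss], X_mis))
                    draw = np.clip(draw, lo, hi)
                elif fam == "ordinal":
                    n_levels = ORDINAL_VARIABLES.get(v, int(np.nanmax(y)) + 1)
                    # sequential threshold logits P(y >= k)
                    p_ge = np.ones((int(miss.sum()), n_levels))
                    for k in range(1, n_levels):
                        yk = (y[~miss] >= k).astype(float)
                        if yk.min() == yk.max():
                            p_ge[:, k] = yk.mean()
                            continue
                        try:
                            fitk = fit_logistic(X_obs, yk)
                            p_ge[:, k] = _predict_sub(fitk, X_mis)
                        except Exception:
                            p_ge[:, k] = yk.mean()
                    p_ge = np.minimum.accumulate(p_ge, axis=1)
                    u = rng.random(int(miss.sum()))
                    draw = (u[:, None] < p_ge[:, 1:]).sum(axis=1).astype(float)
                else:
                    raise InvalidConfigError(f"unknown family {fam!r} for {v!r}")
                vals = df[v].to_numpy(dtype=float)
                vals[miss] = draw
                df[v] = vals
                trace_rows.append(
                    {"dataset": d, "iteration": it, "variable": v,
                     "mean_imputed": float(np.mean(draw))}
                )
        datasets.append(df)

    trace = pd.DataFrame(trace_rows)
    return ImputationStack(datasets=datasets, trace=trace,
                           exclusion_log=pd.DataFrame())


def _predict_sub(fit, X_full):
    """Predict from a fit whose columns may have been collinearity-dropped.

    ``X_full`` columns are positional (const first) matching the design the
    fit was built from; dropped columns are skipped by name index.
    """
    # fit.names are the kept subset of the original positional names x0..xk
    idx = []
    for n in fit.names:
        idx.append(0 if n == "const" else int(n[1:]))
    return fit.predict(X_full[:, idx])


# ---------------------------------------------------------------------------
# Rubin pooling
# ---------------------------------------------------------------------------


def pool_rubin(estimates, variances) -> PooledEstimate:
    """Combine per-dataset estimates by Rubin's rules."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if len(q) != len(u):
        raise ValueError("estimates and variances must have equal length")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 datasets")
    point = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1.0 + 1.0 / m) * between
    se = float(np.sqrt(total))
    return PooledEstimate(
        point=point,
        within_var=within,
        between_var=between,
        total_var=total,
        se=se,
        ci=(point - 1.96 * se, point + 1.96 * se),
        m=m,
    )
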