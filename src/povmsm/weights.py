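"""Exposure modelling, stabilized IPT weights, and balance diagnostics.

The stabilized weight for a row is

    sw = P_num(A_t = a_obs | A_{t-1}, wave) / P_den(A_t = a_obs | W),

with the denominator model containing the full confounder adjustment set and
the numerator only prior exposure and the wave marker, so the marginal time
trend in the exposure stays in the numerator. Weights are per-observation
(single-wave), not cumulative products over waves: the target estimand is the
short-term effect of current poverty conditional on the previous year's
exposure status, and past exposure/outcome are regression-adjusted, so
cumulative weighting is not implied.

Logistic fits use a dedicated Newton/IRLS solver with model-based and
cluster-robust (person-level sandwich) covariances; collinear columns are
dropped with a log, and perfect separation raises an error naming the
offending covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import build_design
from .errors import InvalidConfigError, PositivityError, SeparationError

# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


@dataclass
class LogitFit:
    params: pd.Series
    cov: np.ndarray                 # model-based (inverse Fisher information)
    cov_cluster: np.ndarray | None  # person-clustered sandwich
    names: list[str]
    dropped: list[str]
    n_obs: int
    n_iter: int
    loglik: float

    def bse(self, cluster: bool = True) -> pd.Series:
        cov = self.cov_cluster if (cluster and self.cov_cluster is not None) \
            else self.cov
        return pd.Series(np.sqrt(np.diag(cov)), index=self.names)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.names].to_numpy(dtype=float)
        return _expit(X @ self.params.to_numpy())


#: tiny L2 stabilizer; negligible for identified coefficients (shift
#: O(1e-8)) but keeps quasi-separated fits finite and convergent
_RIDGE = 1e-8


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _drop_collinear(X: np.ndarray, names: list[str], tol: float = 1e-9):
    """Return indices of a maximal linearly independent column subset."""
    # fast path: full-rank design (the common case)
    scale = np.sqrt((X * X).sum(axis=0))
    if np.all(scale > tol):
        r = np.linalg.qr(X / scale, mode="r")
        if np.min(np.abs(np.diag(r))) > 1e-7:
            return list(range(X.shape[1]))
    keep: list[int] = []
    # greedy Gram-Schmidt style rank check, keeps earlier columns first
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j]
        norm = np.linalg.norm(col)
        if norm < tol:
            continue
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col
        if np.linalg.norm(resid) > tol * max(1.0, norm):
            keep.append(j)
            basis = np.column_stack([basis, resid / np.linalg.norm(resid)])
    return keep


def fit_logistic(
    X,
    y,
    sample_weight=None,
    clusters=None,
    names: list[str] | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> LogitFit:
    """Weighted maximum-likelihood logistic regression (Newton/IRLS).

    ``sample_weight`` are frequency-type weights (e.g. stabilized IPTWs);
    ``clusters`` are group labels for the sandwich covariance. Collinear
    columns are dropped with a warning; separation raises
    :class:`SeparationError`.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)

    keep = _drop_collinear(X, names)
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(f"dropping collinear/constant columns: {dropped}")
    X = X[:, keep]
    kept_names = [names[j] for j in keep]

    beta = np.zeros(X.shape[1])
    if kept_names and kept_names[0] == "const":
        p0 = min(max(float(np.average(y, weights=w)), 1e-6), 1 - 1e-6)
        beta[0] = np.log(p0 / (1 - p0))

    def _ll(b):
        eta = X @ b
        # stable log-likelihood: -sum w*log(1+exp(-(2y-1)*eta)) - ridge
        z = (2.0 * y - 1.0) * eta
        return -float(np.sum(w * np.logaddexp(0.0, -z))) \
            - 0.5 * _RIDGE * float(b @ b)

    ll = _ll(beta)
    n_iter = 0
    grad_scale = max(1.0, float(np.abs(w).sum()) / len(w))
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        p = _expit(eta)
        mu_w = w * p * (1.0 - p)
        grad = X.T @ (w * (y - p)) - _RIDGE * beta
        if np.max(np.abs(grad)) < tol * grad_scale:
            break
        # ridge keeps the Hessian invertible and the optimum finite even
        # under quasi-separation (rare indicator levels with no events)
        H = (X * mu_w[:, None]).T @ X + _RIDGE * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        # step-halving line search on the penalized log-likelihood
        for _ in range(30):
            ll_new = _ll(beta + step)
            if ll_new >= ll - 1e-13 * abs(ll):
                break
            step *= 0.5
        beta = beta + step
        if abs(ll_new - ll) < 1e-12 * (1.0 + abs(ll)):
            ll = ll_new
            break
        ll = ll_new

    eta = X @ beta
    # complete separation: the linear predictor perfectly classifies y
    if (y == 1).any() and (y == 0).any():
        if float(eta[y == 1].min()) > float(eta[y == 0].max()):
            worst = kept_names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(worst)

    p = _expit(eta)
    mu_w = w * p * (1.0 - p)
    H = (X * mu_w[:, None]).T @ X + _RIDGE * np.eye(X.shape[1])
    cov = np.linalg.inv(H)
    with np.errstate(divide="ignore"):
        loglik = float(np.sum(w * (y * np.log(np.maximum(p, 1e-300))
                                   + (1 - y) * np.log(np.maximum(1 - p, 1e-300)))))

    cov_cluster = None
    if clusters is not None:
        score = X * (w * (y - p))[:, None]
        groups = pd.factorize(np.asarray(clusters))[0]
        n_g = groups.max() + 1
        S = np.zeros((n_g, X.shape[1]))
        np.add.at(S, groups, score)
        meat = S.T @ S
        adj = n_g / max(n_g - 1, 1)
        cov_cluster = adj * cov @ meat @ cov

    return LogitFit(
        params=pd.Series(beta, index=kept_names),
        cov=cov,
        cov_cluster=cov_cluster,
        names=kept_names,
        dropped=dropped,
        n_obs=len(y),
        n_iter=n_iter,
        loglik=loglik,
    )


# ---------------------------------------------------------------------------
# adjustment sets and weight construction
# ---------------------------------------------------------------------------

#: full confounder adjustment set used by both the exposure (denominator) and
#: outcome models: time-invariant confounders, lagged time-varying
#: confounders, employment at t and t-1, prior exposure/outcome/MCS,
#: age + age^2 and the wave marker
DEFAULT_ADJUSTMENT_SET = [
    "gender", "ethnicity", "education",
    "employment", "employment_lag",
    "benefits_lag", "tenure_lag", "marital_lag", "n_children_lag",
    "region_lag", "sf12_pcs_lag", "sf12_mcs_lag",
    "poverty_lag", "ghq_case_lag",
    "age_c", "age_c2", "wave",
]

#: wave-only (marginal-within-wave) numerator: keeps the exposure time trend
#: in the numerator while letting the weights balance *all* adjusted
#: covariates marginally, including prior poverty and prior caseness.  A
#: P(A_t | A_{t-1}, wave) numerator is also supported but deliberately leaves
#: the lagged-exposure dependence in the pseudo-population, so lagged
#: covariates would not show marginal balance.
DEFAULT_NUMERATOR = ["wave"]


@dataclass(frozen=True)
class ExposureModelSpec:
    denominator: tuple[str, ...] = tuple(DEFAULT_ADJUSTMENT_SET)
    numerator: tuple[str, ...] = tuple(DEFAULT_NUMERATOR)
    truncation: tuple[float, float] | None = None  # percentile pair, e.g. (1, 99)
    positivity_floor: float = 1e-6

    def validate(self) -> None:
        if not set(self.numerator) <= set(self.denominator):
            raise InvalidConfigError("numerator covariates must be a subset "
                                     "of denominator covariates")
        if self.truncation is not None:
            lo, hi = self.truncation
            if not 0 <= lo < hi <= 100:
                raise InvalidConfigError("truncation percentiles must satisfy "
                                         "0 <= lo < hi <= 100")


@dataclass
class WeightSet:
    sw: np.ndarray
    p_num: np.ndarray          # fitted numerator P(A=a_obs)
    p_den: np.ndarray          # fitted denominator P(A=a_obs)
    truncated: np.ndarray      # bool flags
    summary: dict = field(default_factory=dict)
    denominator_fit: LogitFit | None = None
    numerator_fit: LogitFit | None = None


def compute_stabilized_weights(
    analysis_table: pd.DataFrame,
    spec: ExposureModelSpec = ExposureModelSpec(),
    exposure: str = "poverty",
    cluster: str = "person_id",
) -> WeightSet:
    """Fit numerator/denominator exposure models and form stabilized weights."""
    spec.validate()
    a = analysis_table[exposure].to_numpy(dtype=float)
    clusters = analysis_table[cluster].to_numpy()

    X_den = build_design(analysis_table, list(spec.denominator))
    X_num = build_design(analysis_table, list(spec.numerator))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns in restricted tables
        # cluster-robust covariances are not needed for weight construction
        den_fit = fit_logistic(X_den, a)
        num_fit = fit_logistic(X_num, a)

    p_den1 = den_fit.predict(X_den)
    p_num1 = num_fit.predict(X_num)
    p_den = np.where(a > 0, p_den1, 1.0 - p_den1)
    p_num = np.where(a > 0, p_num1, 1.0 - p_num1)

    bad = p_den < spec.positivity_floor
    if bad.any():
        raise PositivityError(np.nonzero(bad)[0], spec.positivity_floor)

    sw = p_num / p_den
    truncated = np.zeros(len(sw), dtype=bool)
    if spec.truncation is not None:
        lo, hi = np.percentile(sw, spec.truncation)
        truncated = (sw < lo) | (sw > hi)
        sw = np.clip(sw, lo, hi)

    summary = {
        "mean": float(sw.mean()),
        "sd": float(sw.std(ddof=1)) if len(sw) > 1 else 0.0,
        "min": float(sw.min()),
        "max": float(sw.max()),
        "p01": float(np.percentile(sw, 1)),
        "p99": float(np.percentile(sw, 99)),
        "n_truncated": int(truncated.sum()),
    }
    if not 0.9 <= summary["mean"] <= 1.1:
        warnings.warn(
            f"mean stabilized weight {summary['mean']:.3f} outside [0.9, 1.1]"
        )
    return WeightSet(sw=sw, p_num=p_num, p_den=p_den, truncated=truncated,
                     summary=summary, denominator_fit=den_fit,
                     numerator_fit=num_fit)


# ---------------------------------------------------------------------------
# balance diagnostics
# ---------------------------------------------------------------------------


def compute_smd(values, groups, weights=None) -> float:
    """Standardized mean difference (group 1 minus group 0).

    (m1 - m0) / sqrt((v1 + v0) / 2) with weighted means and *population*
    (ddof=0) weighted variances, so integer weights reproduce row
    replication exactly. Binary covariates are 0/1 numerics. Zero pooled
    variance yields signed infinity when means differ, else 0.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups, dtype=float)
    w = np.ones(len(x)) if weights is None else np.asarray(weights, dtype=float)
    if not (g == 1).any() or not (g == 0).any():
        raise ValueError("both exposure groups must be non-empty")
    stats = []
    for lvl in (1.0, 0.0):
        m = g == lvl
        wm = w[m]
        mean = np.average(x[m], weights=wm)
        var = np.average((x[m] - mean) ** 2, weights=wm)
        stats.append((mean, var))
    (m1, v1), (m0, v0) = stats
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0.0:
        return 0.0 if m1 == m0 else float(np.sign(m1 - m0) * np.inf)
    return float((m1 - m0) / pooled)


def balance_table(
    analysis_table: pd.DataFrame,
    weight_set: WeightSet | None,
    covariates: list[str] | None = None,
    exposure: str = "poverty",
) -> pd.DataFrame:
    """Per-covariate unweighted and weighted SMDs with 0.1/0.2 flags.

    Categorical covariates are expanded to one indicator per level (all
    levels, no reference dropping — balance is assessed level by level).
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_ADJUSTMENT_SET if c != "wave"]
    g = analysis_table[exposure].to_numpy(dtype=float)
    w = None if weight_set is None else weight_set.sw

    rows = []
    for cov in covariates:
        base = cov.removesuffix("_lag")
        if base in ("education", "region", "wave"):
            vals = analysis_table[cov].to_numpy()
            for lvl in np.unique(vals):
                x = (vals == lvl).astype(float)
                rows.append((f"{cov}[{lvl}]", x))
        else:
            rows.append((cov, analysis_table[cov].to_numpy(dtype=float)))

    out = []
    for name, x in rows:
        smd_u = compute_smd(x, g)
        smd_w = compute_smd(x, g, w) if w is not None else smd_u
        out.append(
            {
                "covariate": name,
                "smd_unweighted": smd_u,
                "smd_weighted": smd_w,
                "flag_0.1": abs(smd_w) >= 0.1,
                "flag_0.2": abs(smd_w) >= 0.2,
            }
        )
    return pd.DataFrame(out)


def love_plot(balance: pd.DataFrame, path) -> None:
    """Dot plot of SMDs before/after weighting (saved to ``path``)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    b = balance.iloc[::-1]
    fig, ax = plt.subplots(figsize=(7, 0.32 * len(b) + 1.5))
    ypos = np.arange(len(b))
    ax.scatter(b["smd_unweighted"].abs(), ypos, marker="o", facecolors="none",
               edgecolors="tab:red", label="unweighted")
    ax.scatter(b["smd_weighted"].abs(), ypos, marker="o", color="tab:blue",
               label="weighted")
    ax.axvline(0.1, ls=":", color="grey")
    ax.axvline(0.2, ls="--", color="grey")
    ax.set_yticks(ypos, b["covariate"])
    ax.set_xlabel("|standardized mean difference|")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
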