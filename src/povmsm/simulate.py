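"""Synthetic household-panel generator with counterfactual oracle truth.

Emulates an annual UK-style household panel: a binary after-housing-costs
poverty exposure derived from equivalized household income (<60% of the
contemporaneous median), a binary common-mental-disorder (CMD) outcome from a
GHQ-12-style screening score (caseness at >=4), time-invariant confounders
(gender, ethnicity, education), time-varying confounders (employment,
benefits, tenure, marital status, children, SF-12 physical and mental
component scores, age), exposure-outcome feedback (health selection: prior
CMD depresses income), monotone attrition, and missing-at-random item
missingness.

The generative equations use *only* variables in the analysis adjustment set
(time-invariant confounders; time-varying confounders at t-1; employment at t
and t-1; prior poverty, prior caseness and prior SF-12 MCS; age, age^2), so
the adjustment set is sufficient by construction and both the exposure and
outcome working models can be correctly specified. Log equivalized income
receives additive logistic noise, which makes the implied poverty propensity
logistic in the adjustment set whenever the autoregressive income deviation
is switched off (``IncomeParams.ar1 = 0``).

Oracle effects are computed by forcing the current-wave exposure to 1 and 0
with all earlier history at its natural values, and averaging the implied
outcome-probability difference (a Rao-Blackwellized counterfactual contrast).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfounderEffect:
    """Coefficients of one confounder on the (log-)income and CMD equations."""

    on_income: float
    on_cmd: float


def default_confounder_effects() -> dict[str, ConfounderEffect]:
    """Calibrated default coefficients; see docs/methods.md for rationale.

    Continuous confounders are scaled: SF-12 scores per 10 points above 50,
    age per decade above 45.
    """
    return {
        "gender": ConfounderEffect(-0.06, 0.30),        # female
        "ethnicity": ConfounderEffect(-0.08, 0.08),     # minority ethnicity
        "education": ConfounderEffect(0.15, -0.10),     # per ordinal level
        "employment": ConfounderEffect(0.40, -0.25),    # current wave
        "employment_lag": ConfounderEffect(0.10, -0.10),
        "benefits": ConfounderEffect(-0.22, 0.22),      # lagged
        "tenure": ConfounderEffect(0.12, -0.12),        # lagged, owner
        "marital": ConfounderEffect(0.08, -0.18),       # lagged, coupled
        "children": ConfounderEffect(-0.05, 0.06),      # lagged, per child
        "physical_health": ConfounderEffect(0.05, -0.25),  # lagged PCS /10
        "mental_health": ConfounderEffect(0.03, -0.45),    # lagged MCS /10
        "age": ConfounderEffect(0.05, -0.05),           # per decade
        "age2": ConfounderEffect(-0.02, 0.03),          # per decade^2
    }


@dataclass(frozen=True)
class IncomeParams:
    """Log equivalized after-housing-costs income model.

    log-income = location + confounder terms + poverty_persistence * A_{t-1}
                 - selection_effect * Y_{t-1} + u_t + logistic noise,
    with u_t = ar1 * u_{t-1} an optional latent AR(1) deviation.
    """

    log_mean: float = 7.10          # location, log GBP/month equivalized AHC
    noise_scale: float = 0.27       # scale of the logistic innovation
    ar1: float = 0.25               # persistence of the latent deviation
    housing_fraction: float = 0.25  # mean housing-cost share of gross income
    poverty_persistence: float = -0.30  # A_{t-1} on log income


@dataclass(frozen=True)
class MissingnessConfig:
    """Cell-level MAR missingness plus monotone wave attrition."""

    rate: float = 0.0               # marginal per-cell missingness
    mar_coefficients: dict[str, float] = field(default_factory=dict)
    columns: tuple[str, ...] = (
        "income", "housing_costs", "ghq_score", "ghq_case",
        "sf12_pcs", "sf12_mcs", "benefits", "tenure", "marital",
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int
    n_waves: int = 9
    seed: int = 0
    exposure_effect: float = 0.16     # log-odds of A_t on the CMD latent model
    exposure_effect_persist: float | None = None  # A_t effect when A_{t-1}=1
    selection_effect: float = 0.20    # Y_{t-1} depressing log income
    y_persistence: float = 1.20       # Y_{t-1} on the CMD latent model
    baseline_cmd_logit: float = -1.62
    confounder_effects: dict[str, ConfounderEffect] = field(
        default_factory=default_confounder_effects
    )
    income_params: IncomeParams = field(default_factory=IncomeParams)
    missingness: MissingnessConfig = field(default_factory=MissingnessConfig)
    attrition_rate: float = 0.04
    randomize_exposure: float | None = None  # Bernoulli(p) exposure, diagnostic

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise InvalidConfigError("n_individuals must be positive")
        if self.n_waves < 2:
            raise InvalidConfigError("n_waves must be >= 2 (lags need a prior wave)")
        for name, p in [
            ("attrition_rate", self.attrition_rate),
            ("missingness.rate", self.missingness.rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {p}")
        if self.randomize_exposure is not None and not (
            0.0 <= self.randomize_exposure <= 1.0
        ):
            raise InvalidConfigError("randomize_exposure must be in [0, 1]")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def scenario(name: str, n_individuals: int, seed: int = 0, **kwargs) -> SimulationConfig:
    """Named scenario presets.

    default          calibrated to ~22% poverty / ~20% CMD prevalence
    null_effect      exposure_effect = 0
    strong_selection health selection strong enough to visibly bias the
                     crude association
    no_confounding   all confounder paths, selection and outcome persistence
                     switched off (also the symmetric-transition scenario)
    """
    base = SimulationConfig(n_individuals=n_individuals, seed=seed)
    if name == "default":
        cfg = base
    elif name == "null_effect":
        cfg = base.replace(exposure_effect=0.0)
    elif name == "strong_selection":
        cfg = base.replace(selection_effect=0.80)
    elif name == "no_confounding":
        null_effects = {
            k: ConfounderEffect(v.on_income, 0.0)
            for k, v in default_confounder_effects().items()
        }
        cfg = base.replace(
            confounder_effects=null_effects,
            selection_effect=0.0,
            y_persistence=0.0,
        )
    else:
        raise InvalidConfigError(f"unknown scenario {name!r}")
    if kwargs:
        # allow plain-dict overrides (e.g. from YAML configs)
        if isinstance(kwargs.get("income_params"), dict):
            kwargs["income_params"] = IncomeParams(**kwargs["income_params"])
        if isinstance(kwargs.get("missingness"), dict):
            mk = dict(kwargs["missingness"])
            if "columns" in mk:
                mk["columns"] = tuple(mk["columns"])
            kwargs["missingness"] = MissingnessConfig(**mk)
        if "confounder_effects" in kwargs:
            kwargs["confounder_effects"] = {
                k: v if isinstance(v, ConfounderEffect) else ConfounderEffect(*v)
                for k, v in kwargs["confounder_effects"].items()
            }
        cfg = cfg.replace(**kwargs)
    return cfg


@dataclass(frozen=True)
class OracleTruth:
    """Counterfactual ground truth for a synthetic scenario (percent scale)."""

    true_rd: float          # percentage points
    true_or: float
    true_rd_into: float     # among A_{t-1}=0 (at risk of entering poverty)
    true_rd_outof: float    # among A_{t-1}=1, effect of leaving poverty
    mc_se: float            # cluster-aware Monte-Carlo SE of true_rd


# ---------------------------------------------------------------------------
# simulation core
# ---------------------------------------------------------------------------

PANEL_COLUMNS = [
    "person_id", "household_id", "wave", "income", "housing_costs",
    "n_adults", "n_children", "gender", "ethnicity", "education",
    "employment", "benefits", "tenure", "marital", "region", "age",
    "sf12_pcs", "sf12_mcs", "ghq_case", "ghq_score",
]


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _income_index(cfg, *, female, nonwhite, edu, emp, emp_lag, ben_lag,
                  ten_lag, mar_lag, chd_lag, pcs_lag, mcs_lag, age,
                  a_lag, y_lag):
    ce = cfg.confounder_effects
    age_c = (age - 45.0) / 10.0
    m = (
        cfg.income_params.log_mean
        + ce["gender"].on_income * female
        + ce["ethnicity"].on_income * nonwhite
        + ce["education"].on_income * edu
        + ce["employment"].on_income * emp
        + ce["employment_lag"].on_income * emp_lag
        + ce["benefits"].on_income * ben_lag
        + ce["tenure"].on_income * ten_lag
        + ce["marital"].on_income * mar_lag
        + ce["children"].on_income * chd_lag
        + ce["physical_health"].on_income * (pcs_lag - 50.0) / 10.0
        + ce["mental_health"].on_income * (mcs_lag - 50.0) / 10.0
        + ce["age"].on_income * age_c
        + ce["age2"].on_income * age_c ** 2
        + cfg.income_params.poverty_persistence * a_lag
        - cfg.selection_effect * y_lag
    )
    return m


def _cmd_logit(cfg, *, female, nonwhite, edu, emp, emp_lag, ben_lag, ten_lag,
               mar_lag, chd_lag, pcs_lag, mcs_lag, age, a, a_lag, y_lag):
    ce = cfg.confounder_effects
    age_c = (age - 45.0) / 10.0
    beta_onset = cfg.exposure_effect
    beta_persist = (
        cfg.exposure_effect
        if cfg.exposure_effect_persist is None
        else cfg.exposure_effect_persist
    )
    beta = np.where(a_lag > 0, beta_persist, beta_onset)
    eta = (
        cfg.baseline_cmd_logit
        + beta * a
        + cfg.y_persistence * y_lag
        + ce["gender"].on_cmd * female
        + ce["ethnicity"].on_cmd * nonwhite
        + ce["education"].on_cmd * edu
        + ce["employment"].on_cmd * emp
        + ce["employment_lag"].on_cmd * emp_lag
        + ce["benefits"].on_cmd * ben_lag
        + ce["tenure"].on_cmd * ten_lag
        + ce["marital"].on_cmd * mar_lag
        + ce["children"].on_cmd * chd_lag
        + ce["physical_health"].on_cmd * (pcs_lag - 50.0) / 10.0
        + ce["mental_health"].on_cmd * (mcs_lag - 50.0) / 10.0
        + ce["age"].on_cmd * age_c
        + ce["age2"].on_cmd * age_c ** 2
    )
    return eta


def _simulate(cfg: SimulationConfig, collect_oracle: bool):
    """Shared simulation engine.

    Returns (panel DataFrame, oracle row records) where each oracle record is
    a dict of person ids, A_{t-1}, and the counterfactual probability pair
    (p1, p0) for eligible person-waves (wave >= 2, age in [25, 64]).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    ip = cfg.income_params

    # time-invariant attributes
    female = (rng.random(n) < 0.52).astype(float)
    nonwhite = (rng.random(n) < 0.13).astype(float)
    edu = rng.choice(3, size=n, p=[0.22, 0.38, 0.40]).astype(float)  # 0 low..2 high
    region = rng.integers(0, 4, size=n)
    age0 = rng.integers(25, 58, size=n).astype(float)
    housing_frac = np.clip(rng.normal(ip.housing_fraction, 0.05, size=n), 0.05, 0.60)

    # wave-1 state
    emp = (rng.random(n) < _expit(1.15 + 0.45 * edu)).astype(float)
    chd = np.clip(rng.poisson(np.where(age0 < 45, 1.2, 0.5)), 0, 4).astype(float)
    ben = (rng.random(n) < _expit(-0.80 - 1.50 * emp + 0.25 * chd)).astype(float)
    mar = (rng.random(n) < 0.68).astype(float)
    ten = (rng.random(n) < _expit(0.30 + 0.50 * edu + 0.60 * mar)).astype(float)
    pcs = 52.0 - 0.8 * (age0 - 45.0) / 10.0 + rng.normal(0, 9.0, size=n)
    mcs = 50.0 + rng.normal(0, 9.0, size=n)
    u_sd_factor = 1.0 / np.sqrt(max(1.0 - ip.ar1 ** 2, 1e-12))
    u = rng.logistic(0.0, ip.noise_scale, size=n) * u_sd_factor
    a_prev = np.zeros(n)
    y_prev = np.zeros(n)

    # wave 1 exposure/outcome (initialization; analysis uses waves >= 2)
    m1 = _income_index(
        cfg, female=female, nonwhite=nonwhite, edu=edu, emp=emp, emp_lag=emp,
        ben_lag=ben, ten_lag=ten, mar_lag=mar, chd_lag=chd, pcs_lag=pcs,
        mcs_lag=mcs, age=age0, a_lag=a_prev, y_lag=y_prev,
    )
    log_eq = m1 + u
    eq_inc = np.exp(log_eq)
    if cfg.randomize_exposure is not None:
        a = (rng.random(n) < cfg.randomize_exposure).astype(float)
    else:
        a = (eq_inc < 0.6 * np.median(eq_inc)).astype(float)
    eta1 = _cmd_logit(
        cfg, female=female, nonwhite=nonwhite, edu=edu, emp=emp, emp_lag=emp,
        ben_lag=ben, ten_lag=ten, mar_lag=mar, chd_lag=chd, pcs_lag=pcs,
        mcs_lag=mcs, age=age0, a=a, a_lag=a_prev, y_lag=y_prev,
    )
    y = (rng.random(n) < _expit(eta1)).astype(float)
    mcs = 50.0 + 0.55 * (mcs - 50.0) - 6.5 * y + rng.normal(0, 6.5, size=n)

    alive = np.ones(n, dtype=bool)
    rows = []
    oracle = []

    def emit(wave, age, eq_inc_w, a_w, y_w, emp_w, ben_w, ten_w, mar_w,
             chd_w, pcs_w, mcs_w, mask):
        scale = 1.0 + 0.5 * mar_w + 0.3 * chd_w
        gross = eq_inc_w * scale / (1.0 - housing_frac)
        housing = gross * housing_frac
        score = np.where(
            y_w > 0,
            4 + rng.binomial(8, 0.33, size=n),
            rng.binomial(3, 0.38, size=n),
        )
        idx = np.nonzero(mask)[0]
        extra = {}
        if cfg.randomize_exposure is not None:
            # diagnostic mode: the assigned exposure is not derivable from
            # income, so emit it explicitly
            extra["assigned_exposure"] = a[idx]
        rows.append(
            pd.DataFrame(
                {
                    "person_id": idx,
                    "household_id": idx,
                    "wave": wave,
                    "income": gross[idx],
                    "housing_costs": housing[idx],
                    "n_adults": (1.0 + mar_w)[idx],
                    "n_children": chd_w[idx],
                    "gender": female[idx],
                    "ethnicity": nonwhite[idx],
                    "education": edu[idx],
                    "employment": emp_w[idx],
                    "benefits": ben_w[idx],
                    "tenure": ten_w[idx],
                    "marital": mar_w[idx],
                    "region": region[idx].astype(float),
                    "age": age[idx],
                    "sf12_pcs": pcs_w[idx],
                    "sf12_mcs": mcs_w[idx],
                    "ghq_case": y_w[idx],
                    "ghq_score": score[idx].astype(float),
                    **extra,
                }
            )
        )

    age = age0.copy()
    emit(1, age, eq_inc, a, y, emp, ben, ten, mar, chd, pcs, mcs, alive)

    for wave in range(2, cfg.n_waves + 1):
        # lagged state (pre-update copies)
        emp_lag, ben_lag, ten_lag, mar_lag = emp, ben, ten, mar
        chd_lag, pcs_lag, mcs_lag = chd, pcs, mcs
        a_lag, y_lag = a, y
        age = age0 + (wave - 1)

        emp = (rng.random(n) < _expit(
            -0.90 + 2.60 * emp_lag + 0.25 * edu - 0.50 * y_lag - 0.30 * ben_lag
        )).astype(float)
        ben = (rng.random(n) < _expit(
            -1.10 + 1.80 * ben_lag - 1.10 * emp + 0.25 * chd_lag
        )).astype(float)
        ten = (rng.random(n) < _expit(
            -1.20 + 4.00 * ten_lag + 0.30 * edu - 0.40 * a_lag
        )).astype(float)
        mar = (rng.random(n) < _expit(-2.75 + 5.60 * mar_lag)).astype(float)
        births = (rng.random(n) < np.where((age < 42) & (mar_lag > 0), 0.09, 0.015))
        departs = (chd_lag > 0) & (rng.random(n) < (0.07 + 0.04 * (age > 45)))
        chd = np.clip(chd_lag + births - departs, 0, 5).astype(float)
        pcs = 50.0 + 0.75 * (pcs_lag - 50.0) - 0.6 * (age - 45.0) / 10.0 \
            + rng.normal(0, 6.0, size=n)

        m = _income_index(
            cfg, female=female, nonwhite=nonwhite, edu=edu, emp=emp,
            emp_lag=emp_lag, ben_lag=ben_lag, ten_lag=ten_lag, mar_lag=mar_lag,
            chd_lag=chd_lag, pcs_lag=pcs_lag, mcs_lag=mcs_lag, age=age,
            a_lag=a_lag, y_lag=y_lag,
        )
        u = ip.ar1 * u + rng.logistic(0.0, ip.noise_scale, size=n)
        eq_inc = np.exp(m + u)
        if cfg.randomize_exposure is not None:
            a = (rng.random(n) < cfg.randomize_exposure).astype(float)
        else:
            line = 0.6 * np.median(eq_inc[alive])
            a = (eq_inc < line).astype(float)

        cmd_kwargs = dict(
            female=female, nonwhite=nonwhite, edu=edu, emp=emp,
            emp_lag=emp_lag, ben_lag=ben_lag, ten_lag=ten_lag, mar_lag=mar_lag,
            chd_lag=chd_lag, pcs_lag=pcs_lag, mcs_lag=mcs_lag, age=age,
            a_lag=a_lag, y_lag=y_lag,
        )
        eta = _cmd_logit(cfg, a=a, **cmd_kwargs)
        y = (rng.random(n) < _expit(eta)).astype(float)

        if collect_oracle:
            p1 = _expit(_cmd_logit(cfg, a=np.ones(n), **cmd_kwargs))
            p0 = _expit(_cmd_logit(cfg, a=np.zeros(n), **cmd_kwargs))
            eligible = alive & (age >= 25) & (age <= 64)
            oracle.append(
                {
                    "person": np.nonzero(eligible)[0],
                    "a_lag": a_lag[eligible],
                    "p1": p1[eligible],
                    "p0": p0[eligible],
                }
            )

        mcs = 50.0 + 0.55 * (mcs_lag - 50.0) - 6.5 * y + rng.normal(0, 6.5, size=n)

        alive = alive & (rng.random(n) >= cfg.attrition_rate)
        emit(wave, age, eq_inc, a, y, emp, ben, ten, mar, chd, pcs, mcs, alive)

    panel = pd.concat(rows, ignore_index=True)
    panel = panel.sort_values(["person_id", "wave"], kind="stable").reset_index(
        drop=True
    )
    return panel, oracle


def generate_panel(config: SimulationConfig) -> pd.DataFrame:
    """Generate a complete long-format person-wave panel.

    One row per person-wave; no missing cells (use :func:`impose_missingness`
    separately). Deterministic given (config, seed).
    """
    panel, _ = _simulate(config, collect_oracle=False)
    return panel


def compute_oracle_truth(config: SimulationConfig, n_mc: int = 100_000) -> OracleTruth:
    """Monte-Carlo counterfactual truth for ``config``'s scenario.

    Simulates ``n_mc`` individuals, forces the current-wave exposure to 1 and
    to 0 at each eligible person-wave (history at natural values), and
    averages the outcome-probability contrast. Effects are on the percent
    scale; ``mc_se`` is a person-clustered Monte-Carlo standard error.
    """
    if n_mc < 10_000:
        raise InvalidConfigError("n_mc must be >= 10000")
    cfg = config.replace(
        n_individuals=n_mc,
        missingness=MissingnessConfig(rate=0.0),
    )
    _, oracle = _simulate(cfg, collect_oracle=True)
    person = np.concatenate([o["person"] for o in oracle])
    a_lag = np.concatenate([o["a_lag"] for o in oracle])
    p1 = np.concatenate([o["p1"] for o in oracle])
    p0 = np.concatenate([o["p0"] for o in oracle])
    d = p1 - p0

    true_rd = 100.0 * d.mean()
    mean_p1, mean_p0 = p1.mean(), p0.mean()
    true_or = (mean_p1 / (1 - mean_p1)) / (mean_p0 / (1 - mean_p0))
    into = a_lag == 0
    true_rd_into = 100.0 * d[into].mean() if into.any() else np.nan
    true_rd_outof = -100.0 * d[~into].mean() if (~into).any() else np.nan

    # cluster (person) MC standard error of the pooled mean of d
    order = np.argsort(person, kind="stable")
    pers_sorted, d_sorted = person[order], d[order]
    uniq, start = np.unique(pers_sorted, return_index=True)
    sums = np.add.reduceat(d_sorted, start)
    counts = np.diff(np.append(start, len(d_sorted)))
    resid = sums - d.mean() * counts
    mc_se = 100.0 * np.sqrt((resid ** 2).sum()) / counts.sum()

    return OracleTruth(
        true_rd=float(true_rd),
        true_or=float(true_or),
        true_rd_into=float(true_rd_into),
        true_rd_outof=float(true_rd_outof),
        mc_se=float(mc_se),
    )


def impose_missingness(
    panel: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply MAR cell-level missingness; returns (panel, indicator table).

    The missingness probability of a cell depends only on *other* observed
    covariates of the same row (never on the cell's own value), via a logit
    shifted so the marginal rate matches ``config.missingness.rate``.
    ``ghq_case`` and ``ghq_score`` are amputated jointly (one underlying
    instrument response).
    """
    mc = config.missingness
    if not 0.0 <= mc.rate <= 1.0:
        raise InvalidConfigError("missingness rate must be in [0, 1]")
    out = panel.copy()
    indicators = pd.DataFrame(index=panel.index)
    if mc.rate == 0.0:
        for col in mc.columns:
            if col in panel.columns:
                indicators[col] = False
        return out, indicators

    rng = np.random.default_rng(config.seed + 1_000_003)
    # linear MAR predictor from standardized observed covariates
    shift = np.zeros(len(panel))
    for col, coef in mc.mar_coefficients.items():
        v = panel[col].to_numpy(dtype=float)
        sd = v.std()
        shift += coef * ((v - v.mean()) / sd if sd > 0 else 0.0)
    base = np.log(mc.rate / (1.0 - mc.rate))
    # calibrate the intercept so the mean probability equals the target rate
    for _ in range(30):
        p = _expit(base + shift)
        base += np.log(mc.rate / p.mean())
    p = _expit(base + shift)

    ghq_pair = {"ghq_case", "ghq_score"}
    ghq_draw = rng.random(len(panel))
    for col in mc.columns:
        if col not in panel.columns:
            continue
        miss = (ghq_draw if col in ghq_pair else rng.random(len(panel))) < p
        out.loc[miss, col] = np.nan
        indicators[col] = miss
    return out, indicators
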