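"""Derivation of analysis variables from a raw person-wave panel.

Turns raw household income into equivalized after-housing-costs income, the
per-wave relative poverty line (60% of the contemporaneous median) and the
binary poverty exposure; GHQ-12 scores into CMD caseness; and the long panel
into the analysis table with one-wave-lagged covariates attached.

Conventions (documented design choices):

* even-count median = mean of the two central values; the median is taken
  over person-wave rows (person-weighted);
* strict inequality at the poverty line — a household exactly at the line is
  not in poverty;
* lags require consecutive observed waves: a skipped wave breaks the lag
  chain for the wave after the gap;
* the working-age filter (25-64) is applied per row, not per person.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError

WORKING_AGE = (25.0, 64.0)

#: time-varying covariates lagged onto each analysis row
LAGGED_VARIABLES = [
    "poverty", "ghq_case", "employment", "benefits", "tenure", "marital",
    "n_children", "region", "sf12_pcs", "sf12_mcs",
]


def equivalence_scale(n_adults, n_children) -> np.ndarray:
    """Modified-OECD scale: 1.0 first adult + 0.5 per other adult + 0.3 per child."""
    return 1.0 + 0.5 * (np.asarray(n_adults, dtype=float) - 1.0) \
        + 0.3 * np.asarray(n_children, dtype=float)


def equivalize_income(income, housing_costs, scale):
    """Equivalized after-housing-costs income: (income - housing) / scale.

    May legitimately be negative (housing costs exceeding income).
    """
    scale = np.asarray(scale, dtype=float)
    if np.any(scale <= 0):
        raise ValueError("equivalence scale must be positive")
    out = (np.asarray(income, dtype=float) - np.asarray(housing_costs, dtype=float)) \
        / scale
    return float(out) if out.ndim == 0 else out


def poverty_line(equivalized_incomes) -> float:
    """60% of the median equivalized income of one wave (NaNs ignored)."""
    v = np.asarray(equivalized_incomes, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("poverty line undefined for an empty wave")
    return 0.6 * float(np.median(v))


def derive_poverty(panel: pd.DataFrame) -> pd.DataFrame:
    """Attach eq_income, poverty_line and the binary poverty exposure.

    The line is recomputed within each wave; exposure is strict `<`.
    Rows with missing income components get NaN exposure.
    """
    out = panel.copy()
    scale = equivalence_scale(out["n_adults"], out["n_children"])
    out["eq_income"] = equivalize_income(out["income"], out["housing_costs"], scale)
    lines = out.groupby("wave")["eq_income"].transform(
        lambda s: 0.6 * s.median(skipna=True)
    )
    out["poverty_line"] = lines
    pov = (out["eq_income"] < lines).astype(float)
    pov[out["eq_income"].isna()] = np.nan
    out["poverty"] = pov
    return out


def derive_caseness(ghq_score):
    """CMD caseness: GHQ-12 score >= 4. Scores outside [0, 12] are an error."""
    v = np.asarray(ghq_score, dtype=float)
    valid = np.isnan(v) | ((v >= 0) & (v <= 12))
    if not valid.all():
        raise ValueError("GHQ-12 score outside [0, 12]")
    out = np.where(np.isnan(v), np.nan, (v >= 4).astype(float))
    return float(out) if out.ndim == 0 else out


def build_analysis_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Attach one-wave lags and return the estimation table.

    Requires `poverty` (see :func:`derive_poverty`) and `ghq_case`. Each
    person's first observed wave contributes lag data only; rows whose
    previous wave was not observed (gap) are excluded; rows outside working
    age are dropped. Adds `age_c` ((age-45)/10), `age_c2` and keeps `wave`
    as the period marker.
    """
    required = {"person_id", "wave", "poverty", "ghq_case"}
    missing = required - set(panel.columns)
    if missing:
        raise SchemaError(f"panel lacks columns {sorted(missing)}")
    if panel.duplicated(["person_id", "wave"]).any():
        raise SchemaError("duplicate (person_id, wave) rows")

    cur = panel.sort_values(["person_id", "wave"], kind="stable").reset_index(drop=True)
    lag_cols = [c for c in LAGGED_VARIABLES if c in cur.columns]
    prev = cur[["person_id", "wave"] + lag_cols].copy()
    prev["wave"] = prev["wave"] + 1
    prev = prev.rename(columns={c: f"{c}_lag" for c in lag_cols})
    at = cur.merge(prev, on=["person_id", "wave"], how="inner")

    at = at[(at["age"] >= WORKING_AGE[0]) & (at["age"] <= WORKING_AGE[1])]
    at = at.reset_index(drop=True)
    at["age_c"] = (at["age"] - 45.0) / 10.0
    at["age_c2"] = at["age_c"] ** 2
    return at


def derive_transitions(analysis_table: pd.DataFrame, estimand: str) -> pd.DataFrame:
    """Restrict to the transition reference population and code its exposure.

    into:  rows with poverty_lag == 0; exposure = poverty (entering vs
           staying out of poverty).
    outof: rows with poverty_lag == 1; exposure = 1 - poverty (leaving vs
           staying in poverty).
    """
    if estimand not in ("into", "outof"):
        raise ValueError(f"unknown estimand {estimand!r}")
    if estimand == "into":
        sub = analysis_table[analysis_table["poverty_lag"] == 0].copy()
        sub["exposure"] = sub["poverty"]
    else:
        sub = analysis_table[analysis_table["poverty_lag"] == 1].copy()
        sub["exposure"] = 1.0 - sub["poverty"]
    return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

CODEBOOK = {
    "gender": "0=male, 1=female",
    "ethnicity": "0=majority, 1=minority ethnicity",
    "education": "0=low (none), 1=medium (secondary), 2=high (degree)",
    "employment": "0=not in paid work, 1=in paid work",
    "benefits": "0=no welfare benefits, 1=receiving benefits",
    "tenure": "0=renter, 1=owner",
    "marital": "0=single, 1=coupled",
    "region": "generic region code 0-3",
    "ghq_case": "0=GHQ-12 score <4, 1=score >=4 (CMD caseness)",
    "poverty": "0=at/above poverty line, 1=below (eq. AHC income < 60% median)",
}


def write_table(df: pd.DataFrame, path, codebook_path=None) -> None:
    """Write a table as CSV with an optional sidecar codebook."""
    df.to_csv(path, index=False)
    if codebook_path is not None:
        with open(codebook_path, "w") as fh:
            for col in df.columns:
                fh.write(f"{col}: {CODEBOOK.get(col, 'numeric')}\n")
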