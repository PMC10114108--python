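"""Design-matrix construction shared by the weighting, outcome and FE models.

Categorical covariates (education, region, survey wave) are expanded to
treatment-coded indicator columns; everything else enters as a numeric column.
An intercept is always prepended.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError

#: columns expanded to one-indicator-per-nonreference-level
CATEGORICAL_COVARIATES = frozenset({"education", "region", "wave"})


def build_design(
    df: pd.DataFrame,
    covariates: list[str],
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Return a numeric design matrix (float64) for ``covariates``.

    Categorical covariates are dummy-expanded dropping the first observed
    level; column names are ``<var>[<level>]``. Raises ``SchemaError`` for a
    missing column.
    """
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["const"] = np.ones(len(df))
    for cov in covariates:
        if cov not in df.columns:
            raise SchemaError(f"covariate {cov!r} not in table")
        base = cov.removesuffix("_lag")
        if base in CATEGORICAL_COVARIATES:
            values = df[cov].to_numpy()
            levels = np.unique(values)
            for level in levels[1:]:
                cols[f"{cov}[{level}]"] = (values == level).astype(float)
        else:
            cols[cov] = df[cov].to_numpy(dtype=float)
    out = pd.DataFrame(cols, index=df.index)
    if out.isna().to_numpy().any():
        bad = out.columns[out.isna().any()].tolist()
        raise SchemaError(f"NaN in design columns {bad}")
    return out
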