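"""Shared exception types."""


class InvalidConfigError(ValueError):
    """A configuration object violates one of its invariants."""


class SchemaError(ValueError):
    """A table is missing required columns or has malformed rows."""


class SeparationError(RuntimeError):
    """Perfect separation in a logistic fit; names the offending covariate."""

    def __init__(self, covariate: str):
        self.covariate = covariate
        super().__init__(
            f"perfect separation detected; offending covariate: {covariate}"
        )


class PositivityError(RuntimeError):
    """Fitted probability of the observed exposure below the positivity floor."""

    def __init__(self, rows, floor: float):
        self.rows = list(rows)
        self.floor = floor
        super().__init__(
            f"{len(self.rows)} rows with fitted exposure probability < {floor:g}; "
            f"first rows: {self.rows[:10]}"
        )
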