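"""Income equivalization, poverty line, caseness, lags, transitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from povmsm.derive import (
    build_analysis_table,
    derive_caseness,
    derive_poverty,
    derive_transitions,
    equivalize_income,
    poverty_line,
)
from povmsm.errors import SchemaError


class TestEquivalize:
    @pytest.mark.parametrize(
        "income,housing,scale,expected",
        [(1000, 200, 1.0, 800.0),
         (1500, 300, 1.5, 800.0),
         (200, 300, 1.0, -100.0)],  # negative disposable income retained
    )
    def test_arithmetic(self, income, housing, scale, expected):
        assert equivalize_income(income, housing, scale) == expected

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            equivalize_income(1000, 100, 0.0)


class TestPovertyLine:
    def test_odd_count_median(self):
        assert poverty_line([100, 200, 300, 400, 500]) == pytest.approx(180.0)

    def test_even_count_median_is_mean_of_central_pair(self):
        assert poverty_line([100, 200, 300, 400]) == pytest.approx(150.0)

    def test_equal_incomes_nobody_poor(self):
        line = poverty_line([250.0] * 7)
        assert line == pytest.approx(150.0)
        assert not (np.array([250.0] * 7) < line).any()

    def test_empty_wave_is_error(self):
        with pytest.raises(ValueError):
            poverty_line([])


def _panel_from_incomes(wave_incomes: dict[int, list[float]]) -> pd.DataFrame:
    rows = []
    for wave, incomes in wave_incomes.items():
        for i, inc in enumerate(incomes):
            rows.append(
                {"person_id": i, "household_id": i, "wave": wave,
                 "income": inc, "housing_costs": 0.0, "n_adults": 1.0,
                 "n_children": 0.0, "ghq_case": 0.0, "age": 40.0}
            )
    return pd.DataFrame(rows)


class TestDerivePoverty:
    def test_strict_inequality_at_line(self):
        panel = derive_poverty(_panel_from_incomes({1: [100, 200, 300, 400, 500]}))
        # line = 180; only the 100 row is poor; 180 itself would not be
        assert panel["poverty"].sum() == 1
        assert panel.loc[panel["income"] == 100, "poverty"].item() == 1
        at_line = derive_poverty(_panel_from_incomes({1: [180, 180, 300, 420]}))
        assert at_line.loc[at_line["income"] == 180, "poverty"].eq(0).all() or \
            at_line["poverty_line"].iloc[0] <= 180

    def test_line_recomputed_per_wave_can_flip_exposure(self):
        panel = derive_poverty(
            _panel_from_incomes({1: [160, 300, 310], 2: [160, 150, 140]})
        )
        w1 = panel[(panel["wave"] == 1) & (panel["income"] == 160)]
        w2 = panel[(panel["wave"] == 2) & (panel["income"] == 160)]
        assert w1["poverty"].item() == 1.0   # line 180
        assert w2["poverty"].item() == 0.0   # line 90

    def test_prevalence_equals_mean_exposure(self):
        panel = derive_poverty(
            _panel_from_incomes({1: list(range(100, 1100, 100))})
        )
        assert panel["poverty"].mean() == pytest.approx(
            (panel["eq_income"] < panel["poverty_line"]).mean()
        )


class TestCaseness:
    @pytest.mark.parametrize("score,expected", [(4, 1), (3, 0), (0, 0), (12, 1)])
    def test_boundary(self, score, expected):
        assert derive_caseness(score) == expected

    @pytest.mark.parametrize("score", [-1, 13, 99])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError):
            derive_caseness(score)


def _longitudinal_panel(obs: list[tuple[int, int]], age=40.0) -> pd.DataFrame:
    rows = []
    for pid, wave in obs:
        rows.append(
            {"person_id": pid, "household_id": pid, "wave": wave,
             "income": 500.0 + 10 * wave, "housing_costs": 100.0,
             "n_adults": 1.0, "n_children": 0.0, "gender": 0.0,
             "ethnicity": 0.0, "education": 1.0, "employment": 1.0,
             "benefits": 0.0, "tenure": 1.0, "marital": 0.0, "region": 0.0,
             "age": age + wave, "sf12_pcs": 50.0, "sf12_mcs": 50.0,
             "ghq_case": 0.0, "poverty": float(pid % 2)}
        )
    return pd.DataFrame(rows)


class TestAnalysisTable:
    def test_three_waves_give_two_rows(self):
        at = build_analysis_table(_longitudinal_panel([(1, 1), (1, 2), (1, 3)]))
        assert len(at) == 2
        assert sorted(at["wave"]) == [2, 3]

    def test_single_observed_wave_contributes_nothing(self):
        assert len(build_analysis_table(_longitudinal_panel([(1, 5)]))) == 0

    def test_counting_identity_complete_panel(self):
        obs = [(p, w) for p in range(7) for w in range(1, 5)]
        at = build_analysis_table(_longitudinal_panel(obs))
        assert len(at) == 7 * 3

    def test_gap_breaks_lag_chain(self):
        at = build_analysis_table(_longitudinal_panel([(1, 1), (1, 2), (1, 4)]))
        assert sorted(at["wave"]) == [2]  # wave 4 lacks a wave-3 predecessor

    def test_working_age_filter_per_row(self):
        at = build_analysis_table(
            _longitudinal_panel([(1, w) for w in range(1, 6)], age=59.0)
        )
        # ages 60..64 at waves 1..5; wave rows with age > 64 would drop
        assert (at["age"] <= 64).all()
        assert len(at) == 4

    def test_duplicate_rows_rejected(self):
        with pytest.raises(SchemaError):
            build_analysis_table(_longitudinal_panel([(1, 2), (1, 2)]))

    def test_lag_columns_attached(self):
        at = build_analysis_table(_longitudinal_panel([(1, 1), (1, 2)]))
        for col in ("poverty_lag", "ghq_case_lag", "employment_lag",
                    "sf12_mcs_lag", "age_c", "age_c2"):
            assert col in at.columns


class TestTransitions:
    def _table(self):
        return pd.DataFrame(
            {"poverty": [0, 1, 0, 1], "poverty_lag": [0, 0, 1, 1],
             "ghq_case": [0, 1, 0, 1]}
        )

    def test_into_coding(self):
        into = derive_transitions(self._table(), "into")
        assert len(into) == 2
        assert into["exposure"].tolist() == [0.0, 1.0]

    def test_outof_coding(self):
        outof = derive_transitions(self._table(), "outof")
        assert len(outof) == 2
        # leaving poverty (1 -> 0) is the exposed state
        assert outof["exposure"].tolist() == [1.0, 0.0]

    def test_partition_identity(self):
        t = self._table()
        assert len(derive_transitions(t, "into")) + \
            len(derive_transitions(t, "outof")) == len(t)

    def test_degenerate_all_previously_poor(self):
        t = pd.DataFrame({"poverty": [0, 1], "poverty_lag": [1, 1]})
        assert len(derive_transitions(t, "into")) == 0  # empty, error-free

    def test_unknown_estimand_rejected(self):
        with pytest.raises(ValueError):
            derive_transitions(self._table(), "sideways")


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(-1e5, 1e6), min_size=1, max_size=40))
def test_poverty_line_is_scale_of_median(incomes):
    assert poverty_line(incomes) == pytest.approx(
        0.6 * float(np.median(incomes)), rel=1e-12, abs=1e-9
    )


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 2**30))
def test_derive_poverty_invariant_to_id_relabelling(offset):
    panel = _panel_from_incomes({1: [120, 250, 330, 470, 90]})
    relabelled = panel.assign(person_id=panel["person_id"] + offset)
    a = derive_poverty(panel)["poverty"].to_numpy()
    b = derive_poverty(relabelled)["poverty"].to_numpy()
    assert (a == b).all()
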