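"""Panel model, CSV round trips, validation errors, reach aggregation."""

import json

import numpy as np
import pandas as pd
import pytest

from hrequity import (
    DEFAULT_INDICATORS,
    RegionalPanel,
    aggregate_reaches,
    panel_from_long,
    read_panel,
    round_half_away,
    write_table,
)
from hrequity.errors import (
    DuplicateRecordError,
    PanelSchemaError,
    PanelValidationError,
)

from conftest import TOY_INDICATORS, make_panel


def _write_csv(panel, path):
    panel.data.to_csv(path, index=False)
    return path


class TestReadPanel:
    def test_round_trip_identity(self, toy_panel, tmp_path):
        path = _write_csv(toy_panel, tmp_path / "panel.csv")
        back = read_panel(path, schema=TOY_INDICATORS)
        pd.testing.assert_frame_equal(
            back.data[toy_panel.data.columns], toy_panel.data, check_dtype=False
        )
        assert back.indicator_ids == ["beds", "doctors"]
        assert back.regions == ["a", "b", "c", "d"]

    def test_missing_column_names_it(self, toy_panel, tmp_path):
        df = toy_panel.data.drop(columns=["area"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(PanelSchemaError, match="area"):
            read_panel(path, schema=TOY_INDICATORS)

    def test_zero_population_rejected(self, toy_panel, tmp_path):
        df = toy_panel.data.copy()
        df.loc[1, "population"] = 0
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(PanelValidationError, match="population"):
            read_panel(path, schema=TOY_INDICATORS)

    def test_negative_indicator_has_coordinates(self, toy_panel):
        df = toy_panel.data.copy()
        df.loc[2, "beds"] = -1.0
        with pytest.raises(PanelValidationError, match=r"beds.*\[2\]"):
            RegionalPanel(data=df, indicators=TOY_INDICATORS)

    def test_non_numeric_cell_has_coordinates(self, toy_panel, tmp_path):
        df = toy_panel.data.astype(object)
        df.loc[0, "doctors"] = "many"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(PanelValidationError, match="doctors"):
            read_panel(path, schema=TOY_INDICATORS)

    def test_duplicate_region_year(self, toy_panel):
        df = pd.concat([toy_panel.data, toy_panel.data.iloc[[0]]], ignore_index=True)
        with pytest.raises(DuplicateRecordError):
            RegionalPanel(data=df, indicators=TOY_INDICATORS)

    def test_groups_csv_attached(self, toy_panel, tmp_path):
        path = _write_csv(toy_panel, tmp_path / "panel.csv")
        gpath = tmp_path / "groups.csv"
        pd.DataFrame(
            {"region_id": ["a", "b", "c", "d"], "group": ["e", "e", "w", "w"]}
        ).to_csv(gpath, index=False)
        panel = read_panel(path, schema=TOY_INDICATORS, groups=gpath)
        assert panel.grouping == {"a": "e", "b": "e", "c": "w", "d": "w"}

    def test_long_format_pivot(self, toy_panel):
        long = toy_panel.data.melt(
            id_vars=["region_id", "region_name", "year", "population", "area", "gdp_per_capita"],
            value_vars=["beds", "doctors"],
            var_name="indicator",
            value_name="value",
        )
        panel = panel_from_long(long, schema=TOY_INDICATORS)
        got = panel.data.sort_values("region_id").set_index("region_id")
        want = toy_panel.data.set_index("region_id")
        for col in ("population", "beds", "doctors"):
            assert np.allclose(got[col], want[col])


class TestRoundingAndWrite:
    @pytest.mark.parametrize(
        "value,digits,expected",
        [
            (0.356156, 3, 0.356),     # published-table convention
            (0.5, 0, 1.0),            # half away from zero
            (-0.5, 0, -1.0),
            (2.2465, 3, 2.247),       # half up at 3 dp
            (1.0005, 3, 1.001),
        ],
    )
    def test_half_away_from_zero(self, value, digits, expected):
        assert round_half_away(value, digits) == expected

    def test_write_rounds_but_does_not_mutate(self, toy_panel, tmp_path):
        df = toy_panel.data.copy()
        df["beds"] = df["beds"] + 0.356156
        out = tmp_path / "t.csv"
        write_table(df, out, round_digits=3)
        assert df["beds"].iloc[0] == 30.356156  # caller frame untouched
        back = pd.read_csv(out)
        assert back["beds"].iloc[0] == 30.356

    def test_json_output_is_numeric(self, toy_panel, tmp_path):
        out = tmp_path / "t.json"
        write_table(toy_panel.data, out, round_digits=3)
        records = json.loads(out.read_text())
        assert isinstance(records[0]["beds"], (int, float))

    def test_round_trip_bit_identical_for_rounded_data(self, toy_panel, tmp_path):
        first = tmp_path / "a.csv"
        second = tmp_path / "b.csv"
        write_table(toy_panel.data, first, round_digits=3)
        back = read_panel(first, schema=TOY_INDICATORS)
        write_table(back.data, second, round_digits=3)
        assert first.read_bytes() == second.read_bytes()


class TestAggregateReaches:
    def test_additivity_and_weighted_gdp(self, toy_panel):
        reach = aggregate_reaches(toy_panel)
        east = reach.observations(2019).set_index("region_id").loc["east"]
        assert east["population"] == 40.0
        assert east["area"] == 10.0
        # populations 10, 30 with gdp 2, 4 -> weighted mean 3.5
        assert east["gdp_per_capita"] == pytest.approx(3.5)
        assert east["beds"] == 50.0

    def test_conserves_totals(self, toy_panel):
        reach = aggregate_reaches(toy_panel)
        for col in ("population", "area", "beds", "doctors"):
            assert reach.observations(2019)[col].sum() == pytest.approx(
                toy_panel.observations(2019)[col].sum(), rel=1e-12
            )

    def test_parent_totals_frozen_from_source(self, toy_panel):
        reach = aggregate_reaches(toy_panel)
        assert reach.parent_totals is not None
        assert reach.totals(2019)["population"] == pytest.approx(100.0)

    def test_row_order_invariance(self, toy_panel):
        shuffled = RegionalPanel(
            data=toy_panel.data.iloc[[3, 1, 0, 2]].reset_index(drop=True),
            indicators=TOY_INDICATORS,
            grouping=toy_panel.grouping,
        )
        a = aggregate_reaches(toy_panel).data.set_index("region_id").sort_index()
        b = aggregate_reaches(shuffled).data.set_index("region_id").sort_index()
        pd.testing.assert_frame_equal(a, b, check_like=True)

    def test_grouping_must_cover_regions(self, toy_panel):
        with pytest.raises(PanelValidationError, match="grouping"):
            RegionalPanel(
                data=toy_panel.data,
                indicators=TOY_INDICATORS,
                grouping={"a": "east", "b": "east", "c": "west"},  # d missing
            )

    def test_ungrouped_panel_cannot_aggregate(self, toy_panel):
        bare = RegionalPanel(data=toy_panel.data, indicators=TOY_INDICATORS)
        with pytest.raises(PanelSchemaError):
            aggregate_reaches(bare)


def test_explicit_parent_totals_take_precedence(toy_panel):
    totals = pd.DataFrame(
        {"population": [200.0], "area": [80.0], "beds": [200.0], "doctors": [40.0]},
        index=pd.Index([2019], name="year"),
    )
    panel = RegionalPanel(
        data=toy_panel.data, indicators=TOY_INDICATORS, parent_totals=totals
    )
    assert panel.totals(2019)["area"] == 80.0


def test_explicit_parent_totals_must_be_positive(toy_panel):
    totals = pd.DataFrame(
        {"population": [200.0], "area": [0.0], "beds": [200.0], "doctors": [40.0]},
        index=pd.Index([2019], name="year"),
    )
    with pytest.raises(PanelValidationError):
        RegionalPanel(data=toy_panel.data, indicators=TOY_INDICATORS, parent_totals=totals)
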