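"""Regional panel data model, CSV I/O, validation and reach aggregation.

A *panel* is a wide table with one row per (region, year): metadata
columns (``region_id``, ``region_name``, ``year``, ``population``,
``area``, ``gdp_per_capita``) followed by one column per resource
indicator.  This mirrors the layout of statistical-yearbook extracts.
Long-format tables (one row per region/year/indicator) are accepted via
:func:`panel_from_long`.

Row order is preserved throughout the pipeline and is the deterministic
tie-break for every ranking and sorting step downstream.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    PanelSchemaError,
    PanelValidationError,
)
from .indicators import DEFAULT_INDICATORS, IndicatorDef, check_unique_ids

META_COLUMNS = ("region_id", "region_name", "year", "population", "area", "gdp_per_capita")
#: metadata columns that must be strictly positive
_POSITIVE = ("population", "area", "gdp_per_capita")


@dataclass
class RegionalPanel:
    """Validated per-region, per-year observations plus reach grouping.

    Attributes
    ----------
    data
        Wide observation table (meta columns + one column per indicator),
        row order meaningful.
    indicators
        Indicator definitions; ``data`` has one column per ``id``.
    grouping
        Optional map region_id -> group label (e.g. reach membership).
    parent_totals
        Optional explicit parent-region totals per year (DataFrame indexed
        by year with columns ``population``, ``area`` and indicator ids).
        When absent, totals default to column sums over the observations
        of that year.
    """

    data: pd.DataFrame
    indicators: tuple[IndicatorDef, ...] = DEFAULT_INDICATORS
    grouping: Mapping[str, str] | None = None
    parent_totals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.indicators = tuple(self.indicators)
        validate_panel(self.data, self.indicators)
        if self.grouping is not None:
            missing = [r for r in self.regions if r not in self.grouping]
            if missing:
                raise PanelValidationError(
                    f"grouping does not cover region(s): {missing}"
                )
        if self.parent_totals is not None:
            needed = ["population", "area", *self.indicator_ids]
            absent = [c for c in needed if c not in self.parent_totals.columns]
            if absent:
                raise PanelSchemaError(f"parent_totals missing column(s): {absent}")
            if (self.parent_totals[needed] <= 0).any().any():
                raise PanelValidationError("explicit parent totals must be strictly positive")

    # -- accessors ---------------------------------------------------------

    @property
    def indicator_ids(self) -> list[str]:
        return [ind.id for ind in self.indicators]

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    @property
    def regions(self) -> list[str]:
        """Region ids in first-appearance (row) order."""
        return list(dict.fromkeys(self.data["region_id"]))

    def observations(self, year: int) -> pd.DataFrame:
        """The rows of one year, in panel row order."""
        out = self.data[self.data["year"] == year]
        if out.empty:
            from .errors import MissingYearError

            raise MissingYearError([year])
        return out

    def totals(self, year: int) -> pd.Series:
        """Parent totals for one year: population, area and each indicator.

        Explicit ``parent_totals`` take precedence; otherwise column sums
        over that year's observations.
        """
        cols = ["population", "area", *self.indicator_ids]
        if self.parent_totals is not None and year in self.parent_totals.index:
            return self.parent_totals.loc[year, cols].astype(float)
        return self.observations(year)[cols].sum().astype(float)

    def with_grouping(self, grouping: Mapping[str, str]) -> "RegionalPanel":
        return replace(self, grouping=dict(grouping))


def validate_panel(df: pd.DataFrame, indicators: Sequence[IndicatorDef]) -> None:
    """Check schema and value invariants, raising coordinate-bearing errors."""
    check_unique_ids(indicators)
    ids = [ind.id for ind in indicators]
    missing = [c for c in (*META_COLUMNS, *ids) if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"missing column(s): {missing}")

    numeric = ["year", "population", "area", "gdp_per_capita", *ids]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise PanelValidationError(
                f"non-numeric value in column '{col}' at row(s) {bad.tolist()}"
            )
    for col in _POSITIVE:
        vals = pd.to_numeric(df[col])
        bad = df.index[vals <= 0]
        if len(bad):
            raise PanelValidationError(
                f"column '{col}' must be strictly positive; "
                f"violations at row(s) {bad.tolist()}"
            )
    for col in ids:
        vals = pd.to_numeric(df[col])
        bad = df.index[vals < 0]
        if len(bad):
            raise PanelValidationError(
                f"indicator '{col}' has negative value(s) at row(s) {bad.tolist()}"
            )
    dup = df.duplicated(subset=["region_id", "year"])
    if dup.any():
        pairs = df.loc[dup, ["region_id", "year"]].itertuples(index=False, name=None)
        raise DuplicateRecordError(f"duplicate (region, year) record(s): {list(pairs)}")


# -- I/O -------------------------------------------------------------------


def read_panel(
    path: str | Path,
    schema: Sequence[IndicatorDef] = DEFAULT_INDICATORS,
    groups: str | Path | Mapping[str, str] | None = None,
) -> RegionalPanel:
    """Read a wide CSV panel, validate it, optionally attach a grouping.

    ``groups`` may be a mapping region_id -> label or a path to a CSV with
    columns ``region_id, group``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    for col in ("year", "population", "area", "gdp_per_capita", *(i.id for i in schema)):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "year" in df.columns and df["year"].notna().all():
        y = df["year"]
        if (y == y.round()).all():
            df["year"] = y.astype(int)
    grouping = None
    if groups is not None:
        if isinstance(groups, Mapping):
            grouping = dict(groups)
        else:
            gdf = pd.read_csv(groups)
            if not {"region_id", "group"} <= set(gdf.columns):
                raise PanelSchemaError("groups file needs columns: region_id, group")
            grouping = dict(zip(gdf["region_id"], gdf["group"]))
    return RegionalPanel(data=df, indicators=tuple(schema), grouping=grouping)


def panel_from_long(
    df: pd.DataFrame,
    schema: Sequence[IndicatorDef] = DEFAULT_INDICATORS,
    indicator_col: str = "indicator",
    value_col: str = "value",
    grouping: Mapping[str, str] | None = None,
) -> RegionalPanel:
    """Pivot a long table (one row per region/year/indicator) to a panel."""
    meta = [c for c in META_COLUMNS if c in df.columns]
    wide = (
        df.pivot_table(
            index=meta, columns=indicator_col, values=value_col, aggfunc="first"
        )
        .reset_index()
    )
    wide.columns.name = None
    return RegionalPanel(data=wide, indicators=tuple(schema), grouping=grouping)


def round_half_away(x: float, digits: int = 3) -> float:
    """Round half away from zero at ``digits`` decimals (0.5 -> 1, -0.5 -> -1).

    Operates on the shortest decimal representation of the float so that
    values that *print* as exact halves round up, matching how published
    tables are rounded.
    """
    q = decimal.Decimal(1).scaleb(-digits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d)


def _round_frame(df: pd.DataFrame, digits: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: round_half_away(v, digits) if pd.notna(v) else v)
    return out


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    round_digits: int = 3,
    fmt: str | None = None,
) -> None:
    """Write a result table as CSV (default) or JSON records.

    Float columns are rounded half-away-from-zero to ``round_digits``
    (the convention of published provincial tables); the caller's frame
    is left untouched, so full precision is retained in memory.  JSON
    output keeps numbers numeric.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    rounded = _round_frame(table, round_digits)
    if fmt == "csv":
        rounded.to_csv(path, index=False)
    elif fmt == "json":
        rounded.to_json(path, orient="records", indent=2)
    else:
        raise ValueError(f"unknown table format: {fmt!r}")


# -- reach aggregation -----------------------------------------------------


def aggregate_reaches(panel: RegionalPanel) -> RegionalPanel:
    """Aggregate member regions into their groups (reaches).

    Population, area and every indicator are summed; per-capita GDP of a
    group is the population-weighted mean of its members.  Parent totals
    are carried over unchanged, so group-level agglomeration degrees are
    computed against the same parent region as province-level ones.
    """
    if panel.grouping is None:
        raise PanelSchemaError("panel has no grouping; cannot aggregate reaches")
    labels = [panel.grouping[r] for r in panel.regions]
    label_order = list(dict.fromkeys(labels))

    rows = []
    for year in panel.years:
        obs = panel.observations(year)
        glab = obs["region_id"].map(panel.grouping)
        for lab in label_order:
            members = obs[glab == lab]
            if members.empty:
                raise PanelValidationError(f"group '{lab}' is empty in year {year}")
            pop = float(members["population"].sum())
            row = {
                "region_id": lab,
                "region_name": lab,
                "year": year,
                "population": pop,
                "area": float(members["area"].sum()),
                "gdp_per_capita": float(
                    (members["population"] * members["gdp_per_capita"]).sum() / pop
                ),
            }
            for ind in panel.indicator_ids:
                row[ind] = float(members[ind].sum())
            rows.append(row)
    data = pd.DataFrame(rows)

    parent = panel.parent_totals
    if parent is None:
        # freeze the implicit totals of the source panel so the aggregate
        # is judged against the full parent region, not against itself
        parent = pd.DataFrame(
            {year: panel.totals(year) for year in panel.years}
        ).T
        parent.index.name = "year"
    return RegionalPanel(
        data=data,
        indicators=panel.indicators,
        grouping={lab: lab for lab in label_order},
        parent_totals=parent,
    )
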