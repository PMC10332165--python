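"""Concentration curves and concentration indices over an economic gradient.

Regions are sorted by ascending per-capita GDP; the curve plots the
cumulative share of a resource (Y) against the cumulative share of
population (X), starting at the origin.  The area S under the curve is
accumulated with the trapezoid rule,

    S = 1/2 * sum_{i=0}^{n-1} (Y_i + Y_{i+1}) (X_{i+1} - X_i),

and the concentration index is CI = 2 * (0.5 - S), in (-1, 1).  A curve
above the fairness diagonal (resource concentrated in poorer regions)
gives S > 1/2 and hence CI < 0; a curve below the diagonal (pro-rich
allocation) gives CI > 0; exact per-capita proportionality gives CI = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MissingYearError, UndefinedStatisticError
from .panel import RegionalPanel


@dataclass(frozen=True)
class ConcentrationResult:
    """Curve coordinates and index for one indicator-year."""

    indicator_id: str
    year: int
    region_order: tuple[str, ...]  # ascending per-capita GDP
    x: np.ndarray  # cumulative population share, length n+1, starts at 0
    y: np.ndarray  # cumulative resource share, length n+1, starts at 0
    area_s: float
    ci: float

    @property
    def points(self) -> pd.DataFrame:
        """Curve points including the origin, one row per vertex."""
        return pd.DataFrame(
            {
                "region_id": ("", *self.region_order),
                "X": self.x,
                "Y": self.y,
            }
        )


def concentration_curve(
    panel: RegionalPanel, indicator: str, year: int
) -> ConcentrationResult:
    """Concentration curve and index of one indicator in one year.

    Ties in per-capita GDP are broken by panel row order, so results are
    deterministic for a given input file.
    """
    if indicator not in panel.indicator_ids:
        raise KeyError(f"unknown indicator: {indicator!r}")
    obs = panel.observations(year)
    order = np.argsort(obs["gdp_per_capita"].to_numpy(float), kind="stable")
    pop = obs["population"].to_numpy(float)[order]
    res = obs[indicator].to_numpy(float)[order]
    regions = obs["region_id"].to_numpy()[order]

    res_tot = res.sum()
    if res_tot <= 0:
        raise UndefinedStatisticError(
            f"total of '{indicator}' in {year} is {res_tot}; concentration undefined"
        )
    cum_pop = np.cumsum(pop)
    cum_res = np.cumsum(res)
    x = np.concatenate(([0.0], cum_pop / cum_pop[-1]))
    y = np.concatenate(([0.0], cum_res / cum_res[-1]))

    area = float(np.trapezoid(y, x))
    ci = 2.0 * (0.5 - area)
    return ConcentrationResult(
        indicator_id=indicator,
        year=int(year),
        region_order=tuple(regions),
        x=x,
        y=y,
        area_s=area,
        ci=ci,
    )


def ci_timeseries(
    panel: RegionalPanel,
    indicators: Sequence[str] | None = None,
    years: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Concentration index per (indicator, year).

    Tidy output with columns year, indicator, area_s, ci.  Use
    ``.pivot(index="year", columns="indicator", values="ci")`` for the
    year x indicator matrix layout.
    """
    indicators = list(indicators) if indicators is not None else panel.indicator_ids
    years = list(years) if years is not None else panel.years
    missing = set(years) - set(panel.years)
    if missing:
        raise MissingYearError(missing)
    rows = []
    for year in years:
        for ind in indicators:
            r = concentration_curve(panel, ind, year)
            rows.append(
                {"year": year, "indicator": ind, "area_s": r.area_s, "ci": r.ci}
            )
    return pd.DataFrame(rows)


def curve_points_table(results: Iterable[ConcentrationResult]) -> pd.DataFrame:
    """Stack curve vertices of several results into one tidy table."""
    frames = []
    for r in results:
        pts = r.points
        pts.insert(0, "indicator", r.indicator_id)
        pts.insert(0, "year", r.year)
        frames.append(pts)
    return pd.concat(frames, ignore_index=True)


def plot_curves(results: Sequence[ConcentrationResult], path) -> None:
    """Render concentration curves against the fairness diagonal (optional).

    Requires matplotlib; one panel per indicator, one line per year.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_ind: dict[str, list[ConcentrationResult]] = {}
    for r in results:
        by_ind.setdefault(r.indicator_id, []).append(r)
    n = len(by_ind)
    ncols = min(n, 4)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.5 * nrows), squeeze=False)
    for ax, (ind, rs) in zip(axes.flat, by_ind.items()):
        ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="fairness line")
        for r in sorted(rs, key=lambda r: r.year):
            ax.plot(r.x, r.y, lw=1.0, label=str(r.year))
        ax.set_title(ind, fontsize=9)
        ax.set_xlabel("cumulative population share")
        ax.set_ylabel("cumulative resource share")
    for ax in axes.flat[n:]:
        ax.axis("off")
    axes.flat[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
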