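"""Health-resource and population agglomeration degrees.

The agglomeration degree of a subregion is its share of a quantity
relative to its share of the parent region's land area:

    HRAD_i = (HR_i / HR_n) / (A_i / A_n)    (resource vs. area)
    PAD_i  = (P_i  / P_n)  / (A_i / A_n)    (population vs. area)

HRAD = 1 means the subregion holds resources at exactly the parent's
areal density; > 1 means geographically concentrated.  The fairness
ratio HRAD/PAD cancels the area shares and equals the subregion's
per-capita resource level relative to the parent's, so a ratio near 1
means allocation proportional to population.

The percentage factors in the share definitions cancel; everything here
is computed as pure share ratios.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .panel import RegionalPanel


def compute_hrad(panel: RegionalPanel, indicator: str, year: int) -> pd.Series:
    """Per-region health-resource agglomeration degree for one indicator.

    Returns a Series indexed by region_id in panel row order.
    """
    if indicator not in panel.indicator_ids:
        raise KeyError(f"unknown indicator: {indicator!r}")
    obs = panel.observations(year)
    tot = panel.totals(year)
    hr_n, a_n = float(tot[indicator]), float(tot["area"])
    if hr_n <= 0:
        raise UndefinedStatisticError(
            f"parent total for '{indicator}' in {year} is {hr_n}; HRAD undefined"
        )
    if a_n <= 0:
        raise UndefinedStatisticError(f"parent area in {year} is {a_n}; HRAD undefined")
    vals = (obs[indicator].to_numpy(float) / obs["area"].to_numpy(float)) / (hr_n / a_n)
    return pd.Series(vals, index=pd.Index(obs["region_id"], name="region_id"), name="hrad")


def compute_pad(panel: RegionalPanel, year: int) -> pd.Series:
    """Per-region population agglomeration degree."""
    obs = panel.observations(year)
    tot = panel.totals(year)
    p_n, a_n = float(tot["population"]), float(tot["area"])
    if p_n <= 0 or a_n <= 0:
        raise UndefinedStatisticError(
            f"parent population/area in {year} must be positive (got {p_n}, {a_n})"
        )
    vals = (obs["population"].to_numpy(float) / obs["area"].to_numpy(float)) / (p_n / a_n)
    return pd.Series(vals, index=pd.Index(obs["region_id"], name="region_id"), name="pad")


def compute_ratio(hrad: pd.Series, pad: pd.Series) -> pd.Series:
    """Fairness ratio HRAD/PAD (per-capita resource relative to parent)."""
    pad = pad.reindex(hrad.index)
    if pad.isna().any():
        raise KeyError("pad is missing regions present in hrad")
    if (pad <= 0).any():
        bad = pad.index[pad <= 0].tolist()
        raise UndefinedStatisticError(f"PAD must be positive; zero/negative at {bad}")
    out = hrad / pad
    out.name = "ratio"
    return out


def rank_descending(values: pd.Series) -> pd.Series:
    """Ordinal ranks, largest value = 1; ties broken by input order."""
    if len(values) == 0:
        raise ValueError("cannot rank an empty series")
    order = np.argsort(-values.to_numpy(float), kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return pd.Series(ranks, index=values.index, name=f"{values.name}_rank")


def agglomeration_table(
    panel: RegionalPanel,
    indicators: Sequence[str] | None = None,
    years: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Tidy HRAD/PAD table: one row per (year, region, indicator).

    Columns: year, region_id, indicator, hrad, hrad_rank, pad, ratio,
    ratio_rank.  Ranks run within each (year, indicator) block.
    """
    indicators = list(indicators) if indicators is not None else panel.indicator_ids
    years = list(years) if years is not None else panel.years
    blocks = []
    for year in years:
        pad = compute_pad(panel, year)
        for ind in indicators:
            hrad = compute_hrad(panel, ind, year)
            ratio = compute_ratio(hrad, pad)
            blocks.append(
                pd.DataFrame(
                    {
                        "year": year,
                        "region_id": hrad.index,
                        "indicator": ind,
                        "hrad": hrad.to_numpy(),
                        "hrad_rank": rank_descending(hrad).to_numpy(),
                        "pad": pad.reindex(hrad.index).to_numpy(),
                        "ratio": ratio.to_numpy(),
                        "ratio_rank": rank_descending(ratio).to_numpy(),
                    }
                )
            )
    return pd.concat(blocks, ignore_index=True)
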