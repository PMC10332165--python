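"""Shared fixtures and independent oracles.

The oracles here are deliberately coded straight from the definitions
(loops, no shared helpers with the package) so they can serve as
independent cross-checks of the pipeline implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from hrequity import DEFAULT_INDICATORS, RegionalPanel
from hrequity.indicators import IndicatorDef

TOY_INDICATORS = (
    IndicatorDef(id="beds", label="Beds", category="material", units="count"),
    IndicatorDef(id="doctors", label="Doctors", category="human", units="persons"),
)


def make_panel(
    region_ids,
    population,
    area,
    gdp_per_capita,
    values: dict,
    year=2019,
    grouping=None,
    indicators=None,
):
    """Build a one-year panel from parallel arrays."""
    if indicators is None:
        indicators = tuple(
            IndicatorDef(id=k, label=k, category="material", units="count")
            for k in values
        )
    df = pd.DataFrame(
        {
            "region_id": region_ids,
            "region_name": region_ids,
            "year": year,
            "population": population,
            "area": area,
            "gdp_per_capita": gdp_per_capita,
            **values,
        }
    )
    return RegionalPanel(data=df, indicators=indicators, grouping=grouping)


@pytest.fixture
def toy_panel():
    """Four regions, two groups, two hand-sized indicators."""
    return make_panel(
        region_ids=["a", "b", "c", "d"],
        population=[10.0, 30.0, 20.0, 40.0],
        area=[5.0, 5.0, 10.0, 20.0],
        gdp_per_capita=[2.0, 4.0, 1.0, 3.0],
        values={"beds": [30.0, 20.0, 25.0, 25.0], "doctors": [4.0, 6.0, 2.0, 8.0]},
        grouping={"a": "east", "b": "east", "c": "west", "d": "west"},
        indicators=TOY_INDICATORS,
    )


# -- independent oracles ---------------------------------------------------


def covariance_ci(population, resource, gdp_per_capita) -> float:
    """Grouped covariance-form concentration index.

    CI = (2/mu) * sum_i s_i * mu_i * (R_i - 0.5) with s_i the population
    share, mu_i the per-capita resource, R_i the fractional rank (the
    population-share midpoint of group i after sorting by economic
    level) and mu the overall per-capita mean.
    """
    pop = np.asarray(population, dtype=float)
    res = np.asarray(resource, dtype=float)
    gdp = np.asarray(gdp_per_capita, dtype=float)
    order = np.argsort(gdp, kind="stable")
    pop, res = pop[order], res[order]
    s = pop / pop.sum()
    mu_i = res / pop
    mu = res.sum() / pop.sum()
    ranks = np.cumsum(s) - s / 2.0
    return float((2.0 / mu) * np.sum(s * mu_i * (ranks - 0.5)))


def straight_topsis(matrix: np.ndarray):
    """Plain-loop entropy-weight TOPSIS on a benefit-only matrix.

    Returns (weights, closeness).  Written independently from the
    package implementation, directly from the formulas.
    """
    X = np.asarray(matrix, dtype=float)
    n, m = X.shape
    # entropy weights
    e = np.empty(m)
    for j in range(m):
        p = X[:, j] / X[:, j].sum()
        acc = 0.0
        for pi in p:
            if pi > 0:
                acc += pi * math.log(pi)
        e[j] = -acc / math.log(n)
    d = 1.0 - e
    w = d / d.sum()
    # TOPSIS with vector normalisation
    R = np.empty_like(X)
    for j in range(m):
        R[:, j] = X[:, j] / math.sqrt((X[:, j] ** 2).sum())
    V = R * w
    pos = V.max(axis=0)
    neg = V.min(axis=0)
    c = np.empty(n)
    for i in range(n):
        dp = math.sqrt(((V[i] - pos) ** 2).sum())
        dm = math.sqrt(((V[i] - neg) ** 2).sum())
        c[i] = dm / (dp + dm)
    return w, c


def random_panel(rng: np.random.Generator, n=8, indicator="beds"):
    """A positive random one-year panel for property checks."""
    pop = rng.uniform(1.0, 100.0, n)
    area = rng.uniform(1.0, 50.0, n)
    gdp = rng.uniform(1.0, 10.0, n)
    res = rng.uniform(0.1, 50.0, n)
    return make_panel(
        region_ids=[f"r{i}" for i in range(n)],
        population=pop,
        area=area,
        gdp_per_capita=gdp,
        values={indicator: res},
    )
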