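"""Entropy-weight determination and TOPSIS composite scoring.

The entropy-weight method assigns each criterion an objective weight
proportional to the information it carries: a column whose values are
spread out across alternatives has low Shannon entropy relative to the
uniform distribution and therefore high weight.  With column
proportions p_ij = x_ij / sum_i x_ij,

    e_j = -(1/ln n) * sum_i p_ij ln p_ij      (0*ln 0 := 0)
    d_j = 1 - e_j                              (information utility)
    w_j = d_j / sum_j d_j

TOPSIS then ranks alternatives by relative closeness to an ideal point:
columns are vector-normalised (r_ij = x_ij / sqrt(sum_i x_ij^2)),
weighted, the positive/negative ideals taken column-wise (max/min for
benefit criteria, swapped for cost criteria), and

    C_i = D_i^- / (D_i^+ + D_i^-)

with D^+/D^- the Euclidean distances to the two ideals.  C_i = 1 at the
positive ideal, 0 at the negative ideal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon

from .errors import DegenerateMatrixError, UndefinedStatisticError
from .panel import RegionalPanel

Orientation = Mapping[str, str]  # column -> "benefit" | "cost"


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives (rows, regions) x criteria (columns, indicators).

    ``orientation`` maps each column to ``"benefit"`` (more is better)
    or ``"cost"``; unmapped columns default to benefit.
    """

    values: pd.DataFrame
    orientation: Orientation = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 1:
            raise DegenerateMatrixError(
                f"decision matrix needs >=2 rows and >=1 column, got {v.shape}"
            )
        if v.isna().any().any():
            raise ValueError("decision matrix has missing cells")
        if (v < 0).any().any():
            raise ValueError("decision matrix has negative cells")
        bad = set(self.orientation.values()) - {"benefit", "cost"}
        if bad:
            raise ValueError(f"orientation must be benefit/cost, got {bad}")

    def sense(self, col: str) -> str:
        return self.orientation.get(col, "benefit")

    @classmethod
    def from_panel(
        cls,
        panel: RegionalPanel,
        year: int,
        matrix: str = "hrad",
        orientation: Orientation | None = None,
    ) -> "DecisionMatrix":
        """Build the region x indicator matrix for one year.

        ``matrix="hrad"`` scores agglomeration degrees (the default:
        composite agglomeration level); ``matrix="raw"`` scores the raw
        indicator values.
        """
        from .agglomeration import compute_hrad

        if matrix == "hrad":
            cols = {
                ind: compute_hrad(panel, ind, year) for ind in panel.indicator_ids
            }
            values = pd.DataFrame(cols)
        elif matrix == "raw":
            obs = panel.observations(year)
            values = obs.set_index("region_id")[panel.indicator_ids].astype(float)
            values.index.name = "region_id"
        else:
            raise ValueError(f"matrix must be 'hrad' or 'raw', got {matrix!r}")
        return cls(values=values, orientation=dict(orientation or {}))


@dataclass(frozen=True)
class EntropyWeightResult:
    """Per-criterion entropy e, utility d = 1 - e and weight w."""

    table: pd.DataFrame  # index: criterion; columns: entropy, utility, weight

    @property
    def weights(self) -> pd.Series:
        return self.table["weight"]

    @property
    def entropy(self) -> pd.Series:
        return self.table["entropy"]


@dataclass(frozen=True)
class TopsisResult:
    """Per-alternative ideal-point distances, closeness and rank."""

    table: pd.DataFrame  # index: alternative; columns: d_plus, d_minus, closeness, rank

    @property
    def closeness(self) -> pd.Series:
        return self.table["closeness"]

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]


def entropy_weights(matrix: DecisionMatrix, minmax_scale: bool = False) -> EntropyWeightResult:
    """Entropy weights of the matrix columns.

    ``minmax_scale`` optionally rescales each column to [0, 1] before
    forming column proportions (an alternative normalisation sometimes
    used when columns mix units; irrelevant for share-type inputs).
    """
    X = matrix.values.astype(float)
    if minmax_scale:
        rng = X.max() - X.min()
        X = (X - X.min()).div(rng.where(rng > 0, 1.0))
    sums = X.sum(axis=0)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise UndefinedStatisticError(f"zero column sum(s): {zero}; entropy undefined")
    n = X.shape[0]
    # scipy normalises the column to a probability vector and applies
    # the 0*ln 0 = 0 convention
    e = X.apply(lambda col: _shannon(col.to_numpy()) / np.log(n), axis=0)
    e = e.clip(0.0, 1.0)
    d = 1.0 - e
    if not (d > 1e-12).any():
        raise DegenerateMatrixError(
            "every column is uniform across alternatives; entropy weights degenerate"
        )
    w = d / d.sum()
    table = pd.DataFrame({"entropy": e, "utility": d, "weight": w})
    table.index.name = "indicator"
    return EntropyWeightResult(table=table)


def weights_from_entropy(e: pd.Series) -> pd.DataFrame:
    """The d = 1 - e and w = d / sum(d) stages from given entropies.

    Useful for re-deriving published weight rows from published entropy
    rows without the underlying matrix.
    """
    e = e.astype(float)
    d = 1.0 - e
    if not (d > 1e-12).any():
        raise DegenerateMatrixError("all entropies are 1; weights degenerate")
    return pd.DataFrame({"entropy": e, "utility": d, "weight": d / d.sum()})


def closeness_from_distances(d_plus, d_minus):
    """Relative closeness C = D^- / (D^+ + D^-) from given distances."""
    d_plus = np.asarray(d_plus, dtype=float)
    d_minus = np.asarray(d_minus, dtype=float)
    if (d_plus < 0).any() or (d_minus < 0).any():
        raise ValueError("ideal-point distances must be non-negative")
    denom = d_plus + d_minus
    if (denom <= 0).any():
        raise DegenerateMatrixError(
            "an alternative coincides with both ideals (all columns constant)"
        )
    return d_minus / denom


def topsis_score(
    matrix: DecisionMatrix,
    weights: EntropyWeightResult | pd.Series | Mapping[str, float],
) -> TopsisResult:
    """Score and rank the matrix rows by relative closeness to the ideal."""
    if isinstance(weights, EntropyWeightResult):
        w = weights.weights
    else:
        w = pd.Series(weights, dtype=float)
    X = matrix.values.astype(float)
    w = w.reindex(X.columns)
    if w.isna().any():
        missing = w.index[w.isna()].tolist()
        raise KeyError(f"weights missing for column(s): {missing}")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1, got {w.sum()!r}")

    norms = np.sqrt((X**2).sum(axis=0))
    zero = norms.index[norms <= 0].tolist()
    if zero:
        raise UndefinedStatisticError(f"zero column norm(s): {zero}")
    V = (X / norms) * w

    pos = pd.Series(
        {c: (V[c].max() if matrix.sense(c) == "benefit" else V[c].min()) for c in V.columns}
    )
    neg = pd.Series(
        {c: (V[c].min() if matrix.sense(c) == "benefit" else V[c].max()) for c in V.columns}
    )
    d_plus = np.sqrt(((V - pos) ** 2).sum(axis=1))
    d_minus = np.sqrt(((V - neg) ** 2).sum(axis=1))
    closeness = pd.Series(
        closeness_from_distances(d_plus.to_numpy(), d_minus.to_numpy()), index=X.index
    )

    from .agglomeration import rank_descending

    table = pd.DataFrame(
        {
            "d_plus": d_plus,
            "d_minus": d_minus,
            "closeness": closeness,
            "rank": rank_descending(closeness).to_numpy(),
        }
    )
    table.index.name = X.index.name or "region_id"
    return TopsisResult(table=table)
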