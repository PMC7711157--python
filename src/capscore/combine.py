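"""Rank-based combination of predictor scores into a single severity score.

For each of the three tools, variants are ranked from most to least
structurally disruptive (rank 1 = most disruptive; tied scores share a
rank).  A rank ``r`` out of ``r_max`` ranked variants converts to the null
tail probability ``p = r / r_max``.  The three per-tool p-values combine as

    p_weighted = p_polyphen2 * sqrt(p_sift * p_provean)

PolyPhen-2 enters with full weight because it is algorithmically independent
of the other two; SIFT and PROVEAN, being closely related algorithms, are
treated as dependent and enter through their geometric mean.  p_weighted is
interpreted as a score rather than a calibrated probability; p_weighted <
0.05 marks a significantly disruptive variant, and severity classes are
severe (p_w < 0.01), moderate (0.01 <= p_w < 0.05) and mild (p_w >= 0.05) —
equivalently log10 thresholds of -2 and ~-1.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scores import CORE_TOOLS, TOOL_SPECS, oriented_table

__all__ = [
    "SEVERE_THRESHOLD",
    "SIGNIFICANCE_THRESHOLD",
    "RankVector",
    "rank_scores",
    "rank_to_p",
    "combine_pvalues",
    "classify_severity",
    "score_table",
    "write_combined_table",
]

SEVERE_THRESHOLD = 0.01
SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class RankVector:
    """Per-tool competition ranks, 1 = most disruptive."""

    tool_id: str
    ranks: pd.Series  # int ranks indexed like the input
    r_max: int
    tie_method: str

    def __post_init__(self) -> None:
        if len(self.ranks) and not (
            1 <= self.ranks.min() and self.ranks.max() <= self.r_max
        ):
            raise ValueError("ranks outside [1, r_max]")


def rank_scores(oriented: Mapping | pd.Series, tie_method: str = "min") -> RankVector:
    """Competition-rank oriented scores, ascending = most disruptive first.

    ``tie_method='min'`` gives every member of a tied block the block's top
    position (the default reading of "the highest rank was applied to each
    tied score", rank 1 being highest); ``'max'`` gives the block's bottom
    position.  ``r_max`` is the number of ranked variants, even when tie
    collapsing leaves the largest assigned rank smaller.
    """
    if tie_method not in ("min", "max"):
        raise ValueError(f"tie_method must be 'min' or 'max', got {tie_method!r}")
    series = pd.Series(oriented, dtype=float)
    if series.empty:
        raise ValueError("cannot rank an empty score set")
    if series.isna().any():
        bad = list(series.index[series.isna()])
        raise ValueError(f"non-finite sort key for variant(s) {bad}")
    ranks = pd.Series(
        rankdata(series.to_numpy(), method=tie_method).astype(int),
        index=series.index,
    )
    return RankVector(
        tool_id="", ranks=ranks, r_max=len(series), tie_method=tie_method
    )


def rank_to_p(r: int, r_max: int) -> float:
    """Null tail probability of a rank: p = r / r_max, in (0, 1]."""
    if not 1 <= r <= r_max:
        raise ValueError(f"rank {r} outside [1, {r_max}]")
    return r / r_max


def combine_pvalues(p_polyphen2: float, p_sift: float, p_provean: float) -> float:
    """p_weighted = p_polyphen2 * sqrt(p_sift * p_provean)."""
    for name, p in (
        ("p_polyphen2", p_polyphen2),
        ("p_sift", p_sift),
        ("p_provean", p_provean),
    ):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"{name} = {p} outside (0, 1]")
    return p_polyphen2 * math.sqrt(p_sift * p_provean)


def classify_severity(p_weighted: float, boundary_to_milder: bool = True) -> str:
    """Severity class of a combined score.

    severe: p_w < 0.01 (log10 < -2); moderate: 0.01-0.05; mild: p_w > 0.05.
    The boundary values 0.01 and 0.05, unassigned by the strict inequalities,
    go to the milder class by default.
    """
    if not 0.0 < p_weighted <= 1.0:
        raise ValueError(f"p_weighted = {p_weighted} outside (0, 1]")
    lo, hi = SEVERE_THRESHOLD, SIGNIFICANCE_THRESHOLD
    if boundary_to_milder:
        if p_weighted < lo:
            return "severe"
        if p_weighted < hi:
            return "moderate"
        return "mild"
    if p_weighted <= lo:
        return "severe"
    if p_weighted <= hi:
        return "moderate"
    return "mild"


def score_table(
    scores: pd.DataFrame,
    tie_method: str = "min",
    tools: Iterable[str] = CORE_TOOLS,
    boundary_to_milder: bool = True,
) -> pd.DataFrame:
    """End-to-end combined scoring of a merged raw-score table.

    Orients each tool, ranks, converts ranks to p-values, combines and
    classifies.  The result is sorted ascending by p_weighted (most
    disruptive first), ties broken by variant label, with columns
    site / mutation / p_<tool> / p_weighted / log10_pw / severity.
    """
    tools = tuple(tools)
    if len(tools) != 3:
        raise ValueError(
            "combined scoring needs exactly three tools: the independent one "
            "first, then the two dependent ones"
        )
    missing = [t for t in tools if t not in scores.columns]
    if missing:
        raise KeyError(f"score table lacks tool column(s) {missing}")
    oriented = oriented_table(scores, tools)
    n = len(scores)
    out = pd.DataFrame(index=scores.index.copy())
    if "position" in scores.columns:
        out["site"] = scores["position"].astype(int)
    out["mutation"] = scores.index
    p_cols = []
    for tool in tools:
        rv = rank_scores(oriented[tool], tie_method=tie_method)
        p = rv.ranks / rv.r_max
        col = f"p_{tool}"
        out[col] = p
        p_cols.append(col)
    pp, ps, pv = (out[f"p_{t}"] for t in tools)
    out["p_weighted"] = pp * np.sqrt(ps * pv)
    out["log10_pw"] = np.log10(out["p_weighted"])
    out["severity"] = [
        classify_severity(p, boundary_to_milder) for p in out["p_weighted"]
    ]
    out.attrs["tie_method"] = tie_method
    out.attrs["r_max"] = n
    out = out.sort_values(
        ["p_weighted", "mutation"], kind="mergesort", ascending=True
    )
    return out


def write_combined_table(combined: pd.DataFrame, path) -> None:
    """Serialize a combined table; p-values printed to 9 decimal places."""
    df = combined.copy()
    for col in df.columns:
        if col.startswith("p_") or col == "log10_pw":
            df[col] = df[col].map(lambda x: f"{x:.9f}")
    df.to_csv(path, sep="\t", index=False)
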