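"""Ingest and orientation of raw deleteriousness-predictor outputs.

Three tools feed the combined score: PolyPhen-2 (damaging probability in
[0, 1], higher = more disruptive), SIFT (tolerance probability in [0, 1],
lower = more disruptive) and PROVEAN (alignment-delta score, lower = more
disruptive).  FATHMM and CADD-PHRED are supported through the same generic
machinery for comparison analyses only.

Orientation maps every tool onto a common sort key in which *ascending*
order is most-disruptive-first; downstream ranking depends only on that
order, never on the raw scale.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .catalog import AMINO_ACIDS, Catalog, ParseError

__all__ = [
    "Direction",
    "ToolSpec",
    "CORE_TOOLS",
    "TOOL_SPECS",
    "PredictorScoreSet",
    "read_polyphen2_output",
    "read_provean_sift_output",
    "orient_score",
    "oriented_table",
    "merge_score_table",
    "write_score_table",
    "read_score_table",
]

HIGHER = "higher_is_disruptive"
LOWER = "lower_is_disruptive"
Direction = str


@dataclass(frozen=True)
class ToolSpec:
    """Identity, disruptiveness orientation, and valid range of one predictor."""

    tool_id: str
    direction: Direction
    valid_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER, LOWER):
            raise ValueError(f"unknown direction {self.direction!r}")

    def validate(self, score: float) -> float:
        if self.valid_range is not None:
            lo, hi = self.valid_range
            if not (lo <= score <= hi):
                raise ValueError(
                    f"{self.tool_id} score {score} outside valid range [{lo}, {hi}]"
                )
        return float(score)


TOOL_SPECS: dict[str, ToolSpec] = {
    "polyphen2": ToolSpec("polyphen2", HIGHER, (0.0, 1.0)),
    "sift": ToolSpec("sift", LOWER, (0.0, 1.0)),
    "provean": ToolSpec("provean", LOWER, None),
    "fathmm": ToolSpec("fathmm", LOWER, None),
    "cadd_phred": ToolSpec("cadd_phred", HIGHER, None),
}

#: The three tools that enter the combined p_weighted score.
CORE_TOOLS = ("polyphen2", "sift", "provean")


@dataclass
class PredictorScoreSet:
    """Raw scores of one variant across named tools."""

    variant_key: tuple[str, int, str]
    scores: dict[str, float] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)

    def complete_for(self, tools: Iterable[str] = CORE_TOOLS) -> bool:
        return all(t in self.scores for t in tools)


# Default column maps for the 2019-era batch dialects; callers may override
# when a service revision renames headers.
POLYPHEN2_COLUMNS = {
    "position": "o_pos",
    "ref_aa": "o_aa1",
    "alt_aa": "o_aa2",
    "score": "pph2_prob",
}
PROVEAN_SIFT_COLUMNS = {
    "position": "POSITION",
    "ref_aa": "RESIDUE_REF",
    "alt_aa": "RESIDUE_ALT",
    "provean": "SCORE",
    "sift": "SCORE.1",
}


def _read_tsv(table) -> pd.DataFrame:
    if isinstance(table, (str, Path, io.IOBase)):
        try:
            df = pd.read_csv(table, sep="\t", skipinitialspace=True)
        except pd.errors.EmptyDataError:
            return pd.DataFrame()
    else:
        df = pd.DataFrame(table)
    df.columns = [str(c).strip().lstrip("#").strip() for c in df.columns]
    return df


def _as_key(ref, pos, alt) -> tuple[str, int, str]:
    ref, alt = str(ref).strip(), str(alt).strip()
    if ref not in AMINO_ACIDS or alt not in AMINO_ACIDS:
        raise ParseError(f"malformed amino-acid token in substitution {ref}{pos}{alt}")
    return (ref, int(pos), alt)


def read_polyphen2_output(
    table, columns: Mapping[str, str] | None = None
) -> list[PredictorScoreSet]:
    """Parse a PolyPhen-2 batch report into score fragments.

    When a substitution appears on several rows (transcript isoforms), the
    maximum damaging probability is retained — the most conservative choice
    toward pathogenicity.
    """
    cols = dict(POLYPHEN2_COLUMNS, **(columns or {}))
    df = _read_tsv(table)
    if df.empty:
        return []
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ParseError(
            f"PolyPhen-2 table lacks expected column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    best: dict[tuple[str, int, str], float] = {}
    for _, row in df.iterrows():
        score = row[cols["score"]]
        if pd.isna(score):
            continue
        key = _as_key(row[cols["ref_aa"]], row[cols["position"]], row[cols["alt_aa"]])
        score = TOOL_SPECS["polyphen2"].validate(float(score))
        best[key] = max(best.get(key, score), score)
    return [
        PredictorScoreSet(variant_key=k, scores={"polyphen2": v})
        for k, v in best.items()
    ]


def read_provean_sift_output(
    table, columns: Mapping[str, str] | None = None
) -> tuple[list[PredictorScoreSet], list[str]]:
    """Parse the joint PROVEAN/SIFT batch report.

    Each well-formed row yields both tool entries for the variant key; a row
    with a missing cell stores what is present and records the gap in the
    fragment's ``missing`` set.  Unparseable substitution tokens are
    collected as row-level error strings and ingest continues.
    """
    cols = dict(PROVEAN_SIFT_COLUMNS, **(columns or {}))
    df = _read_tsv(table)
    fragments: dict[tuple[str, int, str], PredictorScoreSet] = {}
    errors: list[str] = []
    if df.empty:
        return [], errors
    missing_cols = [
        c for k, c in cols.items() if k in ("position", "ref_aa", "alt_aa")
        if c not in df.columns
    ]
    if missing_cols:
        raise ParseError(
            f"PROVEAN/SIFT table lacks expected column(s) {missing_cols}"
        )
    for i, row in df.iterrows():
        try:
            key = _as_key(
                row[cols["ref_aa"]], row[cols["position"]], row[cols["alt_aa"]]
            )
        except (ParseError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
            continue
        frag = fragments.setdefault(key, PredictorScoreSet(variant_key=key))
        for tool in ("provean", "sift"):
            value = row.get(cols[tool])
            if value is None or pd.isna(value):
                frag.missing.add(tool)
                continue
            value = TOOL_SPECS[tool].validate(float(value))
            if tool in frag.scores and frag.scores[tool] != value:
                errors.append(
                    f"row {i}: conflicting {tool} scores for "
                    f"{key[0]}{key[1]}{key[2]}"
                )
            frag.scores[tool] = value
            frag.missing.discard(tool)
    return list(fragments.values()), errors


def orient_score(spec: ToolSpec, score: float) -> float:
    """Sort key under which ascending order is most-disruptive-first."""
    score = spec.validate(score)
    return score if spec.direction == LOWER else -score


def oriented_table(scores: pd.DataFrame, tools: Iterable[str] = CORE_TOOLS) -> pd.DataFrame:
    """Apply per-tool orientation to a raw score table."""
    out = {}
    for tool in tools:
        spec = TOOL_SPECS[tool]
        col = scores[tool].astype(float)
        out[tool] = col if spec.direction == LOWER else -col
    return pd.DataFrame(out, index=scores.index)


@dataclass
class MergeReport:
    excluded: list[tuple[str, int, str]] = field(default_factory=list)
    orphans: list[tuple[str, int, str]] = field(default_factory=list)


def merge_score_table(
    catalog: Catalog,
    fragments: Iterable[PredictorScoreSet],
    tools: Iterable[str] = CORE_TOOLS,
    strict: bool = False,
) -> tuple[pd.DataFrame, MergeReport]:
    """Join predictor fragments onto catalog keys.

    Returns a DataFrame indexed by variant label (e.g. ``"R262W"``) with
    columns ref_aa/position/alt_aa plus one column per tool, restricted to
    variants carrying *all* requested tools (others land in the exclusion
    report and do not consume a rank downstream).  Scores for keys absent
    from the catalog are warnings, or errors in strict mode.
    """
    tools = tuple(tools)
    merged: dict[tuple[str, int, str], dict[str, float]] = {}
    report = MergeReport()
    for frag in fragments:
        if frag.variant_key not in catalog:
            report.orphans.append(frag.variant_key)
            if strict:
                raise KeyError(
                    f"score fragment for {frag.variant_key} not in catalog"
                )
            continue
        merged.setdefault(frag.variant_key, {}).update(frag.scores)
    rows = []
    for key in catalog.keys():
        scores = merged.get(key, {})
        if not all(t in scores for t in tools):
            report.excluded.append(key)
            continue
        ref, pos, alt = key
        row = {"ref_aa": ref, "position": pos, "alt_aa": alt}
        row.update({t: scores[t] for t in tools})
        rows.append((f"{ref}{pos}{alt}", row))
    df = pd.DataFrame(
        [r for _, r in rows], index=[label for label, _ in rows]
    )
    if df.empty:
        df = pd.DataFrame(columns=["ref_aa", "position", "alt_aa", *tools])
    return df, report


def write_score_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="variant")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant")
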