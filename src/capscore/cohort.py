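"""Group-level analyses downstream of combined scoring.

Covers disease-wise score distributions and two-sample t-tests, severity
proportions by phenotype and domain, sliding-window mutational-hotspot
detection, top-k overlap against an alternative scorer, and the
pathogenic-versus-benign distribution comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Catalog, Phenotype, unique_mutation_sets
from .domains import DomainMap, locate_position
from .scores import ToolSpec

__all__ = [
    "GroupComparison",
    "Hotspot",
    "distribution_by_group",
    "compare_groups_ttest",
    "severity_proportions",
    "detect_hotspots",
    "rank_overlap",
    "benign_compare",
    "filter_by_maf",
]

Key = tuple[str, int, str]


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_log10_pw_a: float
    mean_log10_pw_b: float
    welch: bool = False


@dataclass(frozen=True)
class Hotspot:
    """A residue interval with an elevated count of distinct mutated sites."""

    start: int
    end: int
    count: int
    window: int
    members: tuple = ()


def _label(key: Key) -> str:
    return f"{key[0]}{key[1]}{key[2]}"


def distribution_by_group(
    combined: pd.DataFrame,
    catalog: Catalog,
    unique_only: bool = False,
) -> dict[Phenotype, np.ndarray]:
    """Per-phenotype arrays of log10 p_weighted.

    A variant reported under several phenotypes contributes its score to each
    of them; with ``unique_only``, only variants annotated with exactly one
    phenotype contribute, and only to that phenotype.  Phenotypes with no
    member are present with an empty array.
    """
    log10 = combined["log10_pw"]
    out: dict[Phenotype, list[float]] = {p: [] for p in Phenotype}
    if unique_only:
        for pheno, keys in unique_mutation_sets(catalog).items():
            for key in keys:
                label = _label(key)
                if label in log10.index:
                    out[pheno].append(float(log10[label]))
    else:
        for key in catalog.keys():
            label = _label(key)
            if label not in log10.index:
                continue
            for pheno in catalog.phenotypes_of(key):
                out[pheno].append(float(log10[label]))
    return {p: np.sort(np.asarray(v, dtype=float)) for p, v in out.items()}


def compare_groups_ttest(
    a: Sequence[float],
    b: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided unpaired t-test between two groups of log10 p_weighted.

    Equal-variance (Student's) by default; Welch behind a flag.  Two
    identical zero-variance groups compare as statistic 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations for a t-test")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in group comparison")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0 and a.mean() == b.mean():
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        stat, p = float(stat), float(p)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        statistic=stat,
        p_value=p,
        n_a=len(a),
        n_b=len(b),
        mean_log10_pw_a=float(a.mean()),
        mean_log10_pw_b=float(b.mean()),
        welch=welch,
    )


def severity_proportions(
    combined: pd.DataFrame,
    catalog: Catalog | None = None,
    domain_map: DomainMap | None = None,
    group_by: Sequence[str] = ("phenotype",),
    unique_only: bool = False,
) -> pd.DataFrame:
    """Nested severity-class proportions.

    ``group_by`` may contain "phenotype" (needs a catalog) and/or "domain" /
    "subdomain" (needs a domain map); proportions of severe/moderate/mild
    sum to 1 within each outer group, with counts preserved alongside.
    """
    allowed = {"phenotype", "domain", "subdomain"}
    if any(g not in allowed for g in group_by):
        raise ValueError(f"group_by entries must be among {sorted(allowed)}")
    if "phenotype" in group_by and catalog is None:
        raise ValueError("phenotype grouping requires a catalog")
    if ({"domain", "subdomain"} & set(group_by)) and domain_map is None:
        raise ValueError("domain grouping requires a domain map")

    records = []
    if catalog is not None:
        for key in catalog.keys():
            label = _label(key)
            if label not in combined.index:
                continue
            severity = combined.loc[label, "severity"]
            phenos = catalog.phenotypes_of(key)
            if unique_only:
                if len(phenos) != 1:
                    continue
            for pheno in phenos:
                rec = {"severity": severity}
                if "phenotype" in group_by:
                    rec["phenotype"] = pheno.value
                if "domain" in group_by or "subdomain" in group_by:
                    loc = locate_position(key[1], domain_map)
                    if "domain" in group_by:
                        rec["domain"] = loc.domain
                    if "subdomain" in group_by:
                        rec["subdomain"] = loc.subdomain or loc.domain
                records.append(rec)
                if "phenotype" not in group_by:
                    break
    else:
        for label, row in combined.iterrows():
            rec = {"severity": row["severity"]}
            if "domain" in group_by or "subdomain" in group_by:
                loc = locate_position(int(row["site"]), domain_map)
                if "domain" in group_by:
                    rec["domain"] = loc.domain
                if "subdomain" in group_by:
                    rec["subdomain"] = loc.subdomain or loc.domain
            records.append(rec)

    df = pd.DataFrame(records)
    if df.empty:
        return pd.DataFrame(columns=[*group_by, "severity", "count", "proportion"])
    outer = [g for g in group_by]
    counts = (
        df.groupby([*outer, "severity"], observed=True).size().rename("count").reset_index()
        if outer
        else df.groupby("severity").size().rename("count").reset_index()
    )
    if outer:
        totals = counts.groupby(outer, observed=True)["count"].transform("sum")
    else:
        totals = counts["count"].sum()
    counts["proportion"] = counts["count"] / totals
    return counts


def detect_hotspots(
    positions: Iterable[int],
    window: int = 10,
    min_count: int = 3,
    members: Mapping[int, Iterable[Key]] | None = None,
) -> list[Hotspot]:
    """Sliding-window scan for residue intervals dense in distinct mutated sites.

    A block of ``min_count`` consecutive distinct positions qualifies when it
    fits inside a ``window``-residue interval; overlapping qualifying blocks
    merge into maximal runs.  Returned intervals are disjoint, each spanning
    the first to last mutated residue of its run.  Defaults (window 10,
    min_count 3) recover the canonical CAPS hotspots; both parameters are
    analysis choices and are recorded on the output.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if min_count < 2:
        raise ValueError("min_count must be >= 2")
    distinct = sorted(set(int(p) for p in positions))
    if len(distinct) < min_count:
        return []
    runs: list[list[int]] = []  # index ranges [i, j] into distinct
    for i in range(len(distinct) - min_count + 1):
        j = i + min_count - 1
        if distinct[j] - distinct[i] <= window - 1:
            if runs and i <= runs[-1][1]:
                runs[-1][1] = j
            else:
                runs.append([i, j])
    hotspots = []
    for i, j in runs:
        posns = distinct[i : j + 1]
        mem: list[Key] = []
        if members is not None:
            for p in posns:
                mem.extend(members.get(p, ()))
        hotspots.append(
            Hotspot(
                start=posns[0],
                end=posns[-1],
                count=len(posns),
                window=window,
                members=tuple(mem),
            )
        )
    return hotspots


def rank_overlap(
    set_a: Iterable[Key],
    ranking_b: Mapping[Key, float],
    spec: ToolSpec,
    k: int,
) -> dict:
    """Intersection of a variant set with the top-k of an alternative ranking.

    ``ranking_b`` holds raw scores of the alternative tool; orientation per
    its ToolSpec puts the most disruptive first.  Boundary ties break by
    variant key for determinism.
    """
    set_a = set(set_a)
    if k > len(ranking_b):
        raise ValueError(f"k = {k} exceeds ranking coverage {len(ranking_b)}")
    sign = 1.0 if spec.direction == "lower_is_disruptive" else -1.0
    ordered = sorted(ranking_b, key=lambda key: (sign * ranking_b[key], key))
    top_k = set(ordered[:k])
    shared = set_a & top_k
    return {"shared": shared, "count": len(shared), "k": k}


def filter_by_maf(
    table: pd.DataFrame, maf_column: str = "maf", threshold: float = 0.001
) -> pd.DataFrame:
    """Retain rows with minor allele frequency strictly below the threshold."""
    return table[table[maf_column] < threshold]


def benign_compare(
    pathogenic: Sequence[float], benign: Sequence[float]
) -> dict:
    """Symmetric summary of pathogenic vs benign log10 p_weighted distributions.

    Reports group means/medians, the two-sample (Student) t-test, and
    Cohen's d.  The benign list is expected to be MAF-filtered upstream; no
    classification decision is made here.
    """
    pathogenic = np.asarray(pathogenic, dtype=float)
    benign = np.asarray(benign, dtype=float)
    if pathogenic.size == 0 or benign.size == 0:
        raise ValueError("both pathogenic and benign lists must be non-empty")
    comp = compare_groups_ttest(
        pathogenic, benign, group_a="pathogenic", group_b="benign"
    )
    n_a, n_b = pathogenic.size, benign.size
    pooled_var = (
        (n_a - 1) * pathogenic.var(ddof=1) + (n_b - 1) * benign.var(ddof=1)
    ) / (n_a + n_b - 2)
    d = 0.0 if pooled_var == 0 else float(
        (pathogenic.mean() - benign.mean()) / np.sqrt(pooled_var)
    )
    return {
        "mean_pathogenic": float(pathogenic.mean()),
        "mean_benign": float(benign.mean()),
        "median_pathogenic": float(np.median(pathogenic)),
        "median_benign": float(np.median(benign)),
        "n_pathogenic": int(n_a),
        "n_benign": int(n_b),
        "t_statistic": comp.statistic,
        "p_value": comp.p_value,
        "cohen_d": d,
    }
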