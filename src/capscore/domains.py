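"""Residue-level domain annotation for NLRP3.

NLRP3 (1036 aa) comprises an N-terminal pyrin (PYR) domain, a central NACHT
nucleotide-binding module subdivided into NBD, HD1, WHD and HD2, and a
C-terminal leucine-rich-repeat (LRR) region, with conserved nucleotide-
binding motifs (Walker A/B, Sensor 1/2, GxP) inside NACHT.  The default map
shipped with the package uses 1-based inclusive residue intervals chosen to
satisfy the memberships reported for this protein (e.g. Arg262 and Asp305 in
the NBD, Trp416/Phe525/Glu527 in the WHD, Gly757 in the LRR); exact
subdomain borders are not standardized and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Interval",
    "DomainLabels",
    "DomainMap",
    "load_domain_map",
    "default_domain_map",
    "locate_position",
    "domain_composition",
]

INTER_DOMAIN = "inter-domain"


@dataclass(frozen=True)
class Interval:
    """Named 1-based inclusive residue interval."""

    name: str
    start: int
    end: int
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.name}: [{self.start}, {self.end}]"
            )

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class DomainLabels:
    domain: str
    subdomain: str | None
    motifs: tuple[str, ...]


@dataclass
class DomainMap:
    """Ordered top-level domains, nested subdomains, and motifs."""

    domains: list[Interval]
    subdomains: list[Interval] = field(default_factory=list)
    motifs: list[Interval] = field(default_factory=list)
    protein_length: int = 1036

    def __post_init__(self) -> None:
        self.domains = sorted(self.domains, key=lambda i: i.start)
        for iv in [*self.domains, *self.subdomains, *self.motifs]:
            if iv.end > self.protein_length:
                raise ValueError(
                    f"{iv.name} extends past protein length {self.protein_length}"
                )
        for a, b in zip(self.domains, self.domains[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"top-level domains {a.name} and {b.name} overlap"
                )
        by_name = {d.name: d for d in self.domains}
        for sub in self.subdomains:
            parent = by_name.get(sub.parent or "")
            if parent is None:
                raise ValueError(f"subdomain {sub.name} has unknown parent {sub.parent!r}")
            if not (parent.start <= sub.start and sub.end <= parent.end):
                raise ValueError(
                    f"subdomain {sub.name} not nested within {parent.name}"
                )


def load_domain_map(config: str | Path | pd.DataFrame) -> DomainMap:
    """Build a validated DomainMap from a key/value TSV config.

    Expected columns: kind (length|domain|subdomain|motif), name, start, end,
    parent (for nested intervals).
    """
    if isinstance(config, pd.DataFrame):
        df = config
    else:
        df = pd.read_csv(config, sep="\t", keep_default_na=False)
    length = 0
    domains, subdomains, motifs = [], [], []
    for _, row in df.iterrows():
        kind = str(row["kind"]).strip()
        if kind == "length":
            length = int(row["end"])
            continue
        iv = Interval(
            name=str(row["name"]),
            start=int(row["start"]),
            end=int(row["end"]),
            parent=str(row.get("parent", "")) or None,
        )
        {"domain": domains, "subdomain": subdomains, "motif": motifs}[kind].append(iv)
    if not domains:
        raise ValueError("domain map config defines no top-level domains")
    if length == 0:
        length = max(iv.end for iv in domains)
    return DomainMap(
        domains=domains, subdomains=subdomains, motifs=motifs, protein_length=length
    )


def default_domain_map() -> DomainMap:
    """The packaged NLRP3 map (PYR 1-100, NACHT 131-675 with NBD/HD1/WHD/HD2,
    LRR 676-1036, plus nucleotide-binding motifs)."""
    src = resources.files("capscore.data").joinpath("nlrp3_domains.tsv")
    with resources.as_file(src) as p:
        return load_domain_map(p)


def locate_position(pos: int, domain_map: DomainMap) -> DomainLabels:
    """Deterministic domain/subdomain/motif labels of one residue."""
    if not 1 <= pos <= domain_map.protein_length:
        raise ValueError(
            f"position {pos} outside [1, {domain_map.protein_length}]"
        )
    domain = next((d.name for d in domain_map.domains if pos in d), INTER_DOMAIN)
    subdomain = next((s.name for s in domain_map.subdomains if pos in s), None)
    motifs = tuple(m.name for m in domain_map.motifs if pos in m)
    return DomainLabels(domain=domain, subdomain=subdomain, motifs=motifs)


def domain_composition(
    keys: Iterable[tuple[str, int, str]],
    domain_map: DomainMap,
    level: str = "domain",
) -> pd.DataFrame:
    """Counts and proportions of a variant set per domain (or subdomain).

    Proportions sum to 1 over the table; positions falling in no interval
    are tabulated as "inter-domain" (or, at subdomain level, under their
    top-level domain name).
    """
    if level not in ("domain", "subdomain"):
        raise ValueError("level must be 'domain' or 'subdomain'")
    labels = []
    for key in keys:
        loc = locate_position(key[1], domain_map)
        if level == "domain":
            labels.append(loc.domain)
        else:
            labels.append(loc.subdomain if loc.subdomain else loc.domain)
    if not labels:
        return pd.DataFrame(columns=["count", "proportion"])
    counts = pd.Series(labels).value_counts().sort_index()
    out = pd.DataFrame({"count": counts})
    out["proportion"] = out["count"] / out["count"].sum()
    return out
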