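"""Curation of the literature-derived NLRP3 missense compendium.

The compendium lists protein-level substitutions (e.g. ``R262W``) grouped by
disease phenotype, each with one or more cDNA notations and literature tags.
This module parses that notation, canonicalizes residue numbering to the
first methionine (M1), checks cDNA/protein position consistency, and builds a
deduplicated catalog keyed by protein substitution.

Residue numbering: many primary reports count NLRP3 residues from the second
methionine (M3, residue 3 of the canonical sequence), so M3-based positions
are exactly 2 lower than M1-based ones.  cDNA positions in the compendium
follow the M3 start codon even when protein positions are M1-based, so the
expected residue for a cDNA position ``c`` is ``ceil(c / 3) + 2``.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "Phenotype",
    "NumberingOrigin",
    "MissenseVariant",
    "DiseaseAnnotation",
    "Catalog",
    "ConsistencyReport",
    "ParseError",
    "parse_variant_notation",
    "parse_cdna",
    "renumber_m3_to_m1",
    "check_position_consistency",
    "expected_position",
    "load_compendium",
    "build_catalog",
    "load_default_catalog",
    "unique_mutation_sets",
    "write_catalog",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_VARIANT_RE = re.compile(
    r"(?P<ref>[A-Za-z])(?P<pos>\d+)(?P<alt>[A-Za-z])\s*"
    r"(?:\((?P<cdna>[^)]*)\))?"
    r"(?:\s*\^(?P<note>[^^]*)\^)?"
)
_CDNA_RE = re.compile(r"c\.(?P<pos>\d+)(?P<ref>[ACGT])>(?P<alt>[ACGT])")


class ParseError(ValueError):
    """Raised when a compendium cell cannot be interpreted."""


class Phenotype(str, Enum):
    """Closed disease-phenotype vocabulary of the compendium."""

    FCAS = "FCAS"
    MWS = "MWS"
    MOSAIC_MWS = "mosaic_MWS"
    CINCA_NOMID = "CINCA_NOMID"
    MOSAIC_CINCA_NOMID = "mosaic_CINCA_NOMID"
    MOSAIC_NLRP3_AID = "mosaic_NLRP3_AID"
    UNSPECIFIED_CAPS = "unspecified_CAPS"
    UNSPECIFIED_NONCAPS_AID = "unspecified_nonCAPS_AID"
    JIA = "JIA"
    RA = "RA"
    OTHER_UNKNOWN = "other_unknown"


MOSAIC_PHENOTYPES = frozenset(
    {Phenotype.MOSAIC_MWS, Phenotype.MOSAIC_CINCA_NOMID, Phenotype.MOSAIC_NLRP3_AID}
)


class NumberingOrigin(str, Enum):
    M1 = "M1"
    M3 = "M3"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class MissenseVariant:
    """A single protein-level substitution with its cDNA notations."""

    ref_aa: str
    position: int
    alt_aa: str
    cdna_changes: tuple[str, ...] = ()
    numbering_origin: NumberingOrigin = NumberingOrigin.M1

    def __post_init__(self) -> None:
        if self.ref_aa not in AMINO_ACIDS:
            raise ParseError(f"invalid reference amino acid {self.ref_aa!r}")
        if self.alt_aa not in AMINO_ACIDS:
            raise ParseError(f"invalid alternate amino acid {self.alt_aa!r}")
        if self.ref_aa == self.alt_aa:
            raise ParseError(
                f"{self.ref_aa}{self.position}{self.alt_aa} is synonymous, not missense"
            )
        if self.position < 1:
            raise ParseError(f"residue position must be >= 1, got {self.position}")
        for c in self.cdna_changes:
            m = _CDNA_RE.fullmatch(c)
            if m is None:
                raise ParseError(f"malformed cDNA change {c!r}")
            if m.group("ref") == m.group("alt"):
                raise ParseError(f"cDNA change {c!r} has identical ref and alt bases")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.ref_aa, self.position, self.alt_aa)

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class DiseaseAnnotation:
    """One phenotype report of a variant, with provenance tags."""

    phenotype: Phenotype
    overlap_note: str = ""
    mosaic: bool = False
    references: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = Phenotype(self.phenotype) in MOSAIC_PHENOTYPES
        if self.mosaic != expected:
            raise ValueError(
                f"mosaic flag {self.mosaic} inconsistent with phenotype "
                f"{self.phenotype}"
            )


@dataclass
class CatalogEntry:
    variant: MissenseVariant
    annotations: list[DiseaseAnnotation] = field(default_factory=list)


@dataclass
class Catalog:
    """Deduplicated compendium keyed by (ref_aa, position, alt_aa)."""

    entries: dict[tuple[str, int, str], CatalogEntry] = field(default_factory=dict)

    @property
    def n(self) -> int:
        """Number of unique protein-level substitutions (the ranking r_max basis)."""
        return len(self.entries)

    def __len__(self) -> int:
        return self.n

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self.entries

    def keys(self):
        return self.entries.keys()

    def variant(self, key: tuple[str, int, str]) -> MissenseVariant:
        return self.entries[key].variant

    def annotations(self, key: tuple[str, int, str]) -> list[DiseaseAnnotation]:
        return self.entries[key].annotations

    def phenotypes_of(self, key: tuple[str, int, str]) -> set[Phenotype]:
        return {a.phenotype for a in self.entries[key].annotations}

    def incidence(self) -> pd.DataFrame:
        """Boolean disease x variant incidence table."""
        index = sorted(self.entries, key=lambda k: (k[1], k[0], k[2]))
        data = {
            p.value: [p in self.phenotypes_of(k) for k in index] for p in Phenotype
        }
        labels = [f"{r}{pos}{a}" for r, pos, a in index]
        return pd.DataFrame(data, index=labels)


@dataclass(frozen=True)
class CdnaCheck:
    cdna: str
    cdna_position: int
    expected_position: int
    consistent: bool


@dataclass(frozen=True)
class ConsistencyReport:
    variant: MissenseVariant
    checks: tuple[CdnaCheck, ...]

    @property
    def consistent(self) -> bool:
        return all(c.consistent for c in self.checks)


def parse_cdna(text: str) -> tuple[str, ...]:
    """Split a cDNA cell like ``"c.907G>A; c.913G>A"`` into validated tokens."""
    tokens = [t.strip() for t in re.split(r"[;,]", text) if t.strip()]
    out = []
    for tok in tokens:
        if _CDNA_RE.fullmatch(tok) is None:
            raise ParseError(f"malformed cDNA change {tok!r}")
        out.append(tok)
    return tuple(out)


def parse_variant_notation(
    text: str, numbering_origin: NumberingOrigin = NumberingOrigin.M1
) -> list[tuple[MissenseVariant, str]]:
    """Parse a compendium cell into (variant, note) pairs.

    A cell is a comma-delimited run of entries like ``"V200M (c.562G>A)"``;
    one protein change may carry several cDNA notations separated by
    semicolons inside the parentheses, and an entry may be followed by a
    superscript-style note delimited by carets.
    """
    if not text.strip():
        return []
    results: list[tuple[MissenseVariant, str]] = []
    pos = 0
    while pos < len(text):
        m = _VARIANT_RE.search(text, pos)
        if m is None:
            remainder = text[pos:].strip(" ,;")
            if remainder:
                raise ParseError(f"unparseable compendium span {remainder!r}")
            break
        ref, alt = m.group("ref").upper(), m.group("alt").upper()
        if ref not in AMINO_ACIDS or alt not in AMINO_ACIDS:
            raise ParseError(
                f"malformed amino-acid token in {text[m.start():m.end()]!r}"
            )
        cdna = parse_cdna(m.group("cdna")) if m.group("cdna") else ()
        variant = MissenseVariant(
            ref_aa=ref,
            position=int(m.group("pos")),
            alt_aa=alt,
            cdna_changes=cdna,
            numbering_origin=numbering_origin,
        )
        results.append((variant, (m.group("note") or "").strip()))
        pos = m.end()
    return results


def serialize_variant(v: MissenseVariant, note: str = "") -> str:
    """Inverse of :func:`parse_variant_notation` for a single entry."""
    s = str(v)
    if v.cdna_changes:
        s += " (" + "; ".join(v.cdna_changes) + ")"
    if note:
        s += f" ^{note}^"
    return s


def renumber_m3_to_m1(v: MissenseVariant) -> MissenseVariant:
    """Shift an M3-numbered variant to canonical M1 numbering (+2 residues).

    M3 is residue 3 of the canonical sequence, so positions counted from it
    are exactly 2 lower.  Applying this to an already-M1 variant warns and
    returns it unchanged.
    """
    if v.numbering_origin is NumberingOrigin.M1:
        warnings.warn(
            f"{v} is already M1-numbered; renumbering is a no-op", stacklevel=2
        )
        return v
    return replace(v, position=v.position + 2, numbering_origin=NumberingOrigin.M1)


def expected_position(cdna_position: int) -> int:
    """M1-based residue implied by an M3-anchored cDNA position."""
    return math.ceil(cdna_position / 3) + 2


def check_position_consistency(v: MissenseVariant) -> ConsistencyReport:
    """Flag cDNA notations whose implied residue disagrees with the protein one.

    cDNA positions are interpreted against the M3 start codon (the
    compendium's dominant convention) while protein positions are M1-based.
    Inconsistencies are findings, never corrections.
    """
    checks = []
    for c in v.cdna_changes:
        cpos = int(_CDNA_RE.fullmatch(c).group("pos"))
        exp = expected_position(cpos)
        checks.append(
            CdnaCheck(
                cdna=c,
                cdna_position=cpos,
                expected_position=exp,
                consistent=(exp == v.position),
            )
        )
    return ConsistencyReport(variant=v, checks=tuple(checks))


def load_compendium(path: str | Path | None = None) -> pd.DataFrame:
    """Read a compendium TSV (phenotype, protein_change, cdna_changes, mosaic,
    notes, refs).  With no path, loads the packaged NLRP3 compendium."""
    if path is None:
        src = resources.files("capscore.data").joinpath("nlrp3_compendium.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"phenotype", "protein_change", "cdna_changes", "mosaic", "notes", "refs"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"compendium missing columns: {sorted(missing)}")
    return df


def build_catalog(rows: pd.DataFrame | Iterable[Mapping]) -> Catalog:
    """Assemble a deduplicated catalog from compendium rows.

    Identical (ref, pos, alt) keys reported under several diseases collapse
    to one entry whose annotation list carries every report.  Conflicting
    reference residues at one position+alt are a hard error.
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")
    catalog = Catalog()
    ref_at: dict[int, str] = {}
    for row in rows:
        phenotype = Phenotype(row["phenotype"])
        parsed = parse_variant_notation(str(row["protein_change"]))
        if len(parsed) != 1:
            raise ParseError(
                f"expected one protein change per row, got {row['protein_change']!r}"
            )
        variant, _ = parsed[0]
        cdna = parse_cdna(str(row.get("cdna_changes", "") or ""))
        variant = replace(variant, cdna_changes=cdna)
        refs = tuple(t for t in str(row.get("refs", "")).split(";") if t)
        ann = DiseaseAnnotation(
            phenotype=phenotype,
            overlap_note=str(row.get("notes", "") or ""),
            mosaic=phenotype in MOSAIC_PHENOTYPES,
            references=refs,
        )
        key = variant.key
        seen_ref = ref_at.setdefault(key[1], key[0])
        if seen_ref != key[0]:
            raise ValueError(
                f"catalog corruption: position {key[1]} reported with reference "
                f"residues {seen_ref} and {key[0]}"
            )
        entry = catalog.entries.setdefault(key, CatalogEntry(variant=variant))
        if variant.cdna_changes and not entry.variant.cdna_changes:
            entry.variant = variant
        entry.annotations.append(ann)
    return catalog


def load_default_catalog() -> Catalog:
    """Catalog built from the packaged NLRP3 compendium (177 unique variants)."""
    return build_catalog(load_compendium())


def unique_mutation_sets(
    catalog: Catalog,
) -> dict[Phenotype, set[tuple[str, int, str]]]:
    """Variants annotated with exactly one phenotype, keyed by that phenotype."""
    out: dict[Phenotype, set[tuple[str, int, str]]] = {p: set() for p in Phenotype}
    for key in catalog.keys():
        phenos = catalog.phenotypes_of(key)
        if len(phenos) == 1:
            out[next(iter(phenos))].add(key)
    return out


def write_compendium(catalog: Catalog, path: str | Path) -> None:
    """Serialize a catalog back to compendium format, one row per annotation;
    inverse of :func:`build_catalog` up to row order."""
    rows = []
    for key in sorted(catalog.keys(), key=lambda k: (k[1], k[0], k[2])):
        entry = catalog.entries[key]
        for ann in entry.annotations:
            rows.append(
                {
                    "phenotype": ann.phenotype.value,
                    "protein_change": str(entry.variant),
                    "cdna_changes": ";".join(entry.variant.cdna_changes),
                    "mosaic": int(ann.mosaic),
                    "notes": ann.overlap_note,
                    "refs": ";".join(ann.references),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    """Serialize a catalog to TSV, one row per unique variant."""
    rows = []
    for key in sorted(catalog.keys(), key=lambda k: (k[1], k[0], k[2])):
        entry = catalog.entries[key]
        rows.append(
            {
                "variant": str(entry.variant),
                "position": key[1],
                "cdna_changes": ";".join(entry.variant.cdna_changes),
                "phenotypes": ";".join(
                    sorted(p.value for p in catalog.phenotypes_of(key))
                ),
                "n_reports": len(entry.annotations),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
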