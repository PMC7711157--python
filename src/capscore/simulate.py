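"""Synthetic cohorts with the statistical structure the scoring model assumes.

The generator emulates the *inputs* of the pipeline — a compendium of
missense variants with disease labels and a three-tool raw score table — not
the predictors themselves.  Its moving parts mirror the analysis
assumptions:

* a latent per-variant disruptiveness (higher = more disruptive) with an
  additive per-phenotype severity shift, in log10-score units;
* PolyPhen-2 as an increasing sigmoidal transform of the latent plus
  independent noise; SIFT and PROVEAN as decreasing transforms of latents
  sharing a correlated noise component (the two algorithms are closely
  related, so their scores co-vary);
* residue positions drawn from a mixture of a uniform background and
  Gaussian bumps at configurable hotspot centers;
* an optional benign set whose latent is shifted toward harmless, with
  minor-allele frequencies straddling the 0.001 rarity filter.

Only rank structure matters downstream (the combined score is invariant to
monotone per-tool transforms), so the marginal shapes are phenomenological.
A brute-force enumeration of the null distribution of p_weighted is provided
as an exact oracle for small cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog import (
    MOSAIC_PHENOTYPES,
    Catalog,
    CatalogEntry,
    DiseaseAnnotation,
    MissenseVariant,
    Phenotype,
)

__all__ = [
    "SyntheticConfig",
    "generate_cohort",
    "generate_benign_set",
    "generate_null_scores",
    "null_pweighted_samples",
    "null_distribution_oracle",
]

_AA = sorted("ACDEFGHIKLMNPQRSTVWY")

# Default phenotype mix follows the germline CAPS report counts of the
# packaged compendium (FCAS 20 : MWS 36 : CINCA/NOMID 73); default severity
# shifts encode the observed ordering in which FCAS variants score as the
# most structurally disruptive.
_DEFAULT_WEIGHTS = {
    Phenotype.FCAS: 20 / 129,
    Phenotype.MWS: 36 / 129,
    Phenotype.CINCA_NOMID: 73 / 129,
}
_DEFAULT_SHIFTS = {
    Phenotype.FCAS: 1.0,
    Phenotype.MWS: 0.5,
    Phenotype.CINCA_NOMID: 0.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic cohort; defaults follow the NLRP3
    compendium scale (177 variants, 1036-residue protein, three CAPS
    hotspots)."""

    n_variants: int = 177
    phenotype_weights: Mapping[Phenotype, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    severity_shift: Mapping[Phenotype, float] = field(
        default_factory=lambda: dict(_DEFAULT_SHIFTS)
    )
    latent_sd: float = 0.5
    sift_provean_correlation: float = 0.8
    hotspot_centers: tuple[int, ...] = (264, 308, 503)
    hotspot_sd: float = 4.0
    hotspot_fraction: float = 0.5
    protein_length: int = 1036
    benign_n: int = 100
    benign_shift: float = 1.0
    tie_fraction: float = 0.0
    balanced_phenotypes: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        weights = {Phenotype(k): v for k, v in self.phenotype_weights.items()}
        if any(w < 0 for w in weights.values()) or not math.isclose(
            sum(weights.values()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("phenotype_weights must be non-negative and sum to 1")
        if not 0.0 <= self.sift_provean_correlation < 1.0:
            raise ValueError("sift_provean_correlation must be in [0, 1)")
        for name in ("hotspot_fraction", "tie_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.latent_sd <= 0 or self.hotspot_sd <= 0:
            raise ValueError("latent_sd and hotspot_sd must be positive")
        if self.protein_length < 1 or self.benign_n < 0:
            raise ValueError("protein_length and benign_n must be positive")
        for c in self.hotspot_centers:
            if not 1 <= c <= self.protein_length:
                raise ValueError(f"hotspot center {c} outside protein")


def _substream(cfg: SyntheticConfig, label: int) -> np.random.Generator:
    # one global seed; deterministic per-stage substreams derived from it
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, label]))


def _draw_positions(cfg: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    hot = rng.random(n) < cfg.hotspot_fraction
    pos = rng.integers(1, cfg.protein_length + 1, size=n)
    if hot.any() and cfg.hotspot_centers:
        centers = rng.choice(np.asarray(cfg.hotspot_centers), size=int(hot.sum()))
        bumps = np.rint(rng.normal(centers, cfg.hotspot_sd)).astype(int)
        pos[hot] = np.clip(bumps, 1, cfg.protein_length)
    return pos


def _keys_for_positions(
    positions: np.ndarray, rng: np.random.Generator
) -> list[tuple[str, int, str]]:
    """Unique (ref, pos, alt) keys; the reference residue is a deterministic
    function of position so one position never carries two references."""
    keys: list[tuple[str, int, str]] = []
    seen: set[tuple[str, int, str]] = set()
    for pos in positions:
        pos = int(pos)
        key = None
        while key is None:
            ref = _AA[pos % 20]
            alts = [a for a in _AA if a != ref]
            rng.shuffle(alts)
            for alt in alts:
                if (ref, pos, alt) not in seen:
                    key = (ref, pos, alt)
                    break
            else:  # all 19 substitutions taken; walk to the next residue
                pos = pos + 1
        seen.add(key)
        keys.append(key)
    return keys


def _scores_from_latent(
    latent: np.ndarray, rho: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Tool-specific marginals: increasing sigmoid for PolyPhen-2, decreasing
    sigmoid for SIFT, decreasing affine for PROVEAN; SIFT and PROVEAN share a
    correlated noise component with weight sqrt(rho)."""
    n = len(latent)
    noise_pp = rng.normal(0.0, 0.3, n)
    shared = rng.normal(0.0, 0.3, n)
    eps_sift = rng.normal(0.0, 0.3, n)
    eps_prov = rng.normal(0.0, 0.3, n)
    w_shared, w_own = math.sqrt(rho), math.sqrt(1.0 - rho)
    sift_latent = latent + w_shared * shared + w_own * eps_sift
    prov_latent = latent + w_shared * shared + w_own * eps_prov
    polyphen2 = 1.0 / (1.0 + np.exp(-(latent + noise_pp)))
    sift = 1.0 / (1.0 + np.exp(sift_latent))
    provean = -2.5 * prov_latent - 2.0
    return pd.DataFrame(
        {
            "polyphen2": np.clip(polyphen2, 0.0, 1.0),
            "sift": np.clip(sift, 0.0, 1.0),
            "provean": provean,
        }
    )


def _assign_phenotypes(
    cfg: SyntheticConfig, rng: np.random.Generator, n: int
) -> list[Phenotype]:
    labels = [Phenotype(k) for k in cfg.phenotype_weights]
    weights = np.asarray([cfg.phenotype_weights[k] for k in labels], dtype=float)
    if cfg.balanced_phenotypes:
        counts = np.floor(weights * n).astype(int)
        remainder = weights * n - counts
        for i in np.argsort(-remainder)[: n - counts.sum()]:
            counts[i] += 1
        assigned = [lab for lab, c in zip(labels, counts) for _ in range(int(c))]
        rng.shuffle(assigned)
        return assigned
    idx = rng.choice(len(labels), size=n, p=weights / weights.sum())
    return [labels[i] for i in idx]


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[Catalog, pd.DataFrame, pd.DataFrame]:
    """Generate (catalog, raw score table, truth table), reproducibly from
    the config's seed.

    The truth table records each variant's phenotype, latent disruptiveness
    and injected shift, so recovery analyses can compare estimates against
    ground truth.
    """
    cfg.validate()
    rng_pos = _substream(cfg, 1)
    rng_key = _substream(cfg, 2)
    rng_pheno = _substream(cfg, 3)
    rng_latent = _substream(cfg, 4)
    rng_scores = _substream(cfg, 5)
    rng_ties = _substream(cfg, 6)

    n = cfg.n_variants
    positions = _draw_positions(cfg, rng_pos, n)
    keys = _keys_for_positions(positions, rng_key)
    phenotypes = _assign_phenotypes(cfg, rng_pheno, n)
    shifts = np.asarray(
        [float(cfg.severity_shift.get(p, 0.0)) for p in phenotypes]
    )
    latent = rng_latent.normal(0.0, cfg.latent_sd, n) + shifts
    scores = _scores_from_latent(latent, cfg.sift_provean_correlation, rng_scores)

    if cfg.tie_fraction > 0 and n > 1:
        n_tied = int(round(cfg.tie_fraction * n))
        targets = rng_ties.choice(n, size=n_tied, replace=False)
        sources = rng_ties.integers(0, n, size=n_tied)
        for t, s in zip(targets, sources):
            if t != s:
                scores.iloc[t] = scores.iloc[s]

    catalog = Catalog()
    labels = []
    for key, pheno in zip(keys, phenotypes):
        ref, pos, alt = key
        variant = MissenseVariant(ref_aa=ref, position=int(pos), alt_aa=alt)
        ann = DiseaseAnnotation(
            phenotype=pheno, mosaic=pheno in MOSAIC_PHENOTYPES
        )
        catalog.entries[key] = CatalogEntry(variant=variant, annotations=[ann])
        labels.append(str(variant))

    table = pd.DataFrame(
        {
            "ref_aa": [k[0] for k in keys],
            "position": [int(k[1]) for k in keys],
            "alt_aa": [k[2] for k in keys],
        },
        index=labels,
    )
    table = pd.concat([table, scores.set_index(table.index)], axis=1)
    truth = pd.DataFrame(
        {
            "variant": labels,
            "position": [int(k[1]) for k in keys],
            "phenotype": [p.value for p in phenotypes],
            "latent_disruptiveness": latent,
            "severity_shift": shifts,
        }
    ).set_index("variant")
    return catalog, table, truth


def generate_benign_set(
    cfg: SyntheticConfig, stream: int = 7
) -> pd.DataFrame:
    """Benign comparison table: scores from a latent shifted toward harmless
    by ``benign_shift`` log10 units, plus minor allele frequencies drawn
    log-uniformly across the 0.001 rarity threshold."""
    cfg.validate()
    if cfg.benign_n < 1:
        raise ValueError("benign_n must be >= 1 to generate a benign set")
    rng = _substream(cfg, stream)
    n = cfg.benign_n
    positions = rng.integers(1, cfg.protein_length + 1, size=n)
    keys = _keys_for_positions(positions, rng)
    latent = rng.normal(0.0, cfg.latent_sd, n) - cfg.benign_shift
    scores = _scores_from_latent(latent, cfg.sift_provean_correlation, rng)
    maf = 10.0 ** rng.uniform(-6.0, -2.0, n)
    labels = [f"{k[0]}{k[1]}{k[2]}" for k in keys]
    out = pd.DataFrame(
        {
            "ref_aa": [k[0] for k in keys],
            "position": [int(k[1]) for k in keys],
            "alt_aa": [k[2] for k in keys],
        },
        index=labels,
    )
    out = pd.concat([out, scores.set_index(out.index)], axis=1)
    out["maf"] = maf
    out["latent_disruptiveness"] = latent
    return out


def generate_null_scores(n: int, seed: int) -> pd.DataFrame:
    """Three mutually independent continuous score columns for ``n`` variants.

    Each tool's ranks form a uniform random permutation and the three
    permutations are independent; ties are almost surely absent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    return pd.DataFrame(
        {
            "polyphen2": rng.random(n),
            "sift": rng.random(n),
            "provean": rng.normal(-3.0, 2.0, n),
        },
        index=[f"v{i}" for i in range(n)],
    )


def null_pweighted_samples(n: int, reps: int, seed: int) -> np.ndarray:
    """Monte-Carlo p_weighted draws for a focal variant among ``n`` under the
    null (independent continuous scores), vectorized over replicates."""
    if n < 1 or reps < 1:
        raise ValueError("n and reps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    # oriented sort keys: ascending = most disruptive
    pp = -rng.random((reps, n))
    si = rng.random((reps, n))
    pv = rng.normal(-3.0, 2.0, (reps, n))
    ranks = []
    for arr in (pp, si, pv):
        focal = arr[:, :1]
        ranks.append(1 + (arr < focal).sum(axis=1))
    r1, r2, r3 = ranks
    return (r1 / n) * np.sqrt((r2 / n) * (r3 / n))


def null_distribution_oracle(n: int) -> dict[float, float]:
    """Exact null distribution of p_weighted for one variant among ``n``.

    Enumerates all n^3 equally likely rank triples (no ties).  Feasible only
    for small n; for larger cohorts use Monte-Carlo
    (:func:`null_pweighted_samples`).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > 8:
        raise ValueError(
            f"n = {n} would enumerate {n ** 3} triples; use Monte-Carlo instead"
        )
    mass = 1.0 / n ** 3
    dist: dict[float, float] = {}
    for r1, r2, r3 in product(range(1, n + 1), repeat=3):
        pw = round((r1 / n) * math.sqrt((r2 / n) * (r3 / n)), 12)
        dist[pw] = dist.get(pw, 0.0) + mass
    return dist
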