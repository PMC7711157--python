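# Methods

## Compendium curation

The unit of analysis is the protein-level substitution. The packaged
compendium (`src/capscore/data/nlrp3_compendium.tsv`) lists one row per
(phenotype, substitution) report with cDNA notations, mosaic status,
overlap notes and opaque literature tags; building the catalog collapses
identical (reference residue, position, alternate residue) keys across
diseases, so a substitution reported in several conditions counts once and
carries every annotation. The packaged transcription deduplicates to 177
unique substitutions. The phenotype vocabulary is closed (11 labels:
FCAS, MWS, CINCA/NOMID, their mosaic forms, mosaic NLRP3-AID, unspecified
CAPS / non-CAPS, JIA, RA, other/unknown); free-text notes carry overlap
nuance such as "FCAS/MWS overlap syndrome".

Residue numbering follows the canonical sequence counted from the first
methionine (M1). Many primary reports count from the second methionine
(M3, residue 3), whose positions are exactly 2 lower; `renumber_m3_to_m1`
applies the +2 shift once and warns on a no-op. cDNA positions in the
literature are anchored to the M3 start codon even when protein positions
are M1-based, so `check_position_consistency` expects residue
`ceil(c/3) + 2` for cDNA position `c`. Entries that fail this check (e.g.
V200M with c.562G>A, which implies residue 190) are flagged as findings
and never silently corrected: the cDNA may carry a transcription error
while the protein-level identity, the analysis unit, is well attested.

## Combined score

Raw predictor scores are first oriented so that ascending order means more
disruptive (PolyPhen-2 and CADD-PHRED negate; SIFT, PROVEAN and FATHMM pass
through). Each core tool's oriented scores are competition-ranked
(`scipy.stats.rankdata`); tied scores share the top position of their block
(`tie_method="min"`), with the bottom-of-block alternative (`"max"`)
runnable because the convention is ambiguous in practice — the tie method
and `r_max` are recorded in the output metadata. `r_max` is the number of
combined-eligible variants, even when tie collapsing leaves the largest
assigned rank smaller. Variants missing any of the three core tools are
excluded from ranking entirely (they do not consume a rank) rather than
imputed, since the combination requires all three p-values. PolyPhen-2
rows duplicated across transcript isoforms collapse by maximum damaging
probability, the conservative choice toward pathogenicity.

Ranks map to p-values as `p = r / r_max` and combine as
`p_weighted = p_polyphen2 * sqrt(p_sift * p_provean)`. Severity classes
use base-10 log thresholds: severe below 0.01 (log10 < −2), moderate from
0.01 to 0.05, mild at or above 0.05 (10^−1.3 ≈ 0.05). The strict published
inequalities leave the boundary points unassigned; we assign each boundary
to the milder class by default and expose `boundary_to_milder=False` for
the alternative closure. Serialized tables print p-values to 9 decimal
places. Output ordering is ascending `p_weighted` with lexicographic
variant-label tie-breaks, making the table deterministic.

Consequences worth noting: `p_weighted` is invariant to strictly monotone
transforms of any tool's raw scores (only order matters); it equals 1 only
when a variant is bottom-ranked everywhere; a variant ranked `r` in all
three tools scores exactly `(r/N)²`; and SIFT/PROVEAN are exchangeable
while PolyPhen-2 is not (weight 1 vs ½ each).

## Domain map

No standard fixes the NACHT subdomain borders, so the packaged map is a
package choice satisfying the documented residue memberships for NLRP3:
PYR 1–100; NACHT 131–695 with NBD 131–372, HD1 373–415, WHD 416–541,
HD2 542–695; LRR 696–1036; motifs Walker A 226–233, Walker B 300–306,
Sensor 1 348–353, GxP 410–412, Sensor 2 520–524 (approximate, inside
NACHT). The WHD is taken to start at 416 so that Trp416 lies in the WHD
alongside Phe525/Glu527, and the NACHT C-terminus at 695 makes the
compendium's NACHT share 147/177 (83%), consistent with the documented
composition of this mutation set. All coordinates are 1-based inclusive
residue intervals; any alternative map can be supplied as a TSV config and
is validated (sorted, non-overlapping top-level domains; subdomains nested
in their parent; everything within the protein length). Positions covered
by no domain label "inter-domain".

## Cohort analyses

Group comparisons use the two-sided unpaired Student's t-test
(equal-variance, `scipy.stats.ttest_ind`) on log10 p_weighted, with Welch
behind a flag; two identical zero-variance groups compare as t = 0, p = 1.
No multiple-testing correction is applied — comparisons are reported
per-pair, and callers see how many were run. Severity/domain proportion
tables are probability vectors within each outer group, with counts kept
alongside.

Hotspot detection is a sliding-window scan: a block of `min_count`
consecutive distinct mutated residues qualifies when it spans at most
`window` residues; overlapping qualifying blocks merge, and each reported
interval runs from the first to the last mutated residue of its run.
Defaults (window 10, min_count 3) recover the canonical CAPS clusters
(261–268; 303–317 around the Walker B motif) on the packaged compendium;
both parameters are exposed and echoed in the output, since hotspot calls
in the literature are made by inspection. Note that sparse uniform
backgrounds still clump: ~50 uniform positions on a 1000-residue protein
produce at least one qualifying window most of the time, so hotspot counts
should be read against a simulated background, not as significance calls.

Alternative-scorer comparison intersects a variant set with the top-k of
another tool's oriented ranking (boundary ties broken by variant key);
CADD-style filtering uses a PHRED-score threshold (≥ 20 conventionally)
through the same generic tool-spec path. FATHMM and CADD never enter
p_weighted. The benign comparison takes two log10 p_weighted samples —
typically produced by pooling benign and pathogenic variants into one
ranking — and reports means, medians, the t-test and Cohen's d, making no
classification decision; minor-allele-frequency filtering (< 0.001) is a
separate helper applied upstream.

## Synthetic data

The generator emulates the pipeline's inputs, not the predictors. Each
variant draws a latent disruptiveness `N(0, latent_sd²)` plus an additive
per-phenotype shift in log10-score units. PolyPhen-2 is an increasing
sigmoid of latent plus independent noise; SIFT (decreasing sigmoid) and
PROVEAN (decreasing affine) share a correlated noise component weighted by
`sqrt(sift_provean_correlation)`, reproducing the dependence between the
two related algorithms. Positions mix a uniform background with Gaussian
bumps (sd 4 residues) at configurable hotspot centers; reference residues
are a deterministic function of position so a position never carries two
references. All streams derive from one seed via `SeedSequence` spawning,
so every output is a pure function of (config, seed).

Defaults are the compendium's scale: 177 variants on a 1036-residue
protein, phenotype mix 20:36:73 (FCAS:MWS:CINCA/NOMID, the germline CAPS
report counts), hotspot centers 264/308/503, severity shifts FCAS +1.0,
MWS +0.5, CINCA/NOMID 0 with latent sd 0.5 — encoding the observed
ordering in which FCAS variants are the most structurally disruptive — and
a benign set of 100 variants shifted 1.0 log10 unit toward harmless with
MAFs log-uniform across the 0.001 rarity threshold. A `tie_fraction`
option duplicates score rows to exercise tie handling, since continuous
draws never tie. What the generator does **not** emulate: real predictor
marginals and their genome-wide calibration, residue-specific
mutabilities, shared cDNA origins of one protein change, or correlated
phenotype ascertainment across reports. Passing recovery tests therefore
demonstrates that the pipeline preserves injected rank structure and group
contrasts, not that the predictors themselves are accurate on real data.

For the null, `generate_null_scores` draws three mutually independent
continuous columns (each tool's ranks are then uniform independent
permutations) and `null_distribution_oracle` enumerates all n³ rank
triples exactly for n ≤ 8, giving an exact reference distribution for
p_weighted that Monte-Carlo sampling is checked against.

## Numerical and design choices

- Empty score sets refuse to rank; NaN sort keys name the offending
  variant.
- p-values are validated to (0, 1]; out-of-range raw scores are rejected
  at ingest with the tool and range named.
- Analysis problem sizes: recovery and type-I checks use 1000 replicates
  of 20-variants-per-group cohorts; null agreement uses 1e5 Monte-Carlo
  draws against exact enumeration at n ∈ {2, 3, 4}; closed-form checks
  cover N ≤ 20. These sizes give binomial/enumeration error well below the
  effects being checked.
- The Monte-Carlo-vs-oracle comparison is assessed with a chi-square
  goodness-of-fit over the full support plus per-atom SE caps, the
  appropriate joint test when many atoms are compared simultaneously.

## Limitations

- The compendium transcription inherits any typos of its sources; flagged
  cDNA inconsistencies (e.g. V200M/c.562) are surfaced, not resolved, and
  mapping to genomic coordinates or transcript accessions is out of scope.
- Domain borders other than the constrained memberships are conventions;
  subdomain-level compositions shift with the chosen map.
- p_weighted is a relative, cohort-dependent quantity: adding or removing
  variants changes every score. It orders variants within one analysis and
  is not transferable across cohorts as a calibrated probability.
- Structural analyses (homology modelling, docking, binding-energy
  calculations) are outside this package's scope.
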