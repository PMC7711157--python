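# capscore

Rank-based meta-scoring of missense variant severity for NLRP3
autoinflammatory disease.

## The problem

Gain-of-function missense mutations in *NLRP3* cause a spectrum of
autoinflammatory diseases — the cryopyrin-associated periodic syndromes
FCAS, MWS and CINCA/NOMID, plus rarer non-CAPS conditions. Hundreds of such
mutations are scattered across case reports and databases, each typically
accompanied by single-tool deleteriousness predictions whose raw scales
(PolyPhen-2 damaging probabilities, SIFT tolerance probabilities, PROVEAN
alignment deltas) are not comparable. `capscore` is for researchers who
want to curate such a mutation compendium, place all variants on one
severity scale, and run the downstream cohort analyses: disease-group
comparisons, domain/severity composition, mutational hotspots, and
contrasts against benign variation or alternative scorers (FATHMM,
CADD-PHRED).

## The statistic

Each tool's scores are ranked from most to least structurally disruptive
(rank 1 = most disruptive; tied scores share the top rank of their block).
Under a null of random ranks, a rank $r$ among $r_{max}$ variants has tail
probability

$$p = \frac{r}{r_{max}}$$

The three per-tool p-values combine into a single weighted score

$$p_{weighted} = p_{PolyPhen\text{-}2}\cdot\left(p_{SIFT}\times p_{PROVEAN}\right)^{1/2}$$

PolyPhen-2 enters at full weight because its algorithm is independent of
the other two; SIFT and PROVEAN are closely related, so they are treated as
dependent and enter through their geometric mean. $p_{weighted}$ is a
score, not a calibrated probability; $p_{weighted} < 0.05$ marks a
significantly disruptive variant, and classes are **severe**
($p_w < 0.01$, i.e. $\log_{10} p_w < -2$), **moderate** ($0.01 \le p_w <
0.05$) and **mild** ($p_w \ge 0.05$). Because only ranks enter, the score
is invariant to any monotone rescaling of a tool's raw output.

## Worked example

```python
import capscore as cs

catalog = cs.load_default_catalog()           # packaged NLRP3 compendium
print("unique variants:", catalog.n)

report = cs.check_position_consistency(catalog.variant(("R", 262, "W")))
print("R262W cDNA check:", report.checks[0].cdna, "->", report.consistent)

dmap = cs.default_domain_map()
loc = cs.locate_position(262, dmap)
print("residue 262:", loc.domain, "/", loc.subdomain)

caps = {cs.Phenotype.FCAS, cs.Phenotype.MWS, cs.Phenotype.CINCA_NOMID}
positions = [k[1] for k in catalog.keys() if catalog.phenotypes_of(k) & caps]
for h in cs.detect_hotspots(positions, window=10, min_count=3)[:3]:
    print(f"hotspot {h.start}-{h.end}: {h.count} mutated residues")

cfg = cs.SyntheticConfig(n_variants=177, seed=1) # synthetic predictor scores
_, scores, _ = cs.generate_cohort(cfg)
combined = cs.score_table(scores, tie_method="min")
print(combined.head(3)[["site", "mutation", "p_weighted", "severity"]]
      .to_string(index=False))
```

prints

```
unique variants: 177
R262W cDNA check: c.778C>T -> True
residue 262: NACHT / NBD
hotspot 170-175: 4 mutated residues
hotspot 261-268: 5 mutated residues
hotspot 303-317: 10 mutated residues
 site mutation  p_weighted severity
   90     M90C    0.000032   severe
  502    D502W    0.000383   severe
  264    F264P    0.000447   severe
```

The packaged compendium deduplicates to exactly 177 unique protein-level
substitutions; R262W's cDNA notation is consistent with its residue number
under the second-methionine (M3) cDNA convention; residue 262 sits in the
nucleotide-binding subdomain of NACHT; and the classic CAPS hotspot at
residues 261–268 falls out of the sliding-window scan. The last block
scores a synthetic cohort (real predictor outputs are ingested with
`read_polyphen2_output` / `read_provean_sift_output` and merged with
`merge_score_table`).

A CLI mirrors the library:

```sh
capscore catalog validate                 # cDNA/protein consistency report
capscore simulate cohort --seed 1 -o sim/ # synthetic compendium + scores
capscore combine sim/scores.tsv -o combined.tsv
capscore analyze groups combined.tsv ...  # t-tests against FCAS
```

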