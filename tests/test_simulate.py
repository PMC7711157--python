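"""Synthetic-cohort generator: determinism, null structure, effect injection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import capscore as cs
from capscore.simulate import (
    SyntheticConfig,
    generate_benign_set,
    generate_cohort,
    generate_null_scores,
    null_distribution_oracle,
    null_pweighted_samples,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_variants=0),
            dict(phenotype_weights={cs.Phenotype.FCAS: 0.7}),
            dict(sift_provean_correlation=1.0),
            dict(hotspot_fraction=1.5),
            dict(latent_sd=0.0),
            dict(hotspot_centers=(2000,)),
        ],
    )
    def test_invalid_config_rejected_before_generation(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs).validate()


class TestDeterminism:
    def test_same_seed_reproduces_everything(self):
        cfg = SyntheticConfig(n_variants=40, seed=123)
        cat1, tab1, truth1 = generate_cohort(cfg)
        cat2, tab2, truth2 = generate_cohort(cfg)
        assert tab1.equals(tab2) and truth1.equals(truth2)
        assert list(cat1.keys()) == list(cat2.keys())
        assert generate_benign_set(cfg).equals(generate_benign_set(cfg))

    def test_different_seeds_differ(self):
        a = generate_cohort(SyntheticConfig(n_variants=40, seed=1))[1]
        b = generate_cohort(SyntheticConfig(n_variants=40, seed=2))[1]
        assert not a["polyphen2"].equals(b["polyphen2"])


class TestCohortStructure:
    def test_catalog_scores_and_truth_align(self, synthetic_cohort):
        catalog, table, truth = synthetic_cohort
        assert catalog.n == len(table) == len(truth) == 60
        assert list(table.index) == list(truth.index)
        assert (table["sift"].between(0, 1)).all()
        assert (table["polyphen2"].between(0, 1)).all()

    def test_positions_within_protein(self, synthetic_cohort):
        _, table, _ = synthetic_cohort
        assert table["position"].between(1, 1036).all()

    def test_hotspot_fraction_zero_rarely_clusters_at_centers(self):
        # uniform background still clumps occasionally (Poisson clumping),
        # but detections should not preferentially cover the configured
        # centers the way a seeded cohort's do
        hits_null, hits_seeded = 0, 0
        for seed in range(30):
            null_cfg = SyntheticConfig(n_variants=50, seed=seed,
                                       hotspot_fraction=0.0, protein_length=1000)
            seeded_cfg = SyntheticConfig(n_variants=50, seed=seed,
                                         hotspot_fraction=0.6,
                                         hotspot_centers=(264,), protein_length=1000)
            for cfg, bump in ((null_cfg, False), (seeded_cfg, True)):
                _, table, _ = generate_cohort(cfg)
                spots = cs.detect_hotspots(table["position"], window=10, min_count=3)
                covered = any(h.start <= 264 <= h.end for h in spots)
                if bump:
                    hits_seeded += covered
                else:
                    hits_null += covered
        assert hits_seeded >= 25
        assert hits_null <= 10

    def test_hotspot_centers_attract_positions(self):
        cfg = SyntheticConfig(
            n_variants=100, seed=5, hotspot_fraction=0.9,
            hotspot_centers=(264,), hotspot_sd=3.0,
        )
        _, table, _ = generate_cohort(cfg)
        near = table["position"].between(264 - 12, 264 + 12).mean()
        assert near > 0.6

    def test_sift_provean_correlation_raises_score_dependence(self):
        high = SyntheticConfig(n_variants=400, seed=9, sift_provean_correlation=0.9,
                               severity_shift={}, phenotype_weights={cs.Phenotype.FCAS: 1.0})
        low = SyntheticConfig(n_variants=400, seed=9, sift_provean_correlation=0.0,
                              severity_shift={}, phenotype_weights={cs.Phenotype.FCAS: 1.0})
        _, t_high, _ = generate_cohort(high)
        _, t_low, _ = generate_cohort(low)
        rho_high = stats.spearmanr(t_high["sift"], t_high["provean"]).statistic
        rho_low = stats.spearmanr(t_low["sift"], t_low["provean"]).statistic
        # SIFT low = disruptive, PROVEAN low = disruptive: positive dependence
        assert abs(rho_high) > abs(rho_low)

    def test_tie_injection_creates_ties(self):
        cfg = SyntheticConfig(n_variants=50, seed=3, tie_fraction=0.4)
        _, table, _ = generate_cohort(cfg)
        assert table["polyphen2"].duplicated().any()

    def test_balanced_phenotype_allocation(self):
        cfg = SyntheticConfig(
            n_variants=40, seed=4, balanced_phenotypes=True,
            phenotype_weights={cs.Phenotype.FCAS: 0.5, cs.Phenotype.CINCA_NOMID: 0.5},
            severity_shift={cs.Phenotype.FCAS: 1.0},
        )
        _, _, truth = generate_cohort(cfg)
        counts = truth["phenotype"].value_counts()
        assert counts["FCAS"] == counts["CINCA_NOMID"] == 20


class TestNullScores:
    def test_single_variant_has_pw_one(self):
        table = generate_null_scores(1, seed=0)
        out = cs.score_table(table)
        assert out["p_weighted"].iloc[0] == 1.0

    def test_rank_distribution_uniform_by_chi_square(self):
        n, reps = 10, 1000
        counts = np.zeros(n)
        rng_seeds = range(reps)
        for s in rng_seeds:
            table = generate_null_scores(n, seed=s)
            oriented = -table["polyphen2"]
            counts[int(oriented.rank(method="min").iloc[0]) - 1] += 1
        chi2 = ((counts - reps / n) ** 2 / (reps / n)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=n - 1)

    def test_tool_columns_mutually_independent(self):
        table = generate_null_scores(1000, seed=42)
        ranks = table.rank()
        for a, b in [("polyphen2", "sift"), ("polyphen2", "provean"),
                     ("sift", "provean")]:
            rho = np.corrcoef(ranks[a], ranks[b])[0, 1]
            assert abs(rho) < 0.1


class TestNullOracle:
    def test_point_mass_at_one_for_single_variant(self):
        assert null_distribution_oracle(1) == {1.0: 1.0}

    def test_n2_support_and_masses(self):
        dist = null_distribution_oracle(2)
        s = 0.5 * np.sqrt(0.5)
        expected = {
            0.25: 1 / 8,
            round(s, 12): 2 / 8,
            0.5: 2 / 8,
            round(np.sqrt(0.5), 12): 2 / 8,
            1.0: 1 / 8,
        }
        assert dist == pytest.approx(expected)

    def test_masses_sum_to_one(self):
        for n in (1, 2, 3, 4, 5):
            assert sum(null_distribution_oracle(n).values()) == pytest.approx(1.0)

    def test_large_n_advises_monte_carlo(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            null_distribution_oracle(9)

    def test_monte_carlo_agrees_with_enumeration(self):
        # quick agreement check; the full 1e5-draw comparison runs in the
        # acceptance suite
        n, reps = 3, 20000
        samples = np.round(null_pweighted_samples(n, reps, seed=1), 12)
        dist = null_distribution_oracle(n)
        for value, mass in dist.items():
            freq = (samples == value).mean()
            se = np.sqrt(mass * (1 - mass) / reps)
            assert abs(freq - mass) < 4 * se + 1e-9


class TestBenignSet:
    def test_maf_values_straddle_rarity_threshold(self):
        cfg = SyntheticConfig(benign_n=200, seed=6)
        benign = generate_benign_set(cfg)
        kept = cs.filter_by_maf(benign)
        assert 0 < len(kept) < len(benign)

    def test_zero_shift_matches_pathogenic_latent_law(self):
        # equal-in-law check via a two-sample KS test on latents
        cfg = SyntheticConfig(
            n_variants=300, benign_n=300, seed=8, benign_shift=0.0,
            severity_shift={}, phenotype_weights={cs.Phenotype.FCAS: 1.0},
        )
        _, _, truth = generate_cohort(cfg)
        benign = generate_benign_set(cfg)
        ks = stats.ks_2samp(
            truth["latent_disruptiveness"], benign["latent_disruptiveness"]
        )
        assert ks.pvalue > 0.01

    def test_shifted_benign_set_detected_by_comparison(self):
        cfg = SyntheticConfig(
            n_variants=100, benign_n=100, seed=9, benign_shift=1.0,
            severity_shift={}, phenotype_weights={cs.Phenotype.FCAS: 1.0},
        )
        _, table, _ = generate_cohort(cfg)
        benign = generate_benign_set(cfg)
        pooled = pd.concat(
            [table[["polyphen2", "sift", "provean"]],
             benign[["polyphen2", "sift", "provean"]]]
        )
        pooled.index = [f"v{i}" for i in range(len(pooled))]
        combined = cs.score_table(pooled)
        log10 = combined["log10_pw"]
        path_scores = log10[[f"v{i}" for i in range(100)]]
        benign_scores = log10[[f"v{i}" for i in range(100, 200)]]
        out = cs.benign_compare(path_scores, benign_scores)
        assert out["p_value"] < 0.01
        assert out["mean_pathogenic"] < out["mean_benign"]


class TestEffectRecovery:
    def test_injected_shift_ordering_recovered_exactly(self):
        shifts = {
            cs.Phenotype.FCAS: 1.0,
            cs.Phenotype.MWS: 0.5,
            cs.Phenotype.CINCA_NOMID: 0.0,
        }
        cfg = SyntheticConfig(
            n_variants=1000, seed=10,
            phenotype_weights={p: 1 / 3 for p in shifts},
            severity_shift=shifts,
        )
        catalog, table, _ = generate_cohort(cfg)
        combined = cs.score_table(table)
        groups = cs.distribution_by_group(combined, catalog)
        means = [groups[p].mean() for p in shifts]
        injected = [-shifts[p] for p in shifts]  # bigger shift -> lower log10 pw
        rho = stats.spearmanr(injected, means).statistic
        assert rho == 1.0
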