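"""Synthetic-data generator: Mendelian behaviour, determinism, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fnlqtl.simulate import (
    BulkConfig,
    ConfigError,
    CrossConfig,
    PanelConfig,
    TraitModel,
    genotypes_to_dosage,
    make_bulks,
    simulate_f2,
    simulate_f23,
    simulate_panel,
    simulate_phenotypes,
    simulate_qpcr,
    simulate_readcounts,
)


class TestSimulateF2:
    def test_seeded_determinism(self):
        cfg = CrossConfig(n_markers=20, n_f2=50, seed=5)
        assert simulate_f2(cfg).equals(simulate_f2(cfg))

    def test_zero_map_density_gives_uniform_chromosomes(self):
        cfg = CrossConfig(n_markers=15, n_f2=40, cm_per_mb=0.0, seed=2)
        g = simulate_f2(cfg)
        assert (g.nunique(axis=1) == 1).all()

    def test_single_marker_segregation_is_1_2_1(self):
        cfg = CrossConfig(n_markers=5, n_f2=5000, seed=3)
        g = simulate_f2(cfg)
        counts = g.iloc[:, 2].value_counts()
        obs = [counts.get(c, 0) for c in ("MM", "PM", "PP")]
        p = stats.chisquare(obs, f_exp=[1250, 2500, 1250]).pvalue
        assert p > 0.001

    def test_adjacent_recombination_matches_haldane(self):
        # 2 Mb spacing at 5 cM/Mb -> d = 10.53 cM between evenly spaced
        # markers; estimate r by ML and compare with the Haldane expectation
        from fnlqtl.linkage import estimate_rf

        cfg = CrossConfig(n_markers=11, n_f2=3000, chrom_length_bp=20_000_000,
                          cm_per_mb=5.0, seed=9)
        g = simulate_f2(cfg)
        pos = cfg.chrom_positions("chr1")
        d_cm = (pos[1] - pos[0]) / 1e6 * 5.0
        r_true = 0.5 * (1 - np.exp(-2 * d_cm / 100))
        r_hat, _ = estimate_rf(g.iloc[:, 0], g.iloc[:, 1])
        se = np.sqrt(r_true * (1 - r_true) / (2 * cfg.n_f2))
        assert abs(r_hat - r_true) < 3 * se

    def test_invalid_positions_rejected(self):
        with pytest.raises(ConfigError, match="strictly increasing"):
            CrossConfig(positions={"chr1": [100, 100, 200]}, n_markers=3)


class TestPhenotypes:
    def test_noise_free_classes_hit_parental_and_f1_means(self, small_cross):
        _, markers, genotypes = small_cross
        trait = TraitModel(sigma_e=0.0)
        ph = simulate_phenotypes(genotypes, trait, markers, seed=1)
        assert set(np.round(ph.unique(), 6)) <= {7.5, 4.6, 2.2}

    def test_uniform_population_collapses_to_one_mean(self):
        cfg = CrossConfig(n_markers=4, n_f2=30, seed=1)
        g = simulate_f2(cfg)
        g.iloc[:, :] = "PP"
        ph = simulate_phenotypes(g, TraitModel(sigma_e=0.0), cfg.marker_table())
        assert (ph == 7.5).all()

    def test_default_sigma_yields_r2_near_030(self, study_cross):
        _, markers, genotypes, trait, ph = study_cross
        qtl = f"{trait.qtl_chrom}_{12_000_000 + 4}"  # nearest grid marker
        sub = markers.iloc[(markers["pos_bp"] - trait.qtl_pos_bp).abs().argsort()]
        dosage = genotypes_to_dosage(genotypes[[sub.iloc[0]["marker"]]])[:, 0]
        r = np.corrcoef(dosage, ph)[0, 1]
        assert abs(r ** 2 - 0.30) < 0.05

    def test_qtl_outside_genome_rejected(self, small_cross):
        cross, markers, genotypes = small_cross
        bad = TraitModel(qtl_pos_bp=10 * cross.chrom_length_bp)
        with pytest.raises(ConfigError, match="outside"):
            simulate_phenotypes(genotypes, bad, markers,
                                chrom_length_bp=cross.chrom_length_bp)


class TestBulks:
    def test_study_scale_bulks_are_disjoint_fifties(self, study_cross):
        *_, phenotypes = study_cross
        sel = make_bulks(phenotypes, BulkConfig(), seed=1)
        assert len(sel.long_ids) == len(sel.short_ids) == 50
        assert not set(sel.long_ids) & set(sel.short_ids)

    def test_degenerate_identical_phenotypes_fall_back_to_rank(self):
        ph = pd.Series(np.full(200, 5.0), index=[f"i{i}" for i in range(200)])
        sel = make_bulks(ph, BulkConfig(), seed=4)
        assert sel.rule_long == sel.rule_short == "rank"
        assert len(set(sel.long_ids) | set(sel.short_ids)) == 100
        sel2 = make_bulks(ph, BulkConfig(), seed=4)
        assert sel.long_ids == sel2.long_ids

    def test_infinite_thresholds_match_sort_oracle(self):
        rng = np.random.default_rng(8)
        ph = pd.Series(rng.normal(5, 2, 300), index=[f"i{i}" for i in range(300)])
        cfg = BulkConfig(long_threshold_cm=np.inf, short_threshold_cm=-np.inf)
        sel = make_bulks(ph, cfg, seed=0)
        order = ph.sort_values()
        assert set(sel.short_ids) == set(order.index[:50])
        assert set(sel.long_ids) == set(order.index[-50:])
        assert sel.rule_long == sel.rule_short == "rank"

    def test_oversized_bulk_rejected(self):
        ph = pd.Series(np.arange(20.0))
        with pytest.raises(ConfigError, match="half"):
            make_bulks(ph, BulkConfig(n_per_bulk=11))


class TestReadCounts:
    def test_pure_bulk_with_no_error_has_no_m_reads(self):
        cfg = CrossConfig(n_markers=4, n_f2=40, cm_per_mb=0.0, seed=6)
        g = simulate_f2(cfg)
        g.iloc[:, :] = "PP"
        markers = cfg.marker_table()
        ph = simulate_phenotypes(g, TraitModel(sigma_e=0.0), markers)
        sel = make_bulks(ph, BulkConfig(n_per_bulk=10), seed=0)
        counts = simulate_readcounts(g, markers, sel,
                                     BulkConfig(n_per_bulk=10, error_rate=0.0))
        assert (counts["m_ln"] == 0).all() and (counts["m_sn"] == 0).all()

    def test_unlinked_sites_are_unbiased_and_depths_match(self):
        # bulks chosen on pure noise: every site behaves as unlinked
        cfg = CrossConfig(n_markers=10_000, n_f2=300, seed=12)
        g = simulate_f2(cfg)
        markers = cfg.marker_table()
        ph = simulate_phenotypes(g, TraitModel(sigma_e=1.0, mu_pp=5, mu_mm=5,
                                               mu_pm=5), markers, seed=12)
        sel = make_bulks(ph, BulkConfig(), seed=12)
        counts = simulate_readcounts(g, markers, sel, BulkConfig(error_rate=0.0),
                                     seed=12)
        frac = counts["p_ln"] / (counts["p_ln"] + counts["m_ln"])
        assert abs(frac.mean() - 0.5) < 0.01
        assert abs((counts["p_ln"] + counts["m_ln"]).mean() - 61) / 61 < 0.02
        assert abs((counts["p_sn"] + counts["m_sn"]).mean() - 52) / 52 < 0.02

    def test_causal_site_frequencies_reach_the_extremes(self, small_cross):
        # near-zero noise, cuts just inside the parental means
        cross, markers, genotypes = small_cross
        trait = TraitModel(sigma_e=1e-6)
        ph = simulate_phenotypes(genotypes, trait, markers, seed=2)
        cfg = BulkConfig(n_per_bulk=20, long_threshold_cm=7.0,
                         short_threshold_cm=3.0, error_rate=0.0)
        sel = make_bulks(ph, cfg, seed=2)
        counts = simulate_readcounts(genotypes, markers, sel, cfg, seed=2)
        i = (counts["pos"] - trait.qtl_pos_bp).abs().idxmin()
        row = counts.loc[i]
        assert row["m_ln"] == 0 and row["p_sn"] == 0


class TestF23:
    def test_homozygous_parent_family_mean_is_exact(self, small_cross):
        cross, markers, genotypes = small_cross
        trait = TraitModel(sigma_e=0.0)
        fam, _ = simulate_f23(genotypes, trait, markers, n_families=50,
                              plants_per_family=5, sigma_family=0.0, seed=3)
        qtl = markers.iloc[(markers["pos_bp"] - trait.qtl_pos_bp).abs().argsort()]
        dosage = genotypes_to_dosage(
            genotypes[[qtl.iloc[0]["marker"]]]
        )[:50, 0]
        for d, mu in ((2, 7.5), (0, 2.2)):
            sub = fam["mean_fnl_cm"].to_numpy()[dosage == d]
            assert np.allclose(sub, mu)

    def test_het_parent_family_mean_matches_selfing_expectation(self):
        # brute-force selfing expectation: (mu_pp + 2 mu_pm + mu_mm) / 4
        cfg = CrossConfig(n_markers=4, n_f2=5, cm_per_mb=0.0, seed=1)
        g = simulate_f2(cfg)
        g.iloc[:, :] = "PM"
        trait = TraitModel(sigma_e=0.0)
        fam, _ = simulate_f23(g, trait, cfg.marker_table(), n_families=5,
                              plants_per_family=4000, sigma_family=0.0, seed=5)
        expect = (7.5 + 2 * 4.6 + 2.2) / 4
        assert np.allclose(fam["mean_fnl_cm"], expect, atol=0.15)

    def test_family_count_and_shape(self, study_cross):
        _, markers, genotypes, trait, _ = study_cross
        fam, plants = simulate_f23(genotypes, trait, markers, n_families=102,
                                   plants_per_family=10, seed=1)
        assert len(fam) == 102
        assert len(plants) == 1020

    def test_invalid_family_size_rejected(self, small_cross):
        _, markers, genotypes = small_cross
        with pytest.raises(ConfigError):
            simulate_f23(genotypes, TraitModel(), markers, n_families=10,
                         plants_per_family=0)


class TestPanel:
    def test_default_panel_has_158_accessions(self):
        calls, info = simulate_panel(seed=1)
        assert len(calls) == 158 and len(info) == 158
        assert calls.shape[1] == 32

    def test_zero_mutation_rate_collapses_within_group_distance(self):
        from fnlqtl.phylo import genotype_distance

        cfg = PanelConfig(group_sizes=(5, 5), fnl_group_means=(6, 3),
                          geographies=("a", "b"), within_group_mut_rate=0.0)
        calls, info = simulate_panel(cfg, seed=2)
        d = genotype_distance(calls)
        for grp in ("group1", "group2"):
            ids = info.index[info["group"] == grp]
            assert d.loc[ids, ids].to_numpy().max() == 0.0

    def test_between_group_distance_equals_founder_hamming(self):
        founders = np.zeros((2, 32), dtype=np.int8)
        founders[1, :8] = 1  # Hamming distance 8 of 32
        cfg = PanelConfig(group_sizes=(4, 4), fnl_group_means=(6, 3),
                          geographies=("a", "b"), within_group_mut_rate=0.0,
                          founders=founders)
        calls, info = simulate_panel(cfg, seed=3)
        from fnlqtl.phylo import genotype_distance

        d = genotype_distance(calls)
        a = info.index[info["group"] == "group1"]
        b = info.index[info["group"] == "group2"]
        assert np.allclose(d.loc[a, b], 8 / 32)

    def test_single_group_rejected(self):
        with pytest.raises(ConfigError):
            PanelConfig(group_sizes=(10,), fnl_group_means=(5,),
                        geographies=("x",))


class TestQpcr:
    def test_fold_four_lowers_target_ct_by_two_cycles(self):
        ct = simulate_qpcr(["cal", "hi"], {"cal": 1.0, "hi": 4.0},
                           ct_noise_sd=0.0, seed=1)
        mean = ct.groupby(["sample", "gene"])["ct"].mean()
        assert mean[("cal", "target")] - mean[("hi", "target")] == pytest.approx(2.0)
        assert mean[("cal", "reference")] == pytest.approx(mean[("hi", "reference")])

    def test_replicate_count_and_determinism(self):
        ct = simulate_qpcr(["a"], 1.0, reps=3, seed=9)
        assert len(ct) == 6  # 2 genes x 3 reps
        assert ct.equals(simulate_qpcr(["a"], 1.0, reps=3, seed=9))

    def test_invalid_fold_rejected(self):
        with pytest.raises(ConfigError):
            simulate_qpcr(["a"], 0.0)
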