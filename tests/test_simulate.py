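"""Forward simulator: founder panels, intercross populations, phenotypes, pools."""

import numpy as np
import pandas as pd
import pytest

from aipqtl.simulate import (
    PhenotypeModel,
    VarCompSpec,
    advance_generations,
    diallel_base_population,
    dosage_matrix,
    make_founder_panel,
    make_fixture_ct_table,
    make_fixture_network,
    simulate_dgrp_fly_data,
    simulate_elution,
    simulate_pool_seq,
    simulate_varcomp_array,
)
from aipqtl.xqtl import segregating_sites

from conftest import ONE_CHROM, manual_panel


class TestFounderPanel:
    def test_panel_is_homozygous_biallelic_and_sorted(self, small_panel):
        assert set(np.unique(small_panel.genotypes)) <= {0, 1}
        for _, grp in small_panel.sites.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing

    def test_private_site_has_base_frequency_one_sixth(self):
        """An allele private to one of six equally represented founders sits
        at frequency 1/6 ~ 0.167 in the base intercross population."""
        panel = make_founder_panel(6, 40, private_fraction=1.0, seed=3,
                                   chromosomes=ONE_CHROM)
        assert (panel.genotypes.sum(axis=1) == 1).all()
        pop = diallel_base_population(panel, 300, seed=4)
        freq = dosage_matrix(pop, panel).sum(axis=0) / (2 * len(pop))
        assert np.allclose(freq, 1 / 6)
        assert round(float(freq[0]), 3) == 0.167

    def test_zero_private_fraction_gives_no_private_sites(self):
        panel = make_founder_panel(6, 50, private_fraction=0.0, seed=9,
                                   chromosomes=ONE_CHROM)
        assert (panel.genotypes.sum(axis=1) > 1).all()

    def test_two_line_panel_segregates_everywhere(self):
        """With 2 lines every site must differ between them (brute-force scan)."""
        panel = make_founder_panel(2, 10, private_fraction=0.5, seed=21,
                                   chromosomes=ONE_CHROM)
        for i in range(panel.n_sites):
            assert panel.genotypes[i, 0] != panel.genotypes[i, 1]
        assert len(segregating_sites(panel)) == panel.n_sites

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            make_founder_panel(6, 0, 0.3, seed=1)

    def test_bad_private_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_founder_panel(6, 10, 1.5, seed=1)


class TestDiallel:
    def test_equal_founder_representation(self, small_panel):
        pop = diallel_base_population(small_panel, 300, seed=1)
        shares = np.zeros(small_panel.n_lines)
        for ha, hb in pop.individuals:
            for hap in (ha, hb):
                founders, _ = hap["2L"]
                shares[founders[0]] += 1
        assert np.allclose(shares / shares.sum(), 1 / 6)

    def test_no_within_line_crosses(self, small_panel):
        pop = diallel_base_population(small_panel, 150, seed=1)
        for ha, hb in pop.individuals:
            assert ha["2L"][0][0] != hb["2L"][0][0]

    def test_indivisible_size_errors_with_required_multiple(self, small_panel):
        with pytest.raises(ValueError, match="15"):
            diallel_base_population(small_panel, 301, seed=1)

    def test_two_founders_all_f1_heterozygous(self):
        """Direct enumeration: every F1 is heterozygous wherever founders differ."""
        panel = make_founder_panel(2, 10, private_fraction=0.5, seed=8,
                                   chromosomes=ONE_CHROM)
        pop = diallel_base_population(panel, 10, seed=2)
        dos = dosage_matrix(pop, panel)
        differs = panel.genotypes[:, 0] != panel.genotypes[:, 1]
        assert (dos[:, differs] == 1).all()


class TestRandomMating:
    def test_zero_generations_is_identity(self, small_panel):
        pop = diallel_base_population(small_panel, 60, seed=1)
        assert advance_generations(pop, 0, small_panel, seed=2) is pop

    def test_negative_generations_rejected(self, small_panel):
        pop = diallel_base_population(small_panel, 60, seed=1)
        with pytest.raises(ValueError):
            advance_generations(pop, -1, small_panel, seed=2)

    def test_zero_map_length_transmits_parental_haplotypes(self):
        geno = np.array([[1, 0, 1, 0, 1, 0]] * 8)
        panel = manual_panel(geno)
        panel.genetic_map.lengths_cm["2L"] = 0.0
        pop = diallel_base_population(panel, 60, seed=3)
        adv = advance_generations(pop, 5, panel, seed=4)
        for ha, hb in adv.individuals:
            assert len(ha["2L"][0]) == 1 and len(hb["2L"][0]) == 1

    def test_haplotypes_tile_chromosome(self, aip, small_panel):
        length = small_panel.genetic_map.lengths_cm["2L"]
        for ha, hb in aip.individuals:
            for hap in (ha, hb):
                founders, ends = hap["2L"]
                assert ends[-1] == pytest.approx(length)
                assert (np.diff(ends) > 0).all()
                assert (np.diff(founders) != 0).all()  # adjacent segments merged

    def test_ancestry_fractions_sum_to_one(self, aip, small_panel):
        length = small_panel.genetic_map.lengths_cm["2L"]
        total = 0.0
        for ha, hb in aip.individuals:
            for hap in (ha, hb):
                _, ends = hap["2L"]
                segs = np.diff(np.concatenate(([0.0], ends)))
                total += segs.sum()
        assert total == pytest.approx(2 * len(aip) * length)

    def test_neutral_frequency_is_a_martingale(self):
        """Wright-Fisher expectation: replicate-mean drift of a neutral allele
        stays near its initial frequency while replicate variance grows."""
        panel = make_founder_panel(6, 5, private_fraction=1.0, seed=13,
                                   chromosomes=ONE_CHROM)
        base = diallel_base_population(panel, 120, seed=0)
        finals = []
        for rep in range(60):
            adv = advance_generations(base, 10, panel, seed=1000 + rep)
            freq = dosage_matrix(adv, panel).sum(axis=0) / (2 * len(adv))
            finals.append(freq)
        finals = np.array(finals)
        p0 = 1 / 6
        se = finals.std(axis=0, ddof=1).mean() / np.sqrt(len(finals))
        assert abs(finals.mean() - p0) < 4 * se + 1e-9
        assert finals.var(axis=0).mean() > 0

    def test_female_only_recombination_halves_junction_rate(self):
        """Junction counts track the effective map rate: with achiasmatic males
        roughly half the junctions accumulate compared to both-sex recombination."""
        panel = make_founder_panel(6, 5, 0.5, seed=2, chromosomes=ONE_CHROM)
        base = diallel_base_population(panel, 90, seed=0)

        def mean_junctions(female_only, seed):
            adv = advance_generations(base, 8, panel, seed=seed,
                                      female_recombination_only=female_only)
            counts = [len(h["2L"][0]) - 1 for ha, hb in adv.individuals for h in (ha, hb)]
            return np.mean(counts)

        j_half = np.mean([mean_junctions(True, s) for s in range(5)])
        j_full = np.mean([mean_junctions(False, s) for s in range(5, 10)])
        assert j_half < j_full
        assert j_half / j_full == pytest.approx(0.5, abs=0.15)

    def test_reproducible_under_fixed_seed(self, small_panel):
        base = diallel_base_population(small_panel, 60, seed=1)
        a = advance_generations(base, 3, small_panel, seed=42)
        b = advance_generations(base, 3, small_panel, seed=42)
        da = dosage_matrix(a, small_panel)
        db = dosage_matrix(b, small_panel)
        assert (da == db).all()


class TestElution:
    def test_noise_free_limit_hits_grand_mean_bin(self, aip, small_panel):
        model = PhenotypeModel(grand_mean=6.0, residual_sd=0.0)
        table = simulate_elution(aip, model, "F", "E1", 50, seed=1, panel=small_panel)
        assert (table["minutes"] == 6.0).all()

    def test_unknown_exposure_rejected(self, aip, small_panel):
        with pytest.raises(ValueError, match="exposure"):
            simulate_elution(aip, PhenotypeModel(), "F", "E3", 10, seed=1,
                             panel=small_panel)

    def test_tolerance_shift_moves_e2_mean(self, aip, small_panel):
        model = PhenotypeModel(grand_mean=6.0, tolerance_shift=2.0, residual_sd=0.5)
        e1 = simulate_elution(aip, model, "F", "E1", 120, seed=3, panel=small_panel)
        e2 = simulate_elution(aip, model, "F", "E2", 120, seed=4, panel=small_panel)
        assert e2["minutes"].mean() - e1["minutes"].mean() == pytest.approx(2.0, abs=0.3)

    def test_single_qtl_separates_homozygote_classes(self):
        """Additive model: homozygote class means differ by ~2 effects."""
        geno = np.zeros((5, 6), dtype=np.int8)
        geno[2, :3] = 1  # one site splitting the founders 3/3
        geno[0, 0] = geno[1, 1] = geno[3, 2] = geno[4, 4] = 1
        panel = manual_panel(geno)
        pop = diallel_base_population(panel, 600, seed=5)
        model = PhenotypeModel(grand_mean=6.0, qtl_effects={2: 1.0}, residual_sd=0.05)
        table = simulate_elution(pop, model, "F", "E1", 600, seed=6, panel=panel)
        idx = table["id"].str.removeprefix("ind").astype(int).to_numpy()
        dos = dosage_matrix([pop.individuals[i] for i in idx], panel, np.array([2]))[:, 0]
        means = pd.Series(table["minutes"].to_numpy()).groupby(dos).mean()
        assert means[2] - means[0] == pytest.approx(2.0, abs=0.2)

    def test_binning_floors_at_one_bin(self):
        geno = np.eye(6, dtype=np.int8)
        panel = manual_panel(geno)
        pop = diallel_base_population(panel, 30, seed=1)
        model = PhenotypeModel(grand_mean=-5.0, residual_sd=0.1)
        table = simulate_elution(pop, model, "M", "E2", 30, seed=2, panel=panel)
        assert (table["minutes"] >= 1.0).all()


class TestVarCompDraws:
    def test_zero_variances_give_pure_fixed_effects(self):
        spec = VarCompSpec(0, 0, 0, 1e-24, n_lines=4, n_flies_per_rep=3,
                           grand_mean=7.0, factor_effect=0.5)
        arr = simulate_varcomp_array(spec, seed=1)
        assert np.allclose(arr[:, 0], 7.0, atol=1e-9)
        assert np.allclose(arr[:, 1], 7.5, atol=1e-9)

    def test_moment_match_on_large_draw(self):
        """Sample variance decomposition of a large draw matches the
        generating components (moment-matching oracle)."""
        spec = VarCompSpec(sigma2_L=2.0, sigma2_LxF=0.5, sigma2_Rep=0.25,
                           sigma2_eps=3.0, n_lines=400, n_reps=2,
                           n_flies_per_rep=40)
        arr = simulate_varcomp_array(spec, seed=7)
        line_means = arr.mean(axis=(1, 2, 3))
        within_rep = arr.var(axis=3, ddof=1).mean()
        assert within_rep == pytest.approx(3.0, rel=0.05)
        # var of line means ~ s2_L + s2_LxF/b + s2_Rep/(b r) + s2_eps/(b r f)
        expect = 2.0 + 0.5 / 2 + 0.25 / 4 + 3.0 / 160
        assert line_means.var(ddof=1) == pytest.approx(expect, rel=0.2)

    def test_dataframe_layout_is_balanced(self):
        spec = VarCompSpec(1, 1, 1, 1, n_lines=3, n_reps=2, n_flies_per_rep=4)
        df = simulate_dgrp_fly_data(spec, seed=1)
        assert len(df) == 3 * 2 * 2 * 4
        assert df.groupby(["line", "sex", "replicate"]).size().nunique() == 1


class TestPoolSeq:
    def test_fixed_pool_yields_alt_count_equal_depth(self):
        geno = np.ones((4, 6), dtype=np.int8)
        geno[:, 5] = 0  # segregating: five lines alt, one ref
        panel = manual_panel(geno)
        pop = diallel_base_population(panel, 30, seed=1)
        fixed = [i for i, (ha, hb) in enumerate(pop.individuals)
                 if ha["2L"][0][0] != 5 and hb["2L"][0][0] != 5][:5]
        counts = simulate_pool_seq(pop, (fixed, fixed), panel, 30.0, seed=2)
        assert (counts["alt_S"] == counts["d_S"]).all()

    def test_estimated_frequency_unbiased(self, aip, small_panel):
        ids = np.arange(40)
        true = dosage_matrix([aip.individuals[i] for i in ids], small_panel).sum(0)
        seg = segregating_sites(small_panel).index.to_numpy()
        true_freq = true[seg] / 80.0
        ests = []
        for s in range(30):
            c = simulate_pool_seq(aip, (ids, ids), small_panel, 60.0, seed=s)
            ests.append(c["alt_S"] / c["d_S"])
        est = np.mean(ests, axis=0)
        assert np.abs(est - true_freq).mean() < 0.03

    def test_monomorphic_sites_excluded(self):
        geno = np.zeros((3, 6), dtype=np.int8)
        geno[1] = 1  # sites 0 and 1 monomorphic... site 1 all-alt
        geno[2, :2] = 1
        panel = manual_panel(geno)
        pop = diallel_base_population(panel, 30, seed=1)
        counts = simulate_pool_seq(pop, ([0, 1], [2, 3]), panel, 20.0, seed=3)
        assert len(counts) == 1
        assert counts["pos"].iloc[0] == panel.sites["pos"].iloc[2]


class TestFixtures:
    def test_planted_linker_recovered(self):
        from aipqtl.network import extract_subnetwork, graph_from_edges

        edges, cands = make_fixture_network(4, 6, 0, seed=1, planted_linkers=2)
        sub = extract_subnetwork(graph_from_edges(edges), set(cands))
        linkers = [n for n in sub.nodes if n.startswith("link")]
        assert set(linkers) == {"link0", "link1"}

    def test_zero_edges_gives_empty_subnetwork(self):
        from aipqtl.network import extract_subnetwork, graph_from_edges

        edges, cands = make_fixture_network(3, 3, 0, seed=1)
        sub = extract_subnetwork(graph_from_edges(edges), set(cands))
        assert sub.number_of_nodes() == 0

    def test_ct_fixture_reference_everywhere(self):
        table = make_fixture_ct_table(["g1", "g2"], n_bio_reps=3, seed=1)
        strata = table[table["gene"] == "Gpdh"][["sex", "pool", "bio_rep"]]
        assert len(strata.drop_duplicates()) == 2 * 2 * 3

    def test_planted_shift_detected_at_simulated_power(self):
        """A planted 1-cycle ddCt shift with sd 0.3 and 6 replicates is
        essentially always detected; a null gene is not."""
        from aipqtl.expression import delta_ct, pool_ttest

        hits = null_hits = 0
        for s in range(20):
            table = make_fixture_ct_table(["shifted", "flat"], n_bio_reps=6,
                                          effect_sizes={"shifted": 1.0}, seed=s)
            dct = delta_ct(table)
            hits += pool_ttest(dct, "shifted", "M").p_value < 0.05
            null_hits += pool_ttest(dct, "flat", "M").p_value < 0.05
        assert hits >= 18
        assert null_hits <= 5
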