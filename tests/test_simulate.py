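"""Simulator: funnel design, meiosis, DH populations, traits and trials."""

import numpy as np
import pandas as pd
import pytest

from magicgp import (
    default_map, simulate_founders, build_funnel_design, simulate_gamete,
    simulate_population, sample_trait_architecture, simulate_genetic_values,
    simulate_trial, fit_lattice_model,
)
from magicgp.simulate import (
    GeneticMap, TraitArchitecture, TrialLayout, N_FOUNDERS,
)


# ---------------------------------------------------------------------------
# map and founders
# ---------------------------------------------------------------------------

class TestMapAndFounders:
    def test_map_invariants_enforced(self):
        bad = pd.DataFrame({
            "marker": ["a", "b"], "chrom": ["1", "1"],
            "cM": [5.0, 1.0], "bp": [10, 20],
        })
        with pytest.raises(ValueError, match="non-decreasing"):
            GeneticMap(bad)

    def test_founder_panel_shape_and_groups(self, small_map, founders):
        assert founders.haplotypes.shape == (8, small_map.n_markers)
        assert set(np.unique(founders.haplotypes)) <= {0, 1}
        assert founders.groups.count("old") == 4

    def test_forced_maf_half_gives_exact_four_four_split(self, small_map):
        panel = simulate_founders(small_map, maf_range=(0.5, 0.5), rng_seed=4)
        counts = panel.haplotypes.sum(axis=0)
        assert (counts == 4).all()

    def test_same_seed_reproduces_panel(self, small_map):
        a = simulate_founders(small_map, rng_seed=9)
        b = simulate_founders(small_map, rng_seed=9)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            GeneticMap(pd.DataFrame(columns=["marker", "chrom", "cM", "bp"]))


# ---------------------------------------------------------------------------
# funnel design
# ---------------------------------------------------------------------------

class TestFunnelDesign:
    def test_line_counts_sum_to_requested(self, founders):
        design = build_funnel_design(founders, 352, rng_seed=0)
        assert design.n_lines == 352
        assert len(design.stage1) == 4
        assert len(design.stage2) == 6
        # each stage-1 cross pairs one old with one modern founder
        for old_idx, modern_idx in design.stage1:
            assert founders.groups[old_idx] == "old"
            assert founders.groups[modern_idx] == "modern"

    def test_stage3_unites_disjoint_fourway_sets(self, founders):
        design = build_funnel_design(founders, 12, rng_seed=0)
        for a, b in design.stage3:
            merged = set(design.stage2[a]) | set(design.stage2[b])
            assert merged == {0, 1, 2, 3}

    def test_even_split_across_three_funnels(self, founders):
        design = build_funnel_design(founders, 6, rng_seed=0)
        assert sorted(design.lines_per_funnel) == [2, 2, 2]

    def test_zero_lines_rejected(self, founders):
        with pytest.raises(ValueError):
            build_funnel_design(founders, 0)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

class TestMeiosis:
    def test_identical_parents_give_identical_gamete(self, small_map):
        p = small_map.n_markers
        hap = np.tile(np.arange(p) % 2, (2, 1)).astype(np.int8)
        origin = np.zeros((2, p), np.int8)
        gam, orig = simulate_gamete(hap, origin, small_map, rng_seed=0)
        np.testing.assert_array_equal(gam, hap[0])

    def test_length_mismatch_rejected(self, small_map):
        with pytest.raises(ValueError):
            simulate_gamete(np.zeros((2, 3)), np.zeros((2, 3)), small_map)

    def test_crossover_count_poisson_one_morgan(self):
        # 1 Morgan chromosome: switches between two distinguishable parents
        # count crossovers; mean and variance should match Poisson(1)
        gmap = GeneticMap(pd.DataFrame({
            "marker": [f"m{i}" for i in range(200)], "chrom": "1",
            "cM": np.linspace(0, 100, 200), "bp": np.arange(200) * 10_000,
        }))
        hap = np.zeros((2, 200), np.int8)
        origin = np.stack([np.zeros(200, np.int8), np.ones(200, np.int8)])
        rng = np.random.default_rng(11)
        n_draw = 20_000
        counts = np.empty(n_draw)
        from magicgp.simulate import _gamete
        for i in range(n_draw):
            _, orig = _gamete(hap, origin, gmap, rng)
            counts[i] = (np.diff(orig) != 0).sum()
        # observed switches undercount Poisson events (double crossovers
        # between adjacent markers collapse), so compare loosely at this
        # marker density: 3 SE band around the Poisson mean
        se = np.sqrt(1.0 / n_draw)
        assert abs(counts.mean() - 1.0) < 3 * se + 0.05

    def test_haldane_recombination_fraction_50cM(self):
        gmap = GeneticMap(pd.DataFrame({
            "marker": ["a", "b"], "chrom": ["1", "1"],
            "cM": [0.0, 50.0], "bp": [0, 1],
        }))
        hap = np.zeros((2, 2), np.int8)
        origin = np.stack([np.zeros(2, np.int8), np.ones(2, np.int8)])
        rng = np.random.default_rng(5)
        from magicgp.simulate import _gamete
        n_draw = 100_000
        rec = 0
        for _ in range(n_draw):
            _, orig = _gamete(hap, origin, gmap, rng)
            rec += orig[0] != orig[1]
        expected = (1 - np.exp(-2 * 0.5)) / 2     # Haldane: 0.3161
        se = np.sqrt(expected * (1 - expected) / n_draw)
        assert abs(rec / n_draw - expected) < 3 * se


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

class TestPopulation:
    def test_all_lines_homozygous(self, small_population):
        assert set(np.unique(small_population.dosages)) <= {0, 2}

    def test_mosaic_consistent_with_alleles(self, small_population, founders):
        hap = founders.haplotypes
        cols = np.arange(small_population.n_markers)
        expected = 2 * hap[small_population.founder_origin, cols]
        np.testing.assert_array_equal(small_population.dosages, expected)

    def test_founder_shares_near_one_eighth(self, small_map, founders):
        design = build_funnel_design(founders, 600, rng_seed=1)
        pop = simulate_population(design, founders, small_map, rng_seed=2)
        shares = pop.founder_shares()
        assert np.all(np.abs(shares - 1 / N_FOUNDERS) < 0.02)

    def test_fixed_seed_bit_identical(self, small_map, founders):
        design = build_funnel_design(founders, 10, rng_seed=4)
        a = simulate_population(design, founders, small_map, rng_seed=5)
        b = simulate_population(design, founders, small_map, rng_seed=5)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        np.testing.assert_array_equal(a.founder_origin, b.founder_origin)


# ---------------------------------------------------------------------------
# trait architecture and genetic values
# ---------------------------------------------------------------------------

class TestGeneticValues:
    def test_zero_deviations_identical_across_environments(self, small_map,
                                                           small_population):
        arch = sample_trait_architecture(small_map, ["A", "B"], n_qtl=50,
                                         dev_var=0.0, rng_seed=0)
        gv, _ = simulate_genetic_values(small_population, arch, rng_seed=1)
        np.testing.assert_allclose(gv["A"], gv["B"])

    def test_main_zero_gives_near_zero_env_correlation(self, small_map,
                                                       small_population):
        rs = []
        for seed in range(6):
            arch = sample_trait_architecture(small_map, ["A", "B"], n_qtl=60,
                                             main_var=0.0, dev_var=1.0,
                                             rng_seed=seed)
            gv, _ = simulate_genetic_values(small_population, arch,
                                            rng_seed=seed)
            rs.append(np.corrcoef(gv["A"], gv["B"])[0, 1])
        assert abs(np.mean(rs)) < 3 * np.std(rs, ddof=1) / np.sqrt(len(rs)) + 0.1

    def test_equal_main_and_deviation_variance_gives_half_correlation(
            self, small_map, small_population):
        rs = []
        for seed in range(8):
            arch = sample_trait_architecture(small_map, ["A", "B"], n_qtl=60,
                                             main_var=1.0, dev_var=1.0,
                                             rng_seed=seed)
            gv, _ = simulate_genetic_values(small_population, arch,
                                            rng_seed=seed)
            rs.append(np.corrcoef(gv["A"], gv["B"])[0, 1])
        # expectation sigma2_main / (sigma2_main + sigma2_dev) = 0.5
        assert abs(np.mean(rs) - 0.5) < 0.15

    def test_qtl_out_of_range_rejected(self, small_population):
        arch = TraitArchitecture(
            qtl_indices=[small_population.n_markers + 5],
            main_effects=[1.0], env_deviations=[[0.0]],
            environments=["A"], target_h2={"A": 0.5},
        )
        with pytest.raises(ValueError, match="out of marker range"):
            simulate_genetic_values(small_population, arch)

    def test_dh_covariate_narrow_spread(self, small_map, small_population):
        arch = sample_trait_architecture(small_map, ["A"], n_qtl=20,
                                         rng_seed=0)
        _, dh = simulate_genetic_values(small_population, arch, rng_seed=3)
        assert dh.std() < 4.0


# ---------------------------------------------------------------------------
# trial simulation
# ---------------------------------------------------------------------------

class TestTrial:
    @staticmethod
    def _values(n=80, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"L{i}" for i in range(n)]
        g = pd.Series(rng.normal(0, 1, n), index=ids)
        dh = pd.Series(rng.normal(210, 1.2, n), index=ids)
        return g, dh

    def test_zero_residual_limit_identical_reps(self):
        g, dh = self._values()
        layout = TrialLayout("E", 2, 8)
        pt = simulate_trial(g, dh, layout, target_h2=1 - 1e-12,
                            rep_sd=0.0, block_sd=0.0, rng_seed=1)
        piv = pt.pivot_table(index="genotype", columns="rep", values="GY")
        np.testing.assert_allclose(piv[1], piv[2], atol=1e-4)

    def test_target_h2_recovered_downstream(self):
        # simulate at H2 = 0.805 and recover via the lattice model
        ests = []
        for seed in range(10):
            g, dh = self._values(n=200, seed=seed)
            pt = simulate_trial(g, dh, TrialLayout("E", 2, 16),
                                target_h2=0.805, rng_seed=seed)
            ests.append(fit_lattice_model(pt).h2_)
        assert abs(np.mean(ests) - 0.805) < 0.1

    def test_invalid_h2_rejected(self):
        g, dh = self._values()
        with pytest.raises(ValueError):
            simulate_trial(g, dh, TrialLayout("E"), target_h2=1.5)

    def test_zero_covariate_effect_preserves_blup_ranking(self):
        g, dh = self._values(n=60, seed=3)
        pt = simulate_trial(g, dh, TrialLayout("E", 2, 10), target_h2=0.6,
                            covariate_effect=0.0, rng_seed=4)
        with_cov = fit_lattice_model(pt, use_dh_covariate=True).blups_
        without = fit_lattice_model(pt, use_dh_covariate=False).blups_
        assert np.corrcoef(with_cov, without)[0, 1] > 0.999

    def test_fixed_seed_bit_identical_plot_table(self):
        g, dh = self._values()
        a = simulate_trial(g, dh, TrialLayout("E"), target_h2=0.5, rng_seed=9)
        b = simulate_trial(g, dh, TrialLayout("E"), target_h2=0.5, rng_seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_each_genotype_once_per_replicate(self):
        g, dh = self._values(n=30)
        pt = simulate_trial(g, dh, TrialLayout("E", 2, 7), target_h2=0.5,
                            rng_seed=0)
        counts = pt.groupby(["rep", "genotype"]).size()
        assert (counts == 1).all()
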