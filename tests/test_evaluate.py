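"""Cross-validation machinery, statistics, PCA and LD decay."""

import numpy as np
import pandas as pd
import pytest

from magicgp import (
    MEDataset, make_random_partitions, make_me_partitions, tp_size_sweep,
    loo_cv, predictive_ability_summary, welch_compare, run_pca, ld_decay,
    MCMCConfig, default_map,
)
from magicgp.simulate import GeneticMap


class TestRandomPartitions:
    def test_disjoint_and_exhaustive(self):
        ps = make_random_partitions(50, 20, n_reps=10, rng_seed=0)
        assert len(ps.partitions) == 10
        for tr, va in ps.partitions:
            assert len(tr) == 20 and len(va) == 30
            assert not set(tr) & set(va)
            assert set(tr) | set(va) == set(range(50))

    def test_singleton_validation(self):
        ps = make_random_partitions(10, 9, n_reps=3, rng_seed=1)
        assert all(len(va) == 1 for _, va in ps.partitions)

    def test_fixed_seed_identical(self):
        a = make_random_partitions(30, 10, 5, rng_seed=2)
        b = make_random_partitions(30, 10, 5, rng_seed=2)
        for (t1, _), (t2, _) in zip(a.partitions, b.partitions):
            np.testing.assert_array_equal(t1, t2)

    def test_oversized_tp_rejected(self):
        with pytest.raises(ValueError):
            make_random_partitions(10, 10)


class TestMEPartitions:
    @pytest.fixture()
    def data(self):
        rng = np.random.default_rng(3)
        Y = pd.DataFrame(rng.normal(size=(90, 9)),
                         index=[f"L{i}" for i in range(90)],
                         columns=[f"E{j}" for j in range(9)])
        return MEDataset(Y)

    def test_cv1_masks_all_environments_of_ten_percent(self, data):
        ps = make_me_partitions(data, "CV1", n_reps=5, rng_seed=0)
        for cells in ps.partitions:
            lines = {c[0] for c in cells}
            assert len(lines) == 9            # 10% of 90
            assert len(cells) == 9 * 9        # every env masked

    def test_cv2_masked_lines_keep_an_observed_environment(self, data):
        ps = make_me_partitions(data, "CV2", n_reps=5, rng_seed=1)
        for cells in ps.partitions:
            masked = set(cells)
            per_line = {}
            for line, env in masked:
                per_line.setdefault(line, set()).add(env)
            for line, envs in per_line.items():
                assert len(envs) < data.n_envs

    def test_cv2_single_environment_rejected(self):
        Y = pd.DataFrame({"E1": np.random.default_rng(0).normal(size=10)})
        with pytest.raises(ValueError):
            make_me_partitions(MEDataset(Y), "CV2")

    def test_fixed_seed_reproducible(self, data):
        a = make_me_partitions(data, "CV2", n_reps=3, rng_seed=4)
        b = make_me_partitions(data, "CV2", n_reps=3, rng_seed=4)
        assert a.partitions == b.partitions


class TestPredictiveAbility:
    def test_perfect_and_inverted_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        res = predictive_ability_summary([y, -y], [y, y])
        np.testing.assert_allclose(res.correlations["all"], [1.0, -1.0])

    def test_matches_textbook_pearson_formula(self):
        a = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        b = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        res = predictive_ability_summary([a], [b])
        num = ((a - a.mean()) * (b - b.mean())).sum()
        den = np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        assert res.correlations["all"][0] == pytest.approx(num / den,
                                                           abs=1e-10)

    def test_too_few_points_flagged(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            res = predictive_ability_summary([np.array([1.0, 2.0])],
                                             [np.array([1.0, 2.0])])
        assert np.isnan(res.correlations["all"][0])


class TestWelch:
    def test_identical_samples_p_one(self):
        a = np.array([0.5, 0.5, 0.5])
        t, p = welch_compare(a, a.copy())
        assert p == pytest.approx(1.0)

    def test_separated_samples_tiny_p(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.5, 0.01, 100)
        b = rng.normal(0.3, 0.01, 100)
        _, p = welch_compare(a, b)
        assert p < 1e-6

    def test_matches_hand_computation_on_toy(self):
        a = np.array([0.2, 0.4, 0.6])
        b = np.array([0.1, 0.2, 0.3])
        t, p = welch_compare(a, b)
        sa2, sb2 = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_hand = (a.mean() - b.mean()) / np.sqrt(sa2 + sb2)
        assert t == pytest.approx(t_hand, abs=1e-10)
        df_hand = (sa2 + sb2) ** 2 / (sa2 ** 2 / 2 + sb2 ** 2 / 2)
        from scipy.stats import t as tdist
        assert p == pytest.approx(2 * tdist.sf(abs(t_hand), df_hand),
                                  abs=1e-10)


class TestPCA:
    def test_rank_one_explains_everything(self):
        u = np.arange(6, dtype=float)[:, None]
        v = np.ones((1, 10))
        scores, frac = run_pca(u @ v, n_components=3)
        assert frac[0] == pytest.approx(1.0)

    def test_duplicated_lines_identical_scores(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 20))
        X[3] = X[2]
        scores, _ = run_pca(X)
        np.testing.assert_allclose(scores[2], scores[3], atol=1e-10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            run_pca(np.ones((5, 4)))

    def test_funnel_structure_detectable(self, magic_dataset, marker_matrix):
        # lines from the same eight-way funnel cluster together relative to
        # random labels (silhouette comparison on PC1-2)
        from scipy.spatial.distance import pdist, squareform
        scores, _ = run_pca(marker_matrix, n_components=2)
        design = magic_dataset.population.design
        labels = np.repeat(np.arange(len(design.stage3)),
                           design.lines_per_funnel)

        def silhouette(lbl):
            D = squareform(pdist(scores))
            vals = []
            for i in range(len(lbl)):
                same = lbl == lbl[i]
                same[i] = False
                a = D[i, same].mean()
                b = min(D[i, lbl == k].mean()
                        for k in np.unique(lbl) if k != lbl[i])
                vals.append((b - a) / max(a, b))
            return float(np.mean(vals))

        rng = np.random.default_rng(7)
        true_sil = silhouette(labels)
        rand_sil = np.mean([silhouette(rng.permutation(labels))
                            for _ in range(20)])
        assert true_sil > rand_sil


class TestLDDecay:
    def test_perfectly_correlated_pair_retained(self):
        gmap = GeneticMap(pd.DataFrame({
            "marker": ["a", "b"], "chrom": ["1", "1"],
            "cM": [0.0, 1.0], "bp": [0, 50_000]}))
        col = np.array([0, 0, 2, 2, 0, 2, 0, 2] * 4, dtype=float)
        X = np.column_stack([col, col])
        res = ld_decay(X, gmap)
        assert len(res.pairs) == 1
        assert res.pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_markers_mostly_filtered(self):
        rng = np.random.default_rng(8)
        p = 40
        gmap = GeneticMap(pd.DataFrame({
            "marker": [f"m{i}" for i in range(p)], "chrom": "1",
            "cM": np.arange(p, dtype=float),
            "bp": np.arange(p) * 100_000}))
        X = rng.choice([0.0, 2.0], size=(100, p))
        res = ld_decay(X, gmap)
        n_total = p * (p - 1) // 2
        # at p-cut 0.001 under the null, ~0.1% of pairs are kept
        assert len(res.pairs) < 0.05 * n_total

    def test_r2_matches_hand_computed_d_squared(self):
        gmap = GeneticMap(pd.DataFrame({
            "marker": ["a", "b"], "chrom": ["1", "1"],
            "cM": [0.0, 1.0], "bp": [0, 10_000]}))
        # 4 DH haplotypes: alleles per line
        h1 = np.array([0, 0, 1, 1], dtype=float)
        h2 = np.array([0, 1, 1, 1], dtype=float)
        X = np.column_stack([2 * h1, 2 * h2])
        p1, q1 = h1.mean(), 1 - h1.mean()
        p2, q2 = h2.mean(), 1 - h2.mean()
        D = (h1 * h2).mean() - p1 * p2
        expected = D ** 2 / (p1 * q1 * p2 * q2)
        res = ld_decay(X, gmap, p_cut=1.0)
        assert res.pairs["r2"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_ld_decays_with_distance_on_magic(self, magic_dataset):
        res = ld_decay(magic_dataset.population.dosages,
                       magic_dataset.genetic_map)
        g = res.genome_binned.sort_values("bin_lo")
        assert g["mean_r2"].iloc[0] >= g["mean_r2"].iloc[-1]

    def test_single_marker_chromosome_empty(self):
        gmap = GeneticMap(pd.DataFrame({
            "marker": ["a"], "chrom": ["1"], "cM": [0.0], "bp": [0]}))
        res = ld_decay(np.array([[0.0], [2.0]]), gmap)
        assert len(res.pairs) == 0


class TestCVDrivers:
    def test_loo_returns_n_predictions(self, marker_matrix, polygenic_trait):
        y, _ = polygenic_trait
        res = loo_cv("GB", marker_matrix.X[:30], y[:30],
                     mcmc=MCMCConfig(600, 150, 2, 0))
        assert len(res.meta["predictions"]) == 30
        assert -1 <= res.correlations["all"][0] <= 1

    def test_loo_high_signal_high_accuracy(self):
        # noiseless dense trait at full population size: held-out lines are
        # well connected to the training set, so LOO r should be high
        from magicgp import simulate_magic_dataset, qc_and_standardize
        ds = simulate_magic_dataset(n_lines=352, markers_per_chrom=60,
                                    environments=["E1"], rng_seed=7)
        X = qc_and_standardize(ds.population.dosages).X
        rng = np.random.default_rng(9)
        g = X @ rng.normal(0, 1, X.shape[1])
        y = (g - g.mean()) / g.std(ddof=1)
        res = loo_cv("GB", X, y, mcmc=MCMCConfig(400, 100, 2, 0))
        assert res.correlations["all"][0] > 0.9

    def test_null_trait_zero_mean_accuracy(self, marker_matrix):
        rng = np.random.default_rng(10)
        y = rng.normal(size=60)
        rs = []
        for seed in range(5):
            res = loo_cv("GB", marker_matrix.X[:60],
                         np.random.default_rng(seed).permutation(y),
                         mcmc=MCMCConfig(500, 100, 2, seed))
            rs.append(res.correlations["all"][0])
        assert abs(np.mean(rs)) < 3 * np.std(rs, ddof=1) / np.sqrt(5) + 0.15

    def test_predictive_ability_monotone_in_heritability(self, marker_matrix):
        # matched genetic signal, increasing noise: mean CV accuracy should
        # rise monotonically over h2 in {0.1, 0.4, 0.8}
        X = marker_matrix.X
        means = []
        for h2 in (0.1, 0.4, 0.8):
            level = []
            for trait_seed in range(3):
                rng = np.random.default_rng(100 + trait_seed)
                g = X @ rng.normal(0, 1, X.shape[1])
                g = (g - g.mean()) / g.std(ddof=1)
                y = g * np.sqrt(h2) + rng.normal(0, np.sqrt(1 - h2), len(g))
                y = (y - y.mean()) / y.std(ddof=1)
                out = tp_size_sweep(["GB"], X, y, sizes=[80], n_reps=10,
                                    mcmc=MCMCConfig(800, 200, 2, 0),
                                    rng_seed=3)
                level.append(out[("GB", 80)].mean)
            means.append(np.mean(level))
        assert means[0] < means[1] < means[2]

    def test_optimized_tp_loo_beats_random_tp_quantile(self, marker_matrix,
                                                       polygenic_trait):
        # LOO accuracy of an exchange-optimized TP is at least the 25th
        # percentile of equally-sized random TPs
        from magicgp import CriterionContext, exchange_optimize
        y, _ = polygenic_trait
        n_panel, n_sel = 60, 25
        X = marker_matrix.X[:n_panel]
        K = np.cov(X) * 0 + (X @ X.T) / X.shape[1]
        ctx = CriterionContext(K, 1.0)
        mc = MCMCConfig(500, 100, 2, 0)

        def loo_r(idx):
            idx = np.asarray(sorted(idx))
            res = loo_cv("GB", X[idx], y[:n_panel][idx], mcmc=mc)
            return res.correlations["all"][0]

        sel = exchange_optimize("rscore", ctx, n_sel, max_iters=3,
                                rng_seed=0)
        opt_r = loo_r(sel.selected)
        rng = np.random.default_rng(12)
        rand_rs = [loo_r(rng.choice(n_panel, n_sel, replace=False))
                   for _ in range(12)]
        assert opt_r >= np.percentile(rand_rs, 25)

    def test_sweep_shapes_and_counts(self, marker_matrix, polygenic_trait):
        y, _ = polygenic_trait
        out = tp_size_sweep(["GB", "BayesA"], marker_matrix, y,
                            sizes=[40, 80], n_reps=3,
                            mcmc=MCMCConfig(600, 150, 2, 0), rng_seed=0)
        assert set(out) == {("GB", 40), ("GB", 80),
                            ("BayesA", 40), ("BayesA", 80)}
        for res in out.values():
            assert len(res.correlations) == 3
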