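"""Cross-validation, predictive ability, model comparison, PCA and LD decay.

Predictive ability is the Pearson correlation between GEBVs and adjusted
means in the validation set.  Supported schemes:

* repeated random TP/VP partitions at fixed TP size (with a TP-size sweep);
* leave-one-out (LOO) within a training population;
* CV1 (lines unobserved in every environment) and CV2 (lines observed in
  some environments, predicted in others) for multi-environment models.

Also here: Welch's unequal-variance t-test on per-partition correlation
samples, centered PCA via SVD, and linkage-disequilibrium decay (pairwise
r2 against physical distance, chi-square filtered, averaged in 100-kb bins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import MarkerMatrix, grm, squared_euclidean, gaussian_kernel, \
    estimate_bandwidth
from .gp import KernelGP, MEDataset, MultiEnvGP
from .simulate import GeneticMap
from .wgr import BayesianAlphabetRegressor, MCMCConfig, TEST_MCMC

__all__ = [
    "PartitionSet",
    "CVResult",
    "LDResult",
    "make_random_partitions",
    "make_me_partitions",
    "tp_size_sweep",
    "loo_cv",
    "me_crossval",
    "predictive_ability_summary",
    "welch_compare",
    "run_pca",
    "ld_decay",
    "SE_MODELS",
]

SE_MODELS = ("GB", "GK", "BayesA", "BayesB", "BL")


@dataclass
class PartitionSet:
    scheme: str                       # random-size | LOO | CV1 | CV2
    partitions: list                  # (train_idx, val_idx) or masked cells
    n_reps: int
    seed: int
    meta: dict = field(default_factory=dict)


@dataclass
class CVResult:
    scheme: str
    model: str
    correlations: pd.DataFrame        # rows: partitions; cols: env or "all"
    meta: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.correlations.to_numpy().ravel()

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.values, ddof=1))

    def per_environment(self) -> pd.DataFrame:
        return self.correlations.agg(["mean", "std"]).T


@dataclass
class LDResult:
    pairs: pd.DataFrame               # chrom, dist_bp, r2, p
    binned: pd.DataFrame              # chrom, bin_lo, mean_r2, n_pairs
    genome_binned: pd.DataFrame       # bin_lo, mean_r2, n_pairs


# ---------------------------------------------------------------------------
# partitions
# ---------------------------------------------------------------------------

def make_random_partitions(n: int, tp_size: int, n_reps: int = 100,
                           rng_seed: int = 0) -> PartitionSet:
    """Repeated random TP/VP splits: TP drawn uniformly without replacement,
    validation = remainder."""
    if tp_size >= n:
        raise ValueError("tp_size must be smaller than n")
    rng = np.random.default_rng(rng_seed)
    parts = []
    for _ in range(n_reps):
        perm = rng.permutation(n)
        parts.append((np.sort(perm[:tp_size]), np.sort(perm[tp_size:])))
    return PartitionSet("random-size", parts, n_reps, rng_seed,
                        {"tp_size": tp_size})


def make_me_partitions(data: MEDataset, scheme: str,
                       train_fraction: float = 0.9, n_reps: int = 100,
                       rng_seed: int = 0) -> PartitionSet:
    """CV1 / CV2 masks at a 10% validation fraction by default.

    CV1 masks every observed cell of the sampled lines.  CV2 samples
    line x environment cells stratified by environment and guarantees each
    masked line keeps at least one observed environment.
    """
    if scheme not in ("CV1", "CV2"):
        raise ValueError("scheme must be CV1 or CV2")
    obs = data.Y.notna()
    if scheme == "CV2" and data.n_envs < 2:
        raise ValueError("CV2 requires at least 2 environments")
    rng = np.random.default_rng(rng_seed)
    frac = 1 - train_fraction
    parts = []
    lines = np.array(data.line_ids, dtype=object)
    for _ in range(n_reps):
        cells = []
        if scheme == "CV1":
            k = max(1, int(round(frac * data.n_lines)))
            chosen = rng.choice(data.n_lines, k, replace=False)
            for i in chosen:
                for env in data.env_ids:
                    if obs.iloc[i][env]:
                        cells.append((lines[i], env))
        else:
            masked_per_line = {}
            for env in data.env_ids:
                avail = np.flatnonzero(obs[env].to_numpy())
                k = max(1, int(round(frac * len(avail))))
                chosen = rng.choice(avail, k, replace=False)
                for i in chosen:
                    cells.append((lines[i], env))
                    masked_per_line.setdefault(i, []).append(env)
            # restore one cell for lines that lost every observed env
            for i, envs in masked_per_line.items():
                n_obs_i = int(obs.iloc[i].sum())
                if len(envs) == n_obs_i:
                    give_back = envs[int(rng.integers(len(envs)))]
                    cells.remove((lines[i], give_back))
        parts.append(cells)
    return PartitionSet(scheme, parts, n_reps, rng_seed,
                        {"train_fraction": train_fraction})


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3:
        warnings.warn("fewer than 3 points; correlation skipped", stacklevel=2)
        return np.nan
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("constant predictions; correlation undefined",
                      stacklevel=2)
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def predictive_ability_summary(gebvs, adjusted_means, scheme: str = "custom",
                               model: str = "model") -> CVResult:
    """Pearson correlation per partition (and per environment for ME data).

    ``gebvs`` / ``adjusted_means``: list over partitions of aligned pairs —
    either 1-D arrays, or DataFrames (lines x environments) restricted to
    the validated cells (NaN elsewhere).
    """
    rows = []
    for g, a in zip(gebvs, adjusted_means):
        if isinstance(g, pd.DataFrame):
            row = {}
            for env in g.columns:
                mask = a[env].notna() & g[env].notna()
                row[env] = _pearson(g.loc[mask, env].to_numpy(),
                                    a.loc[mask, env].to_numpy())
            rows.append(row)
        else:
            rows.append({"all": _pearson(np.asarray(g), np.asarray(a))})
    return CVResult(scheme, model, pd.DataFrame(rows))


def welch_compare(cv_a: CVResult | np.ndarray, cv_b: CVResult | np.ndarray):
    """Two-sided Welch's t-test on per-partition correlation samples."""
    a = cv_a.values if isinstance(cv_a, CVResult) else np.asarray(cv_a, float)
    b = cv_b.values if isinstance(cv_b, CVResult) else np.asarray(cv_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 correlations per side")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# single-environment CV drivers
# ---------------------------------------------------------------------------

def _fit_predict_se(model: str, X: np.ndarray, D, K_gb, y: np.ndarray,
                    train: np.ndarray, val: np.ndarray,
                    mcmc: MCMCConfig, seed: int) -> np.ndarray:
    """Train one SE-GP method and return predictions for the validation
    lines.  Kernel methods mask validation phenotypes; marker regressions
    train on the TP rows only."""
    cfg = MCMCConfig(mcmc.niter, mcmc.burnin, mcmc.thin, seed)
    if model in ("GB", "GK"):
        if model == "GB":
            K = K_gb
        else:
            h, _ = estimate_bandwidth(
                type(D)(D.D[np.ix_(train, train)],
                        [D.line_ids[i] for i in train], D.scale),
                y[train])
            K = np.exp(-h * D.D)
        ymask = y.astype(float).copy()
        ymask[val] = np.nan
        fit = KernelGP(cfg.niter, cfg.burnin, cfg.thin, cfg.seed).fit(K, ymask)
        return fit.u_[val]
    name = {"BayesA": "bayes_a", "BayesB": "bayes_b", "BL": "bl"}[model]
    est = BayesianAlphabetRegressor(model=name, niter=cfg.niter,
                                    burnin=cfg.burnin, thin=cfg.thin,
                                    seed=cfg.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X[train], y[train])
    return est.predict(X[val], include_intercept=False)


def tp_size_sweep(models, X, y, sizes, n_reps: int = 100,
                  mcmc: MCMCConfig | None = None, rng_seed: int = 0) -> dict:
    """CV of SE-GP models across TP sizes.

    Returns {(model, size): CVResult}; each result holds one Pearson r per
    random partition (fits = len(models) * len(sizes) * n_reps).
    """
    mcmc = mcmc or TEST_MCMC
    Xa = X.X if isinstance(X, MarkerMatrix) else np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    needs_kernel = any(m in ("GB", "GK") for m in models)
    K_gb = grm(Xa).K if needs_kernel else None
    D = squared_euclidean(Xa) if "GK" in models else None
    out = {}
    for size in sizes:
        parts = make_random_partitions(n, size, n_reps, rng_seed + size)
        for model in models:
            gebvs, obs = [], []
            for rep, (train, val) in enumerate(parts.partitions):
                pred = _fit_predict_se(model, Xa, D, K_gb, y, train, val,
                                       mcmc, seed=rng_seed * 1000 + rep)
                gebvs.append(pred)
                obs.append(y[val])
            res = predictive_ability_summary(gebvs, obs, "random-size", model)
            res.meta["tp_size"] = size
            out[(model, size)] = res
    return out


def loo_cv(model: str, X, y, mcmc: MCMCConfig | None = None,
           rng_seed: int = 0) -> CVResult:
    """Leave-one-out within a set of lines: n fits, one correlation from the
    n held-out predictions."""
    mcmc = mcmc or TEST_MCMC
    Xa = X.X if isinstance(X, MarkerMatrix) else np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 3:
        raise ValueError("LOO needs at least 3 lines")
    K_gb = grm(Xa).K if model in ("GB", "GK") else None
    D = squared_euclidean(Xa) if model == "GK" else None
    preds = np.empty(n)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        preds[i] = _fit_predict_se(model, Xa, D, K_gb, y, train,
                                   np.array([i]), mcmc,
                                   seed=rng_seed * 1000 + i)[0]
    r = _pearson(preds, y)
    res = CVResult("LOO", model, pd.DataFrame({"all": [r]}))
    res.meta["predictions"] = preds
    return res


# ---------------------------------------------------------------------------
# multi-environment CV driver
# ---------------------------------------------------------------------------

def me_crossval(data: MEDataset, model: str, K, partitions: PartitionSet,
                env_kernels=None, mcmc: MCMCConfig | None = None) -> CVResult:
    """Refit an ME-GP model on each partition's masked data and correlate
    predicted vs observed adjusted means at the masked cells, per
    environment."""
    mcmc = mcmc or TEST_MCMC
    gebvs, obs = [], []
    for rep, cells in enumerate(partitions.partitions):
        masked = data.with_mask(cells)
        est = MultiEnvGP(model=model, niter=mcmc.niter, burnin=mcmc.burnin,
                         thin=mcmc.thin, seed=mcmc.seed * 1000 + rep)
        est.fit(masked, K, env_kernels=env_kernels)
        gmask = pd.DataFrame(np.nan, index=data.Y.index, columns=data.Y.columns)
        amask = gmask.copy()
        for line, env in cells:
            gmask.loc[line, env] = est.gebv_.loc[line, env]
            amask.loc[line, env] = data.Y.loc[line, env]
        gebvs.append(gmask)
        obs.append(amask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = predictive_ability_summary(gebvs, obs, partitions.scheme, model)
    res.meta["n_reps"] = partitions.n_reps
    return res


# ---------------------------------------------------------------------------
# population structure and LD
# ---------------------------------------------------------------------------

def run_pca(X, n_components: int = 2) -> tuple:
    """Centered PCA via SVD: (scores, explained-variance fractions)."""
    Xa = X.X if isinstance(X, MarkerMatrix) else np.asarray(X, float)
    if Xa.shape[0] < 2:
        raise ValueError("need at least 2 lines")
    Xc = Xa - Xa.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix has no principal components")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    k = min(n_components, len(s))
    return U[:, :k] * s[:k], frac[:k]


def ld_decay(dosages, genetic_map: GeneticMap, p_cut: float = 0.001,
             bin_bp: int = 100_000) -> LDResult:
    """Within-chromosome pairwise LD r2 vs physical distance.

    For DH lines the dosage columns are haplotypes (alleles = dosage/2), so
    r2 is the squared allelic correlation.  The association p-value uses the
    chi-square statistic n * r2 with 1 df; pairs with p > ``p_cut`` are
    filtered out, the rest averaged in half-open ``bin_bp`` windows per
    chromosome plus a marker-pair-weighted genome-wide profile.
    """
    G = np.asarray(dosages, float) / 2.0
    n = G.shape[0]
    bp = genetic_map.table["bp"].to_numpy()
    recs = []
    for chrom, sl in genetic_map.chrom_slices().items():
        cols = G[:, sl]
        pos = bp[sl]
        keep = cols.std(axis=0) > 0
        cols, pos = cols[:, keep], pos[keep]
        if cols.shape[1] < 2:
            continue
        R = np.corrcoef(cols, rowvar=False)
        iu, ju = np.triu_indices(cols.shape[1], k=1)
        r2 = R[iu, ju] ** 2
        pvals = stats.chi2.sf(n * r2, 1)
        dist = np.abs(pos[iu] - pos[ju])
        ok = pvals <= p_cut
        recs.append(pd.DataFrame({
            "chrom": chrom, "dist_bp": dist[ok], "r2": r2[ok], "p": pvals[ok],
        }))
    pairs = pd.concat(recs, ignore_index=True) if recs else pd.DataFrame(
        columns=["chrom", "dist_bp", "r2", "p"])
    if len(pairs):
        pairs["bin_lo"] = (pairs["dist_bp"] // bin_bp).astype(int) * bin_bp
        binned = (pairs.groupby(["chrom", "bin_lo"])
                  .agg(mean_r2=("r2", "mean"), n_pairs=("r2", "size"))
                  .reset_index())
        genome = (pairs.groupby("bin_lo")
                  .agg(mean_r2=("r2", "mean"), n_pairs=("r2", "size"))
                  .reset_index())
    else:
        binned = pd.DataFrame(columns=["chrom", "bin_lo", "mean_r2", "n_pairs"])
        genome = pd.DataFrame(columns=["bin_lo", "mean_r2", "n_pairs"])
    return LDResult(pairs, binned, genome)
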