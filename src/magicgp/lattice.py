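"""Adjusted means from alpha-lattice trials.

Per environment the plot model is

    y_ijk = mu + Rep_i + Block_j(Rep_i) + Gen_k + beta_DH * DH_ijk + e_ijk

with replicate (and the days-to-heading covariate) fixed, incomplete block
within replicate random, genotype random with Gen_k ~ NIID(0, sg2) and
e_ijk ~ NIID(0, se2).  Genotype BLUPs are the adjusted means used as
genomic-prediction phenotypes; variance components give the line-mean
broad-sense heritability H2 = sg2 / (sg2 + se2 / r) for r replicates.

Variance components are estimated by EM-REML on Henderson's mixed-model
equations; predictions of the random genotype effects at the REML estimates
are the BLUPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AlphaLatticeModel",
    "AdjustedMeansTable",
    "PhenotypeStandardizer",
    "fit_lattice_model",
    "compute_heritability",
    "adjusted_means_by_environment",
    "standardize_phenotypes",
]

REQUIRED_COLUMNS = ["env", "rep", "block", "genotype", "DH", "GY"]


def _validate_plots(plots: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(plots.columns)
    if missing:
        raise ValueError(f"plot table missing columns {sorted(missing)}")
    key = plots[["env", "rep", "block", "genotype"]]
    if key.duplicated().any():
        raise ValueError("duplicated (env, rep, block, genotype) plot key")
    return plots


class AlphaLatticeModel:
    """Mixed-model fit of one environment's alpha-lattice trial.

    Parameters
    ----------
    use_dh_covariate : include the days-to-heading plot covariate as a fixed
        regressor.
    max_iter, tol : EM-REML iteration cap and relative-change tolerance on
        the variance components.

    Fitted attributes (sklearn convention, trailing underscore)
    ----------------------------------------------------------
    sigma_g2_, sigma_b2_, sigma_e2_ : genotype, block and residual variances.
    blups_ : pd.Series of genotype BLUPs (the adjusted means, mean ~ 0).
    h2_ : line-mean broad-sense heritability.
    fixed_effects_ : pd.Series (intercept, replicate contrasts, DH slope).
    converged_, n_iter_ : convergence report.
    """

    def __init__(self, use_dh_covariate: bool = True, max_iter: int = 500,
                 tol: float = 1e-6):
        self.use_dh_covariate = use_dh_covariate
        self.max_iter = max_iter
        self.tol = tol

    # -- sklearn plumbing --------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"use_dh_covariate": self.use_dh_covariate,
                "max_iter": self.max_iter, "tol": self.tol}

    def set_params(self, **params) -> "AlphaLatticeModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # ----------------------------------------------------------------------
    def fit(self, plots: pd.DataFrame) -> "AlphaLatticeModel":
        plots = _validate_plots(plots)
        data = plots.dropna(subset=["GY"]).reset_index(drop=True)
        if data["genotype"].nunique() < 2:
            raise ValueError("need at least 2 genotypes")
        y = data["GY"].to_numpy(float)
        n = len(y)

        # fixed design: intercept + replicate contrasts (+ DH covariate)
        rep_levels = sorted(data["rep"].unique())
        X_cols = [np.ones(n)]
        names = ["intercept"]
        for r in rep_levels[1:]:
            X_cols.append((data["rep"] == r).to_numpy(float))
            names.append(f"rep[{r}]")
        if self.use_dh_covariate:
            X_cols.append(data["DH"].to_numpy(float))
            names.append("DH")
        X = np.column_stack(X_cols)
        rank_x = np.linalg.matrix_rank(X)
        if rank_x < X.shape[1]:
            raise ValueError(
                "singular fixed-effect design (aliased among "
                f"{names}); drop the aliased factor"
            )

        geno_levels = pd.Index(sorted(data["genotype"].unique()))
        gi = geno_levels.get_indexer(data["genotype"])
        Z1 = np.zeros((n, len(geno_levels)))
        Z1[np.arange(n), gi] = 1.0

        blk = data["rep"].astype(str) + ":" + data["block"].astype(str)
        blk_levels = pd.Index(sorted(blk.unique()))
        bi = blk_levels.get_indexer(blk)
        Z2 = np.zeros((n, len(blk_levels)))
        Z2[np.arange(n), bi] = 1.0

        q1, q2 = Z1.shape[1], Z2.shape[1]
        W = np.hstack([X, Z1, Z2])
        WtW = W.T @ W
        Wty = W.T @ y
        yty = float(y @ y)
        p_fix = X.shape[1]
        sl1 = slice(p_fix, p_fix + q1)
        sl2 = slice(p_fix + q1, p_fix + q1 + q2)

        vy = float(np.var(y, ddof=1))
        sg2, sb2, se2 = 0.4 * vy, 0.1 * vy, 0.5 * vy
        floor = 1e-10 * vy
        converged = False
        history = []
        for it in range(1, self.max_iter + 1):
            C = WtW.copy()
            C[sl1, sl1] += np.eye(q1) * (se2 / sg2)
            C[sl2, sl2] += np.eye(q2) * (se2 / sb2)
            Cinv = np.linalg.inv(C)
            sol = Cinv @ Wty
            u1, u2 = sol[sl1], sol[sl2]
            new_sg2 = (u1 @ u1 + se2 * np.trace(Cinv[sl1, sl1])) / q1
            new_sb2 = (u2 @ u2 + se2 * np.trace(Cinv[sl2, sl2])) / q2
            new_se2 = (yty - sol @ Wty) / (n - rank_x)
            new_sg2, new_sb2 = max(new_sg2, floor), max(new_sb2, floor)
            rel = max(
                abs(new_sg2 - sg2) / max(sg2, floor),
                abs(new_sb2 - sb2) / max(sb2, floor),
                abs(new_se2 - se2) / max(se2, floor),
            )
            sg2, sb2, se2 = new_sg2, new_sb2, new_se2
            if rel < self.tol:
                converged = True
                break
            # Aitken extrapolation: EM converges linearly, so jump along the
            # geometric tail every few sweeps (guarded to stay positive)
            history.append(np.array([sg2, sb2, se2]))
            if len(history) >= 3 and it % 3 == 0:
                t0, t1, t2 = history[-3], history[-2], history[-1]
                d1, d2 = t1 - t0, t2 - t1
                with np.errstate(divide="ignore", invalid="ignore"):
                    r = np.where(np.abs(d1) > 0, d2 / d1, 0.0)
                    ok = (r > 0) & (r < 0.995)
                    acc = np.where(ok, t2 + r / np.where(ok, 1 - r, 1.0) * d2,
                                   t2)
                # zero is an EM fixed point: cap the jump factor so one
                # accelerated step cannot collapse a component
                acc = np.clip(acc, t2 / 3, 3 * t2)
                acc = np.maximum(acc, floor)
                sg2, sb2, se2 = acc

        C = WtW.copy()
        C[sl1, sl1] += np.eye(q1) * (se2 / sg2)
        C[sl2, sl2] += np.eye(q2) * (se2 / sb2)
        sol = np.linalg.solve(C, Wty)

        self.n_obs_ = n
        self.sigma_g2_, self.sigma_b2_, self.sigma_e2_ = sg2, sb2, se2
        self.converged_, self.n_iter_ = converged, it
        self.fixed_effects_ = pd.Series(sol[:p_fix], index=names)
        self.blups_ = pd.Series(sol[sl1], index=geno_levels, name="BLUP")
        self.block_effects_ = pd.Series(sol[sl2], index=blk_levels)
        self.n_reps_ = len(rep_levels)
        self.h2_ = compute_heritability(self, self.n_reps_)
        return self

    def predict(self, genotypes) -> np.ndarray:
        """Adjusted mean (BLUP) per requested genotype."""
        return self.blups_.reindex(genotypes).to_numpy()


def fit_lattice_model(plots: pd.DataFrame, use_dh_covariate: bool = True,
                      **kwargs) -> AlphaLatticeModel:
    """Functional wrapper over :class:`AlphaLatticeModel`."""
    return AlphaLatticeModel(use_dh_covariate=use_dh_covariate, **kwargs).fit(plots)


def compute_heritability(fit: AlphaLatticeModel, n_reps: int) -> float:
    """Line-mean broad-sense heritability H2 = sg2 / (sg2 + se2/r)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    sg2, se2 = fit.sigma_g2_, fit.sigma_e2_
    h2 = sg2 / (sg2 + se2 / n_reps)
    return float(np.clip(h2, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Adjusted-means table and standardization
# ---------------------------------------------------------------------------

@dataclass
class AdjustedMeansTable:
    """Genotype x environment BLUP matrix plus per-environment H2 and the
    standardization constants needed to back-transform."""

    blups: pd.DataFrame
    h2: dict
    center: pd.Series | None = None
    scale: pd.Series | None = None

    @property
    def standardized(self) -> bool:
        return self.center is not None


def adjusted_means_by_environment(
    plots: pd.DataFrame, use_dh_covariate: bool = True, **kwargs
) -> AdjustedMeansTable:
    """Fit the lattice model separately per environment and assemble the
    adjusted-means table."""
    _validate_plots(plots)
    blup_cols, h2 = {}, {}
    for env, sub in plots.groupby("env", sort=True):
        fit = fit_lattice_model(sub, use_dh_covariate=use_dh_covariate, **kwargs)
        blup_cols[env] = fit.blups_
        h2[env] = fit.h2_
    return AdjustedMeansTable(pd.DataFrame(blup_cols), h2)


class PhenotypeStandardizer:
    """Center each environment by its overall mean and divide by the sample
    standard deviation (idempotent on already-standardized columns)."""

    def fit(self, means: pd.DataFrame) -> "PhenotypeStandardizer":
        sd = means.std(ddof=1)
        zero = sd[(sd == 0) | sd.isna()]
        if len(zero):
            raise ValueError(
                f"zero-variance environment(s): {list(zero.index)}"
            )
        self.center_ = means.mean()
        self.scale_ = sd
        return self

    def transform(self, means: pd.DataFrame) -> pd.DataFrame:
        return (means - self.center_) / self.scale_

    def fit_transform(self, means: pd.DataFrame) -> pd.DataFrame:
        return self.fit(means).transform(means)

    def inverse_transform(self, z: pd.DataFrame) -> pd.DataFrame:
        return z * self.scale_ + self.center_


def standardize_phenotypes(table: AdjustedMeansTable) -> AdjustedMeansTable:
    """Standardized copy of an adjusted-means table (constants stored)."""
    sc = PhenotypeStandardizer()
    z = sc.fit_transform(table.blups)
    return AdjustedMeansTable(z, dict(table.h2), sc.center_, sc.scale_)
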