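"""Kernel genomic prediction: single-environment RKHS/GBLUP and
multi-environment GxE models.

Single environment
------------------
``KernelGP`` fits y = 1 mu + u + e with u ~ N(0, su2 K) and
e ~ N(0, I se2) by Gibbs sampling in the eigenbasis of K.  With the
genetic effect reparametrized as u = L b (K = L L', b ~ N(0, su2 I)) and the
observed-row design rotated by its SVD, the regression coordinates have an
orthonormal design, so the whole coefficient vector is drawn jointly in O(n)
per iteration.  Lines with missing phenotypes are simply excluded from the
likelihood; their genetic values are still predicted, which is what the
cross-validation schemes need.  With the linear kernel K = XX'/p this is
GBLUP; with the Gaussian kernel it is the non-linear RKHS regression.

Multi-environment
-----------------
``MultiEnvGP`` stacks observations across environments,
y = 1 mu + Ze be + Zu u0 + (interaction) + e, with environment effects
fixed (flat priors) and the main genetic effect u0 ~ N(0, su02 K):

* **MM**   — main effect only; one GEBV per line shared by environments.
* **MDs**  — adds an interaction with covariance
  sue2 * [Zu K Zu'] o [Ze Ze'] (Hadamard).  Because [Ze Ze'] is the
  same-environment indicator, this is exactly one independent effect
  v_j ~ N(0, sue2 K) per environment sharing a single variance, which is
  how it is sampled (the N x N Hadamard product is never formed).
* **MDe**  — environment-specific deviations u_Ej ~ N(0, suEj2 K_j), one
  variance per environment (block-diagonal K_E); K_j is the shared GB
  kernel or an environment-specific Gaussian kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import Kernel
from .wgr import MCMCConfig, TEST_MCMC, geweke_z, effective_sample_size

__all__ = [
    "MEDataset",
    "KernelGP",
    "MultiEnvGP",
    "fit_se_kernel",
    "fit_mm",
    "fit_mds",
    "fit_mde",
]

_EIG_TOL = 1e-9


def _kernel_matrix(K) -> np.ndarray:
    return K.K if isinstance(K, Kernel) else np.asarray(K, float)


def _kernel_root(K: np.ndarray) -> np.ndarray:
    """L with K = L L', columns restricted to eigenvalues above tolerance."""
    s, V = np.linalg.eigh((K + K.T) / 2)
    keep = s > _EIG_TOL * max(s.max(), 1.0)
    if s.min() < -1e-6:
        raise np.linalg.LinAlgError("kernel is not PSD")
    return V[:, keep] * np.sqrt(s[keep])


@dataclass
class _RotatedDesign:
    """SVD-rotated design for one random term restricted to observed rows."""

    U: np.ndarray        # (n_rows, r) orthonormal columns
    d: np.ndarray        # (r,) singular values
    M: np.ndarray        # (n_lines, r) maps coefficients to all-line effects
    rows: np.ndarray     # indices into the stacked observation vector

    @classmethod
    def build(cls, L: np.ndarray, line_idx: np.ndarray,
              rows: np.ndarray) -> "_RotatedDesign":
        A = L[line_idx]
        U, d, Tt = np.linalg.svd(A, full_matrices=False)
        return cls(U, d, L @ Tt.T, rows)

    def draw(self, resid: np.ndarray, su2: float, se2: float,
             rng: np.random.Generator) -> tuple:
        """Joint draw of the rotated coefficients given the partial residual
        (this term's contribution already removed).  Returns (c, contrib)."""
        ty = self.U.T @ resid[self.rows]
        lam = se2 / su2
        denom = self.d ** 2 + lam
        mean = self.d * ty / denom
        c = mean + rng.standard_normal(len(self.d)) * np.sqrt(se2 / denom)
        return c, self.U @ (self.d * c)


# ---------------------------------------------------------------------------
# Single environment
# ---------------------------------------------------------------------------

class KernelGP:
    """Single-kernel GP sampler (GBLUP when K = XX'/p, RKHS with GK).

    Fitted attributes: ``mu_``, ``u_`` (genetic values for *all* lines,
    observed or masked), ``sigma_u2_``, ``sigma_e2_``, posterior chains and
    ``diagnostics_``.
    """

    def __init__(self, niter: int = 5000, burnin: int = 1000, thin: int = 5,
                 seed: int = 0, r2: float = 0.5, df: float = 5.0):
        self.niter = niter
        self.burnin = burnin
        self.thin = thin
        self.seed = seed
        self.r2 = r2
        self.df = df

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k)
                for k in ("niter", "burnin", "thin", "seed", "r2", "df")}

    def set_params(self, **params) -> "KernelGP":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, K, y) -> "KernelGP":
        MCMCConfig(self.niter, self.burnin, self.thin, self.seed)
        Km = _kernel_matrix(K)
        y = np.asarray(y, float)
        n = len(y)
        if Km.shape != (n, n):
            raise ValueError("kernel and phenotype dimensions differ")
        obs = np.flatnonzero(np.isfinite(y))
        if len(obs) < 3:
            raise ValueError("need at least 3 observed phenotypes")
        L = _kernel_root(Km)
        design = _RotatedDesign.build(L, obs, np.arange(len(obs)))
        yo = y[obs]
        n_o = len(yo)
        rng = np.random.default_rng(self.seed)

        vy = float(np.var(yo))
        kdiag = float(np.mean(np.diag(Km)))
        df, r2 = float(self.df), float(self.r2)
        scale_u = vy * r2 * (df + 2) / (df * max(kdiag, 1e-12))
        scale_e = vy * (1 - r2) * (df + 2) / df

        mu = float(yo.mean())
        su2, se2 = r2 * vy + 1e-8, (1 - r2) * vy + 1e-8
        r = len(design.d)
        c = np.zeros(r)
        contrib = np.zeros(n_o)
        sU = design.U.sum(axis=0)
        sum_y = yo.sum()

        n_keep = (self.niter - self.burnin + self.thin - 1) // self.thin
        c_mean = np.zeros(r)
        mu_mean = 0.0
        su2_chain = np.empty(n_keep)
        se2_chain = np.empty(n_keep)
        kept = 0
        for it in range(self.niter):
            # intercept (flat prior)
            mu = (sum_y - contrib.sum()) / n_o \
                + rng.standard_normal() * np.sqrt(se2 / n_o)
            # genetic coefficients, jointly
            resid_excl = yo - mu
            c, contrib = design.draw(resid_excl, su2, se2, rng)
            resid = resid_excl - contrib
            # variances (scaled-inverse-chi-square)
            su2 = (df * scale_u + c @ c) / rng.chisquare(df + r)
            se2 = (df * scale_e + resid @ resid) / rng.chisquare(df + n_o)
            if it >= self.burnin and (it - self.burnin) % self.thin == 0:
                c_mean += c
                mu_mean += mu
                su2_chain[kept] = su2
                se2_chain[kept] = se2
                kept += 1
        c_mean /= kept
        self.mu_ = mu_mean / kept
        self.u_ = design.M @ c_mean
        self.sigma_u2_chain_ = su2_chain
        self.sigma_e2_chain_ = se2_chain
        self.sigma_u2_ = float(su2_chain.mean())
        self.sigma_e2_ = float(se2_chain.mean())
        self.observed_ = obs
        self.diagnostics_ = {
            "geweke_z_sigma_e2": geweke_z(se2_chain),
            "ess_sigma_e2": effective_sample_size(se2_chain),
        }
        return self

    def predict(self, indices=None, include_intercept: bool = False):
        u = self.u_ if indices is None else self.u_[np.asarray(indices)]
        return u + self.mu_ if include_intercept else u


def fit_se_kernel(K, y, mcmc: MCMCConfig | None = None, **kwargs) -> KernelGP:
    mcmc = mcmc or TEST_MCMC
    return KernelGP(niter=mcmc.niter, burnin=mcmc.burnin, thin=mcmc.thin,
                    seed=mcmc.seed, **kwargs).fit(K, y)


# ---------------------------------------------------------------------------
# Multi-environment dataset
# ---------------------------------------------------------------------------

@dataclass
class MEDataset:
    """Stacked multi-environment phenotypes.

    Built from a lines x environments table (NaN = unobserved).  Cells can
    be additionally masked for cross-validation; masked cells are excluded
    from the likelihood but still predicted.
    """

    Y: pd.DataFrame                        # lines x environments
    masked: set = field(default_factory=set)   # {(line_id, env_id)}

    @property
    def line_ids(self) -> list:
        return list(self.Y.index)

    @property
    def env_ids(self) -> list:
        return list(self.Y.columns)

    @property
    def n_lines(self) -> int:
        return self.Y.shape[0]

    @property
    def n_envs(self) -> int:
        return self.Y.shape[1]

    def with_mask(self, cells) -> "MEDataset":
        cells = set(cells)
        unknown = [c for c in cells
                   if c[0] not in self.Y.index or c[1] not in self.Y.columns]
        if unknown:
            raise KeyError(f"unknown cells {unknown[:3]}")
        return MEDataset(self.Y, self.masked | cells)

    def stacked(self) -> tuple:
        """(y, line_idx, env_idx) for observed, unmasked cells, env-major."""
        ys, li, ei = [], [], []
        vals = self.Y.to_numpy(float)
        for j, env in enumerate(self.Y.columns):
            for i, line in enumerate(self.Y.index):
                if np.isfinite(vals[i, j]) and (line, env) not in self.masked:
                    ys.append(vals[i, j])
                    li.append(i)
                    ei.append(j)
        return np.asarray(ys), np.asarray(li, int), np.asarray(ei, int)


# ---------------------------------------------------------------------------
# Multi-environment models
# ---------------------------------------------------------------------------

class MultiEnvGP:
    """MM / MDs / MDe sampler (see module docstring).

    Fitted attributes: ``mu_``, ``beta_env_`` (fixed environment effects,
    centered), ``u_main_`` (per line), ``u_env_`` (lines x envs, zero for
    MM), ``gebv_`` (lines x envs DataFrame covering masked cells),
    ``sigma_u02_``, ``sigma_ue2_`` (MDs), ``sigma_uEj2_`` (MDe, per env),
    ``sigma_e2_``, ``variance_table_`` and ``diagnostics_``.
    """

    def __init__(self, model: str = "MM", niter: int = 5000,
                 burnin: int = 1000, thin: int = 5, seed: int = 0,
                 r2: float = 0.5, df: float = 5.0):
        self.model = model
        self.niter = niter
        self.burnin = burnin
        self.thin = thin
        self.seed = seed
        self.r2 = r2
        self.df = df

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k)
                for k in ("model", "niter", "burnin", "thin", "seed",
                          "r2", "df")}

    def set_params(self, **params) -> "MultiEnvGP":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, data: MEDataset, K, env_kernels=None) -> "MultiEnvGP":
        MCMCConfig(self.niter, self.burnin, self.thin, self.seed)
        if self.model not in ("MM", "MDs", "MDe"):
            raise ValueError(f"unknown model {self.model!r}")
        y, line_idx, env_idx = data.stacked()
        n_env, n_lines = data.n_envs, data.n_lines
        env_counts = np.bincount(env_idx, minlength=n_env)
        if (env_counts == 0).any():
            empty = [data.env_ids[j] for j in np.flatnonzero(env_counts == 0)]
            raise ValueError(f"environment(s) with zero observations: {empty}")
        Km = _kernel_matrix(K)
        if Km.shape != (n_lines, n_lines):
            raise ValueError("kernel dimension must match the line count")
        L = _kernel_root(Km)
        n_obs = len(y)
        rng = np.random.default_rng(self.seed)

        main = _RotatedDesign.build(L, line_idx, np.arange(n_obs))
        env_rows = [np.flatnonzero(env_idx == j) for j in range(n_env)]

        interaction = self.model in ("MDs", "MDe")
        env_designs = []
        if interaction:
            if self.model == "MDe" and env_kernels is not None:
                if len(env_kernels) != n_env:
                    raise ValueError(
                        "need one environment kernel per environment"
                    )
                Ls = [_kernel_root(_kernel_matrix(k)) for k in env_kernels]
            else:
                Ls = [L] * n_env
            for j in range(n_env):
                rows = env_rows[j]
                env_designs.append(
                    _RotatedDesign.build(Ls[j], line_idx[rows], rows)
                )

        vy = float(np.var(y))
        kdiag = float(np.mean(np.diag(Km)))
        df, r2 = float(self.df), float(self.r2)
        n_gen_terms = 2 if interaction else 1
        share = r2 / n_gen_terms
        scale_u0 = vy * share * (df + 2) / (df * max(kdiag, 1e-12))
        scale_ue = scale_u0
        scale_e = vy * (1 - r2) * (df + 2) / df

        alpha = np.array([y[rows].mean() for rows in env_rows])
        su02 = share * vy + 1e-8
        se2 = (1 - r2) * vy + 1e-8
        sue2 = share * vy + 1e-8            # MDs shared
        suej2 = np.full(n_env, share * vy + 1e-8)  # MDe per env

        c0 = np.zeros(len(main.d))
        main_contrib = np.zeros(n_obs)
        cjs = [np.zeros(len(d.d)) for d in env_designs]
        int_contrib = np.zeros(n_obs)

        n_keep = (self.niter - self.burnin + self.thin - 1) // self.thin
        c0_mean = np.zeros_like(c0)
        cj_means = [np.zeros_like(c) for c in cjs]
        alpha_mean = np.zeros(n_env)
        su02_chain = np.empty(n_keep)
        se2_chain = np.empty(n_keep)
        sue2_chain = np.empty(n_keep)
        suej2_chain = np.empty((n_keep, n_env))
        kept = 0

        for it in range(self.niter):
            # fixed environment intercepts (flat prior)
            base = y - main_contrib - int_contrib
            for j in range(n_env):
                rows = env_rows[j]
                alpha[j] = base[rows].mean() \
                    + rng.standard_normal() * np.sqrt(se2 / env_counts[j])
            fixed = alpha[env_idx]
            # main genetic effect
            resid_excl = y - fixed - int_contrib
            c0, main_contrib = main.draw(resid_excl, su02, se2, rng)
            # interaction effects per environment
            if interaction:
                resid_base = y - fixed - main_contrib
                for j, dj in enumerate(env_designs):
                    var_j = sue2 if self.model == "MDs" else suej2[j]
                    cjs[j], contrib_j = dj.draw(resid_base, var_j, se2, rng)
                    int_contrib[dj.rows] = contrib_j
            resid = y - fixed - main_contrib - int_contrib
            # variances
            su02 = (df * scale_u0 + c0 @ c0) / rng.chisquare(df + len(c0))
            if self.model == "MDs":
                ss = sum(float(c @ c) for c in cjs)
                r_tot = sum(len(c) for c in cjs)
                sue2 = (df * scale_ue + ss) / rng.chisquare(df + r_tot)
            elif self.model == "MDe":
                for j, c in enumerate(cjs):
                    suej2[j] = (df * scale_ue + c @ c) / \
                        rng.chisquare(df + len(c))
            se2 = (df * scale_e + resid @ resid) / rng.chisquare(df + n_obs)
            if it >= self.burnin and (it - self.burnin) % self.thin == 0:
                c0_mean += c0
                for j in range(len(cjs)):
                    cj_means[j] += cjs[j]
                alpha_mean += alpha
                su02_chain[kept] = su02
                se2_chain[kept] = se2
                sue2_chain[kept] = sue2
                suej2_chain[kept] = suej2
                kept += 1

        c0_mean /= kept
        alpha_mean /= kept
        self.mu_ = float(alpha_mean.mean())
        self.beta_env_ = pd.Series(alpha_mean - self.mu_, index=data.env_ids)
        self.u_main_ = pd.Series(main.M @ c0_mean, index=data.line_ids)
        u_env = np.zeros((n_lines, n_env))
        if interaction:
            for j, dj in enumerate(env_designs):
                u_env[:, j] = dj.M @ (cj_means[j] / kept)
        self.u_env_ = pd.DataFrame(u_env, index=data.line_ids,
                                   columns=data.env_ids)
        gebv = self.u_main_.to_numpy()[:, None] + u_env
        self.gebv_ = pd.DataFrame(gebv, index=data.line_ids,
                                  columns=data.env_ids)
        self.sigma_u02_ = float(su02_chain.mean())
        self.sigma_e2_ = float(se2_chain.mean())
        self.sigma_e2_chain_ = se2_chain
        self.sigma_u02_chain_ = su02_chain
        rows = [("residual", "-", self.sigma_e2_, float(se2_chain.std())),
                ("genetic_main", "-", self.sigma_u02_,
                 float(su02_chain.std()))]
        if self.model == "MDs":
            self.sigma_ue2_ = float(sue2_chain.mean())
            rows.append(("genetic_interaction", "-", self.sigma_ue2_,
                         float(sue2_chain.std())))
        if self.model == "MDe":
            self.sigma_uEj2_ = pd.Series(suej2_chain.mean(axis=0),
                                         index=data.env_ids)
            for env, m, s in zip(data.env_ids, suej2_chain.mean(axis=0),
                                 suej2_chain.std(axis=0)):
                rows.append(("genetic_env_specific", env, float(m), float(s)))
        self.variance_table_ = pd.DataFrame(
            rows, columns=["component", "environment", "mean", "sd"]
        )
        self.diagnostics_ = {
            "geweke_z_sigma_e2": geweke_z(se2_chain),
            "ess_sigma_e2": effective_sample_size(se2_chain),
        }
        return self

    def predict(self, lines=None, envs=None) -> pd.DataFrame:
        g = self.gebv_
        if lines is not None:
            g = g.loc[lines]
        if envs is not None:
            g = g[envs]
        return g


def fit_mm(data: MEDataset, K, mcmc: MCMCConfig | None = None,
           **kwargs) -> MultiEnvGP:
    mcmc = mcmc or TEST_MCMC
    return MultiEnvGP(model="MM", niter=mcmc.niter, burnin=mcmc.burnin,
                      thin=mcmc.thin, seed=mcmc.seed, **kwargs).fit(data, K)


def fit_mds(data: MEDataset, K, mcmc: MCMCConfig | None = None,
            **kwargs) -> MultiEnvGP:
    mcmc = mcmc or TEST_MCMC
    return MultiEnvGP(model="MDs", niter=mcmc.niter, burnin=mcmc.burnin,
                      thin=mcmc.thin, seed=mcmc.seed, **kwargs).fit(data, K)


def fit_mde(data: MEDataset, K, env_kernels=None,
            mcmc: MCMCConfig | None = None, **kwargs) -> MultiEnvGP:
    mcmc = mcmc or TEST_MCMC
    return MultiEnvGP(model="MDe", niter=mcmc.niter, burnin=mcmc.burnin,
                      thin=mcmc.thin, seed=mcmc.seed, **kwargs).fit(
                          data, K, env_kernels=env_kernels)
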