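"""Bayesian whole-genome marker regression (the "Bayesian alphabet").

Three Gibbs-sampled shrinkage regressions of a standardized phenotype on a
standardized marker matrix:

* **BayesA** — every marker has its own variance with a scaled-inverse-chi2
  prior, marginally a scaled-t prior on effects; no effect is exactly zero.
* **BayesB** — spike-and-slab: each effect is exactly zero with probability
  ``pi_zero`` and otherwise drawn from the BayesA-style slab, matching the
  view that many markers contribute nothing to the trait.
* **Bayesian LASSO (BL)** — double-exponential prior via the
  exponential-mixture-of-normals augmentation, with the regularization
  parameter lambda given a diffuse Gamma hyper-prior on lambda^2.

GEBVs are X @ posterior-mean effects.  Default hyperparameters partition an
assumed model R2 of 0.5 between genetic and residual variance with 5 prior
degrees of freedom; all are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._samplers import bayes_a_sampler, bayes_b_sampler, bayes_l_sampler
from .kernels import MarkerMatrix

__all__ = [
    "MCMCConfig",
    "BayesianAlphabetRegressor",
    "fit_wgr",
    "predict_gebv",
    "geweke_z",
    "effective_sample_size",
    "TEST_MCMC",
    "PAPER_MCMC",
]


@dataclass
class MCMCConfig:
    niter: int = 5000
    burnin: int = 1000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burnin >= self.niter:
            raise ValueError("burn-in must be smaller than the iteration count")
        if self.thin < 1:
            raise ValueError("thinning must be >= 1")


TEST_MCMC = MCMCConfig(5000, 1000, 5)
PAPER_MCMC = MCMCConfig(500_000, 10_000, 5)


# ---------------------------------------------------------------------------
# chain diagnostics
# ---------------------------------------------------------------------------

def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing the means of the first and last
    chain segments (naive variance estimate; adequate for thinned chains)."""
    chain = np.asarray(chain, float)
    n = len(chain)
    a = chain[: max(int(first * n), 2)]
    b = chain[-max(int(last * n), 2):]
    denom = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def effective_sample_size(chain: np.ndarray, max_lag: int | None = None) -> float:
    """ESS from the initial positive sequence of autocorrelations."""
    chain = np.asarray(chain, float)
    n = len(chain)
    if n < 4 or chain.var() == 0:
        return float(n)
    if max_lag is None:
        max_lag = min(n // 2, 200)
    c = chain - chain.mean()
    acf = np.correlate(c, c, mode="full")[n - 1:] / (c @ c)
    s = 0.0
    for k in range(1, max_lag):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class BayesianAlphabetRegressor:
    """Gibbs-sampled marker regression with a configurable prior family.

    Parameters
    ----------
    model : "bayes_a" | "bayes_b" | "bl"
    niter, burnin, thin, seed : chain settings (defaults: the short
        5000/1000/5 profile; the long profile is 500000/10000/5).
    r2 : assumed model R2 used to scale the variance priors.
    df : prior degrees of freedom for variance components.
    pi_zero : BayesB prior probability of a null (exactly zero) effect
        (the starting value when ``estimate_pi``).
    estimate_pi : update pi_zero from the inclusion indicators each
        iteration (Beta-Binomial, uniform prior on the inclusion fraction);
        keeps BayesB competitive across sparse and dense architectures.

    Fitted attributes
    -----------------
    coef_ : posterior-mean marker effects.
    intercept_ : posterior-mean intercept.
    inclusion_prob_ : per-marker posterior inclusion (BayesB; ones otherwise).
    sigma_e2_chain_, genetic_var_chain_ : thinned post-burn-in chains.
    diagnostics_ : dict with Geweke z and ESS of the residual-variance chain.
    gebv_ : training GEBVs (X @ coef_).
    """

    def __init__(self, model: str = "bayes_a", niter: int = 5000,
                 burnin: int = 1000, thin: int = 5, seed: int = 0,
                 r2: float = 0.5, df: float = 5.0, pi_zero: float = 0.5,
                 estimate_pi: bool = True):
        self.model = model
        self.niter = niter
        self.burnin = burnin
        self.thin = thin
        self.seed = seed
        self.r2 = r2
        self.df = df
        self.pi_zero = pi_zero
        self.estimate_pi = estimate_pi

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("model", "niter", "burnin", "thin", "seed", "r2", "df",
                 "pi_zero", "estimate_pi")}

    def set_params(self, **params) -> "BayesianAlphabetRegressor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _as_array(X) -> np.ndarray:
        # Fortran order: the samplers sweep over marker columns
        if isinstance(X, MarkerMatrix):
            return np.asfortranarray(X.X, dtype=np.float64)
        return np.asfortranarray(np.asarray(X, dtype=np.float64))

    def fit(self, X, y) -> "BayesianAlphabetRegressor":
        MCMCConfig(self.niter, self.burnin, self.thin, self.seed)  # validate
        Xa = self._as_array(X)
        y = np.asarray(y, dtype=np.float64)
        if Xa.shape[0] != len(y):
            raise ValueError("rows of X must align with y")
        if not np.isfinite(y).all():
            raise ValueError("y contains non-finite values")
        import warnings
        if abs(y.mean()) > 0.2 or not 0.5 < y.std() < 2.0:
            warnings.warn("phenotypes do not look standardized", stacklevel=2)
        n, p = Xa.shape
        vy = max(float(np.var(y)), 1e-8)   # guard null phenotypes
        sum_var_x = float(Xa.var(axis=0).sum())
        if sum_var_x == 0:
            raise ValueError("constant marker matrix")
        df, r2 = float(self.df), float(self.r2)
        scale_e = vy * (1 - r2) * (df + 2) / df
        seed = int(self.seed) % (2 ** 31 - 1)
        if self.model == "bayes_a":
            scale_b = vy * r2 * (df + 2) / (df * sum_var_x)
            out = bayes_a_sampler(Xa, y, self.niter, self.burnin, self.thin,
                                  df, scale_b, df, scale_e, seed)
        elif self.model == "bayes_b":
            if not 0 < self.pi_zero < 1:
                raise ValueError("pi_zero must lie in (0, 1)")
            scale_b = vy * r2 * (df + 2) / (
                df * sum_var_x * (1 - self.pi_zero)
            )
            out = bayes_b_sampler(Xa, y, self.niter, self.burnin, self.thin,
                                  df, scale_b, df, scale_e, self.pi_zero,
                                  self.estimate_pi, seed)
        elif self.model == "bl":
            lam_init2 = 2 * (1 - r2) / max(r2, 1e-8) * sum_var_x
            shape = 1.1
            rate = (shape - 1) / lam_init2 if lam_init2 > 0 else 1.0
            out = bayes_l_sampler(Xa, y, self.niter, self.burnin, self.thin,
                                  df, scale_e, shape, rate, seed)
        else:
            raise ValueError(f"unknown model {self.model!r}")
        b_mean, mu_mean, se2_chain, vg_chain, extra, bad_iter = out
        if bad_iter:
            raise FloatingPointError(
                f"divergent chain (non-finite draw) at iteration {bad_iter}"
            )
        self.n_markers_ = p
        self.coef_ = b_mean
        self.intercept_ = float(mu_mean)
        self.sigma_e2_chain_ = se2_chain
        self.genetic_var_chain_ = vg_chain
        self.sigma_e2_ = float(se2_chain.mean())
        self.genetic_var_ = float(vg_chain.mean())
        if self.model == "bayes_b":
            self.inclusion_prob_ = extra
        elif self.model == "bl":
            self.inclusion_prob_ = np.ones(p)
            self.lambda_chain_ = extra
        else:
            self.inclusion_prob_ = np.ones(p)
        self.diagnostics_ = {
            "geweke_z_sigma_e2": geweke_z(se2_chain),
            "ess_sigma_e2": effective_sample_size(se2_chain),
        }
        return self

    def predict(self, X, include_intercept: bool = True) -> np.ndarray:
        """GEBVs for new lines: X_new @ posterior-mean effects.

        X_new must be standardized with the training constants."""
        Xa = self._as_array(X)
        if Xa.shape[1] != self.n_markers_:
            raise ValueError("marker-set mismatch with the training matrix")
        g = Xa @ self.coef_
        return g + self.intercept_ if include_intercept else g

    def chains_frame(self) -> pd.DataFrame:
        """Thinned post-burn-in variance chains for external diagnostics."""
        d = {"sigma_e2": self.sigma_e2_chain_,
             "genetic_var": self.genetic_var_chain_}
        if hasattr(self, "lambda_chain_"):
            d["lambda"] = self.lambda_chain_
        return pd.DataFrame(d)


def fit_wgr(X, y, model: str = "bayes_a",
            mcmc: MCMCConfig | None = None, **prior) -> BayesianAlphabetRegressor:
    """Functional wrapper over :class:`BayesianAlphabetRegressor`."""
    mcmc = mcmc or TEST_MCMC
    est = BayesianAlphabetRegressor(
        model=model, niter=mcmc.niter, burnin=mcmc.burnin, thin=mcmc.thin,
        seed=mcmc.seed, **prior,
    )
    return est.fit(X, y)


def predict_gebv(fit: BayesianAlphabetRegressor, X_new,
                 include_intercept: bool = False) -> np.ndarray:
    return fit.predict(X_new, include_intercept=include_intercept)
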