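"""Marker QC and relationship kernels for genomic prediction.

Two kernels are supported: the linear genomic relationship matrix
GB = X X' / p on the column-standardized marker matrix X (n x p), and the
non-linear Gaussian kernel GK(i, i') = exp(-h * d2_ii') on squared Euclidean
marker distances, with the bandwidth h chosen by maximizing the marginal
likelihood (empirical Bayes) of a one-random-effect model over a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "DistanceMatrix",
    "Kernel",
    "MarkerQC",
    "qc_and_standardize",
    "grm",
    "squared_euclidean",
    "gaussian_kernel",
    "estimate_bandwidth",
    "DEFAULT_BANDWIDTH_GRID",
]

DEFAULT_BANDWIDTH_GRID = (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 5.0)


@dataclass
class MarkerMatrix:
    """Post-QC marker data: standardized values plus provenance."""

    X: np.ndarray                    # (n, p) standardized
    line_ids: list
    marker_ids: list
    means: np.ndarray                # training column means (raw dosage scale)
    sds: np.ndarray
    raw: np.ndarray | None = None    # imputed dosages, same shape as X

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class DistanceMatrix:
    D: np.ndarray                    # (n, n) squared Euclidean distances
    line_ids: list
    scale: float = 1.0               # divisor applied (off-diagonal mean)


@dataclass
class Kernel:
    K: np.ndarray
    kind: str                        # "GB" | "GK" | "MRD-derived" etc.
    line_ids: list = field(default_factory=list)
    h: float | None = None
    jitter: float = 0.0

    @property
    def n(self) -> int:
        return self.K.shape[0]


def ensure_psd(K: np.ndarray, tol: float = 1e-8, max_jitter: float = 1e-4):
    """Check min eigenvalue; repair by adding diagonal jitter escalating
    10x from 1e-8 up to ``max_jitter``, else fail."""
    w = np.linalg.eigvalsh(K)
    if w.min() >= -tol:
        return K, 0.0
    jitter = 1e-8
    while jitter <= max_jitter:
        if np.linalg.eigvalsh(K + jitter * np.eye(K.shape[0])).min() >= -tol:
            return K + jitter * np.eye(K.shape[0]), jitter
        jitter *= 10
    raise np.linalg.LinAlgError("kernel not PSD even after jitter repair")


# ---------------------------------------------------------------------------
# QC + standardization
# ---------------------------------------------------------------------------

class MarkerQC:
    """QC and standardization transformer for dosage genotype tables.

    Drops markers with missingness above ``max_missing`` (default 10%) and
    monomorphic markers, imputes remaining missing cells by the per-marker
    mode, and standardizes each column to mean 0 / SD 1 using training
    constants (sample SD).  ``transform`` applies the training marker set
    and constants to new lines.
    """

    def __init__(self, max_missing: float = 0.10, impute: str = "mode"):
        self.max_missing = max_missing
        self.impute = impute

    def get_params(self, deep: bool = True) -> dict:
        return {"max_missing": self.max_missing, "impute": self.impute}

    def set_params(self, **params) -> "MarkerQC":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    @staticmethod
    def _as_frame(raw) -> pd.DataFrame:
        if isinstance(raw, pd.DataFrame):
            return raw
        return pd.DataFrame(np.asarray(raw, dtype=float))

    def fit(self, raw) -> "MarkerQC":
        df = self._as_frame(raw)
        vals = df.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        miss = np.isnan(vals).mean(axis=0)
        keep = miss <= self.max_missing
        # per-marker mode among observed dosage classes (ties -> smaller)
        modes = np.full(vals.shape[1], np.nan)
        for j in np.flatnonzero(keep):
            col = vals[:, j]
            obs = col[~np.isnan(col)]
            if obs.size == 0:
                keep[j] = False
                continue
            classes, counts = np.unique(obs, return_counts=True)
            modes[j] = classes[np.argmax(counts)]
        filled = vals.copy()
        ridx, cidx = np.where(np.isnan(filled))
        filled[ridx, cidx] = modes[cidx]
        poly = np.nanstd(filled, axis=0) > 0
        keep &= poly
        if not keep.any():
            raise ValueError("all markers removed by QC")
        self.keep_ = keep
        self.modes_ = modes[keep]
        sub = filled[:, keep]
        self.means_ = sub.mean(axis=0)
        self.sds_ = sub.std(axis=0, ddof=1)
        self.marker_ids_ = [m for m, k in zip(df.columns, keep) if k]
        return self

    def transform(self, raw) -> MarkerMatrix:
        df = self._as_frame(raw)
        vals = df.to_numpy(dtype=float)[:, self.keep_]
        ridx, cidx = np.where(np.isnan(vals))
        vals[ridx, cidx] = self.modes_[cidx]
        X = (vals - self.means_) / self.sds_
        return MarkerMatrix(X, list(df.index), list(self.marker_ids_),
                            self.means_, self.sds_, raw=vals)

    def fit_transform(self, raw) -> MarkerMatrix:
        return self.fit(raw).transform(raw)


def qc_and_standardize(raw, max_missing: float = 0.10,
                       impute: str = "mode") -> MarkerMatrix:
    """Functional wrapper over :class:`MarkerQC`."""
    return MarkerQC(max_missing=max_missing, impute=impute).fit_transform(raw)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def grm(X: MarkerMatrix | np.ndarray) -> Kernel:
    """Genomic relationship matrix K = X X' / p on standardized markers."""
    if isinstance(X, MarkerMatrix):
        mat, ids = X.X, X.line_ids
    else:
        mat, ids = np.asarray(X, float), list(range(len(X)))
    p = mat.shape[1]
    if p == 0:
        raise ValueError("no markers")
    K = mat @ mat.T / p
    K = (K + K.T) / 2
    K, jit = ensure_psd(K)
    return Kernel(K, "GB", list(ids), jitter=jit)


def squared_euclidean(X: MarkerMatrix | np.ndarray,
                      scale_by_mean: bool = True) -> DistanceMatrix:
    """Squared Euclidean distances between standardized marker rows,
    optionally divided by the off-diagonal mean (so a unitless bandwidth
    grid applies across datasets)."""
    if isinstance(X, MarkerMatrix):
        mat, ids = X.X, X.line_ids
    else:
        mat, ids = np.asarray(X, float), list(range(len(X)))
    sq = (mat ** 2).sum(axis=1)
    D = sq[:, None] + sq[None, :] - 2 * mat @ mat.T
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2, 0.0)
    scale = 1.0
    n = D.shape[0]
    if scale_by_mean and n > 1:
        off = D.sum() / (n * (n - 1))
        if off > 0:
            D = D / off
            scale = float(off)
    return DistanceMatrix(D, list(ids), scale)


def gaussian_kernel(D: DistanceMatrix | np.ndarray, h: float) -> Kernel:
    """Gaussian kernel K = exp(-h * D): unit diagonal, entries in (0, 1]."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    mat = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    ids = D.line_ids if isinstance(D, DistanceMatrix) else list(range(len(mat)))
    K = np.exp(-h * mat)
    K, jit = ensure_psd(K)
    return Kernel(K, "GK", list(ids), h=float(h), jitter=jit)


# ---------------------------------------------------------------------------
# Empirical-Bayes bandwidth
# ---------------------------------------------------------------------------

def _profile_evidence(K: np.ndarray, y: np.ndarray,
                      h2_grid: np.ndarray) -> float:
    """Max over the inner variance-ratio grid of the Gaussian marginal
    log-likelihood of y = mu + u + e with u ~ N(0, su2 K).

    With relative covariance C = phi*K + (1-phi)*I the total variance is
    profiled analytically: sigma2_hat = mean(ytilde_i^2 / w_i) in the
    eigenbasis of K."""
    n = len(y)
    yc = y - y.mean()
    s, V = np.linalg.eigh((K + K.T) / 2)
    s = np.maximum(s, 0.0)
    yt = V.T @ yc
    best = -np.inf
    for phi in h2_grid:
        w = phi * s + (1 - phi)
        sigma2 = float(np.mean(yt ** 2 / w))
        ll = -0.5 * (np.log(w).sum() + n * np.log(sigma2) + n)
        best = max(best, ll)
    return best


def estimate_bandwidth(
    D: DistanceMatrix,
    y: np.ndarray,
    grid=DEFAULT_BANDWIDTH_GRID,
    inner_h2_grid=None,
) -> tuple:
    """Empirical-Bayes bandwidth: evaluate the profiled marginal likelihood
    of a single-kernel model at each candidate h and return the maximizer
    (ties broken toward smaller h) plus the evidence profile.

    Returns ``(h, profile)`` where ``profile`` is a pd.Series of log
    evidence indexed by h.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty bandwidth grid")
    y = np.asarray(y, float)
    if np.std(y) == 0:
        raise ValueError("degenerate phenotype (zero variance)")
    if inner_h2_grid is None:
        inner_h2_grid = np.linspace(0.05, 0.95, 19)
    evid = {}
    for h in sorted(grid):
        K = np.exp(-h * D.D)
        evid[h] = _profile_evidence(K, y, np.asarray(inner_h2_grid))
    profile = pd.Series(evid)
    best_h = float(profile.idxmax())  # idxmax returns first (smallest h) on ties
    return best_h, profile
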