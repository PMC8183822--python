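"""Training-population (TP) selection for genomic prediction.

Three model-based criteria evaluated from a relationship kernel K and the
variance ratio lambda_mix = se2/sg2 — the mean coefficient of determination
of candidate contrasts (CD_mean), the mean prediction error variance (PEV)
and an expected-accuracy score (rScore) — plus a purely marker-based
diversity objective, entry-to-nearest-entry on modified Rogers distances
(each selected line's distance to its closest selected neighbor, averaged).

CD_mean, PEV and rScore are optimized by a seeded single-swap exchange
algorithm (first-improvement steepest ascent); entry-to-nearest-entry uses
greedy max-min seeding followed by swap refinement.  Untargeted use (the
default) scores the non-selected lines as the prediction targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import Kernel, DistanceMatrix

__all__ = [
    "CriterionContext",
    "TPSelection",
    "modified_rogers_distance",
    "cd_values",
    "cdmean_criterion",
    "pev_criterion",
    "rscore_criterion",
    "exchange_optimize",
    "entry_to_nearest_entry_select",
]


@dataclass
class CriterionContext:
    """Kernel + variance ratio shared by the model-based criteria."""

    K: np.ndarray
    lambda_mix: float
    line_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.K = self.K.K if isinstance(self.K, Kernel) else np.asarray(self.K, float)
        if self.lambda_mix <= 0:
            raise ValueError("lambda_mix must be positive")
        if not self.line_ids:
            self.line_ids = list(range(self.K.shape[0]))

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass
class TPSelection:
    criterion: str
    selected: list                  # line indices
    value: float
    trajectory: list                # optimized objective over accepted moves
    seed: int
    line_ids: list = field(default_factory=list)

    @property
    def selected_ids(self) -> list:
        return [self.line_ids[i] for i in self.selected] if self.line_ids \
            else list(self.selected)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def modified_rogers_distance(dosages: np.ndarray) -> DistanceMatrix:
    """Modified Rogers distance between lines from biallelic dosages.

    MRD_ij = sqrt( sum_k (f_ik - f_jk)^2 / (2p) ) with f = dosage/2, i.e.
    the within-line allele frequency (0 or 1 for DH lines).  Bounded by
    1/sqrt(2) for fully homozygous panels.
    """
    import warnings
    F = np.asarray(dosages, float) / 2.0
    if np.isin(np.asarray(dosages), (0, 2)).mean() < 0.5:
        warnings.warn("heterozygous-heavy data: MRD uses f = dosage/2",
                      stacklevel=2)
    p = F.shape[1]
    sq = (F ** 2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2 * F @ F.T
    D2 = np.maximum(D2, 0.0)
    D = np.sqrt(D2 / (2 * p))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, list(range(F.shape[0])), scale=1.0)


# ---------------------------------------------------------------------------
# model-based criteria
# ---------------------------------------------------------------------------

def _prepare(ctx: CriterionContext, training: np.ndarray):
    n = ctx.n
    training = np.asarray(sorted(training), int)
    if len(training) == 0:
        raise ValueError("training set is empty")
    if training.min() < 0 or training.max() >= n:
        raise ValueError("training indices outside the candidate set")
    lam = ctx.lambda_mix
    jitter = 1e-8 * np.trace(ctx.K) / n
    Kinv = np.linalg.inv(ctx.K + jitter * np.eye(n))
    ind = np.zeros(n)
    ind[training] = 1.0
    n_t = len(training)
    # Z'MZ for one observation per training line, M projecting out the mean
    ZtMZ = np.diag(ind) - np.outer(ind, ind) / n_t
    A = ZtMZ + lam * Kinv
    Ainv = np.linalg.inv(A)
    return training, lam, Ainv


def _contrasts(n: int, targets: np.ndarray) -> np.ndarray:
    """Columns c_i = e_i - 1/n (line vs population mean) for each target."""
    C = np.full((n, len(targets)), -1.0 / n)
    C[targets, np.arange(len(targets))] += 1.0
    return C


def _default_targets(ctx: CriterionContext, training: np.ndarray) -> np.ndarray:
    mask = np.ones(ctx.n, bool)
    mask[training] = False
    targets = np.flatnonzero(mask)
    return targets if len(targets) else np.arange(ctx.n)


def cd_values(ctx: CriterionContext, training_set, targets=None) -> np.ndarray:
    """Coefficient of determination of each target contrast."""
    training, lam, Ainv = _prepare(ctx, np.asarray(list(training_set), int))
    if targets is None:
        targets = _default_targets(ctx, training)
    targets = np.asarray(list(targets), int)
    C = _contrasts(ctx.n, targets)
    num = np.einsum("ij,ij->j", C, (ctx.K - lam * Ainv) @ C)
    den = np.einsum("ij,ij->j", C, ctx.K @ C)
    return np.clip(num / den, 0.0, 1.0)


def cdmean_criterion(ctx: CriterionContext, training_set, targets=None) -> float:
    """Mean CD over the target (default: non-training) contrasts; in [0,1],
    to be maximized."""
    return float(cd_values(ctx, training_set, targets).mean())


def pev_criterion(ctx: CriterionContext, training_set, targets=None) -> float:
    """Mean prediction error variance of target contrasts (sg2 = 1 units),
    to be minimized."""
    training, lam, Ainv = _prepare(ctx, np.asarray(list(training_set), int))
    if targets is None:
        targets = _default_targets(ctx, training)
    targets = np.asarray(list(targets), int)
    if len(targets) == 0:
        raise ValueError("empty target set")
    C = _contrasts(ctx.n, targets)
    pev = np.einsum("ij,ij->j", C, Ainv @ C) * lam
    return float(pev.mean())


def rscore_criterion(ctx: CriterionContext, training_set, targets=None) -> float:
    """Mean expected predictive correlation of the targets from kernel
    blocks: acc_j = sqrt( k_jT (K_TT + lam I)^-1 k_Tj / k_jj ); in [0,1]."""
    training = np.asarray(sorted(training_set), int)
    if len(training) == 0:
        raise ValueError("training set is empty")
    if targets is None:
        targets = _default_targets(ctx, training)
    targets = np.asarray(list(targets), int)
    if len(targets) == 0:
        raise ValueError("empty target set")
    K = ctx.K
    Ktt = K[np.ix_(training, training)] + ctx.lambda_mix * np.eye(len(training))
    Kjt = K[np.ix_(targets, training)]
    sol = np.linalg.solve(Ktt, Kjt.T)            # (n_t, n_targets)
    quad = np.einsum("ij,ji->i", Kjt, sol)
    kjj = np.maximum(np.diag(K)[targets], 1e-12)
    acc = np.sqrt(np.clip(quad / kjj, 0.0, 1.0))
    return float(acc.mean())


_CRITERIA = {
    "cdmean": (cdmean_criterion, +1),
    "pev": (pev_criterion, -1),       # minimized
    "rscore": (rscore_criterion, +1),
}


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

def exchange_optimize(
    criterion: str,
    ctx: CriterionContext,
    n_select: int,
    max_iters: int = 50,
    rng_seed: int = 0,
) -> TPSelection:
    """Seeded random start + single-swap first-improvement ascent.

    The reported objective is the maximized quantity (PEV enters with sign
    flipped), so the trajectory is monotone non-decreasing.  Ties broken by
    lowest line index through the deterministic scan order.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    fn, sign = _CRITERIA[criterion]
    n = ctx.n
    if not 0 < n_select < n:
        raise ValueError("n_select must satisfy 0 < n_select < n")
    rng = np.random.default_rng(rng_seed)
    selected = set(rng.choice(n, n_select, replace=False).tolist())
    value = sign * fn(ctx, selected)
    trajectory = [value]
    for _ in range(max_iters):
        improved = False
        for i in sorted(selected):
            for j in sorted(set(range(n)) - selected):
                cand = (selected - {i}) | {j}
                v = sign * fn(ctx, cand)
                if v > value + 1e-12:
                    selected, value = cand, v
                    trajectory.append(value)
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    return TPSelection(criterion, sorted(selected), sign * value, trajectory,
                       rng_seed, list(ctx.line_ids))


def _nearest_entry_objective(D: np.ndarray, selected: np.ndarray) -> float:
    sub = D[np.ix_(selected, selected)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def entry_to_nearest_entry_select(
    D: DistanceMatrix | np.ndarray,
    n_select: int,
    always_include=(),
    rng_seed: int = 0,
    max_iters: int = 100,
) -> TPSelection:
    """Maximize the mean distance of each selected entry to its closest
    other selected entry (greedy max-min seeding + swap refinement).

    ``always_include`` forces entries into the selection (e.g. founder
    parents added to a diverse core set).
    """
    Dm = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    n = Dm.shape[0]
    if n_select < 2:
        raise ValueError("n_select must be >= 2")
    if n_select > n:
        raise ValueError("n_select exceeds the candidate count")
    rng = np.random.default_rng(rng_seed)
    selected = list(dict.fromkeys(int(i) for i in always_include))
    if len(selected) > n_select:
        raise ValueError("always_include larger than n_select")
    if not selected:
        i, j = np.unravel_index(np.argmax(Dm), Dm.shape)
        selected = [int(i), int(j)] if n_select >= 2 else [int(i)]
    # greedy max-min completion
    while len(selected) < n_select:
        rest = np.array(sorted(set(range(n)) - set(selected)))
        mind = Dm[np.ix_(rest, selected)].min(axis=1)
        selected.append(int(rest[np.argmax(mind)]))
    sel = np.array(sorted(selected))
    value = _nearest_entry_objective(Dm, sel)
    trajectory = [value]
    forced = set(int(i) for i in always_include)
    for _ in range(max_iters):
        improved = False
        for i in sel:
            if i in forced:
                continue
            for j in sorted(set(range(n)) - set(sel.tolist())):
                cand = np.array(sorted(set(sel.tolist()) - {int(i)} | {j}))
                v = _nearest_entry_objective(Dm, cand)
                if v > value + 1e-12:
                    sel, value = cand, v
                    trajectory.append(value)
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break
    ids = D.line_ids if isinstance(D, DistanceMatrix) else list(range(n))
    return TPSelection("entry_to_nearest_entry", sel.tolist(), value,
                       trajectory, rng_seed, list(ids))
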