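"""Synthetic MAGIC populations and multi-environment trial phenotypes.

An eight-way MAGIC (Multi-parent Advanced Generation Inter-Cross) population
is built by a two-stage funnel design: four two-way crosses pairing one "old"
with one "modern" founder, half-diallel crosses of the four F1s into six
four-way sets, and eight-way funnel crosses uniting two disjoint four-way
sets.  Instead of repeated selfing, each eight-way individual is finished by
doubled-haploid (DH) technology: one gamete is sampled and its genome
doubled, giving a fully homozygous line whose genome is a mosaic of the
eight founder genomes (expected share 1/8 each).

Meiosis follows the Haldane model: crossover counts per chromosome are
Poisson with mean equal to the genetic length in Morgans, crossover
positions are uniform on the cM axis, and there is no interference.

Phenotypes are generated for several environments from a QTL architecture
with a main (environment-common) effect and an environment-specific
deviation per QTL, then observed in two-replicate alpha-lattice field trials
with incomplete blocks, a days-to-heading (DH-days) covariate and Gaussian
plot noise calibrated to a target line-mean heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "FounderPanel",
    "FunnelDesign",
    "MagicPopulation",
    "TraitArchitecture",
    "TrialLayout",
    "default_map",
    "simulate_founders",
    "build_funnel_design",
    "simulate_gamete",
    "simulate_population",
    "sample_trait_architecture",
    "simulate_genetic_values",
    "simulate_trial",
    "simulate_magic_dataset",
]

N_FOUNDERS = 8


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Marker map with genetic (cM) and physical (bp) coordinates.

    ``table`` has columns ``marker``, ``chrom``, ``cM``, ``bp`` sorted by
    chromosome then position; positions are non-decreasing within a
    chromosome on both scales.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "cM", "bp"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"map table missing columns {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("empty genetic map")
        if (self.table["cM"] < 0).any():
            raise ValueError("negative cM position in map")
        for _, sub in self.table.groupby("chrom", sort=False):
            if not (sub["cM"].diff().dropna() >= 0).all():
                raise ValueError("cM positions not non-decreasing within chromosome")
            if not (sub["bp"].diff().dropna() >= 0).all():
                raise ValueError("bp positions not non-decreasing within chromosome")

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.table["chrom"]))

    def chrom_slices(self) -> dict:
        """Contiguous row slice per chromosome (map rows are sorted)."""
        out = {}
        codes = self.table["chrom"].to_numpy()
        start = 0
        for c in self.chromosomes:
            n = int((codes == c).sum())
            out[c] = slice(start, start + n)
            start += n
        return out


@dataclass
class FounderPanel:
    """Eight founder inbreds, four 'old' and four 'modern'.

    ``haplotypes`` is an 8 x p binary matrix (one haplotype per founder —
    founders are fully inbred).  ``monomorphic`` flags markers with no
    variation across the panel.
    """

    founder_ids: list
    groups: list                     # "old" | "modern", aligned to founder_ids
    haplotypes: np.ndarray           # (8, p) in {0, 1}
    monomorphic: np.ndarray          # (p,) bool
    trait_means: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.founder_ids) != N_FOUNDERS:
            raise ValueError("founder panel must contain exactly 8 founders")
        if self.groups.count("old") != 4 or self.groups.count("modern") != 4:
            raise ValueError("founder panel must contain 4 old and 4 modern founders")
        self.haplotypes = np.asarray(self.haplotypes)
        if self.haplotypes.shape[0] != N_FOUNDERS:
            raise ValueError("haplotype matrix must have 8 rows")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("founder alleles must be binary")

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class FunnelDesign:
    """Crossing plan of the two-stage funnel scheme.

    stage1: four (old, modern) founder-index pairs.
    stage2: the six unordered pairs of stage-1 F1s (four-way sets).
    stage3: pairings of two disjoint four-way sets covering all 8 founders.
    lines_per_funnel: DH lines derived from each stage-3 funnel.
    """

    stage1: list
    stage2: list
    stage3: list
    lines_per_funnel: list

    def __post_init__(self) -> None:
        if len(self.stage1) != 4:
            raise ValueError("stage 1 must contain four two-way crosses")
        if len(self.stage2) != 6:
            raise ValueError("stage 2 must enumerate all six F1 pairs")
        if len(self.stage3) != len(self.lines_per_funnel):
            raise ValueError("one line count per stage-3 funnel required")
        for a, b in self.stage3:
            fa = set(self.stage2[a])
            fb = set(self.stage2[b])
            if fa & fb:
                raise ValueError("stage-3 pairing must unite disjoint four-way sets")

    @property
    def n_lines(self) -> int:
        return int(sum(self.lines_per_funnel))


@dataclass
class MagicPopulation:
    """DH MAGIC lines: dosages in {0, 2} plus founder-origin mosaic."""

    line_ids: list
    dosages: np.ndarray              # (n, p) in {0, 2}
    founder_origin: np.ndarray       # (n, p) founder indices 0..7
    design: FunnelDesign
    seed: int

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def founder_shares(self) -> np.ndarray:
        """Per-founder mean genome share across lines and markers."""
        counts = np.bincount(self.founder_origin.ravel(), minlength=N_FOUNDERS)
        return counts / self.founder_origin.size


@dataclass
class TraitArchitecture:
    """QTL effects: environment-common main effect plus per-environment deviation.

    The genetic value of line i in environment j is
    ``sum_k dosage_ik * (b0_k + b_jk)`` — each QTL effect is the sum of an
    effect common to all environments and an environment-specific deviation.
    """

    qtl_indices: np.ndarray
    main_effects: np.ndarray          # (n_qtl,)
    env_deviations: np.ndarray        # (n_qtl, n_env)
    environments: list
    target_h2: dict                   # env -> H2 in (0, 1]
    dh_covariate_effect: float = 0.0

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        self.main_effects = np.asarray(self.main_effects, dtype=float)
        self.env_deviations = np.asarray(self.env_deviations, dtype=float)
        if self.env_deviations.shape != (len(self.qtl_indices), len(self.environments)):
            raise ValueError("env_deviations must be (n_qtl, n_env)")
        for env, h2 in self.target_h2.items():
            if not (0 < h2 <= 1):
                raise ValueError(f"target H2 for {env} outside (0, 1]")


@dataclass
class TrialLayout:
    """Alpha-lattice layout: replicates x incomplete blocks within replicate."""

    environment: str
    n_reps: int = 2
    block_size: int = 16

    def assign(self, genotypes: list, rng: np.random.Generator) -> pd.DataFrame:
        """Plot assignment: each genotype once per replicate, blocks filled by
        seeded random permutation within replicate."""
        rows = []
        n = len(genotypes)
        n_blocks = int(np.ceil(n / self.block_size))
        for rep in range(1, self.n_reps + 1):
            order = rng.permutation(n)
            for pos, gi in enumerate(order):
                rows.append(
                    (self.environment, rep, pos // self.block_size + 1, genotypes[gi])
                )
        df = pd.DataFrame(rows, columns=["env", "rep", "block", "genotype"])
        if df["block"].max() != n_blocks:
            raise AssertionError("block bookkeeping error")
        return df


# ---------------------------------------------------------------------------
# Map and founders
# ---------------------------------------------------------------------------

def default_map(
    n_chrom: int = 7,
    markers_per_chrom: int = 300,
    chrom_length_cM: float = 150.0,
    chrom_length_bp: int = 550_000_000,
    rng_seed: int = 0,
) -> GeneticMap:
    """Equally-informative random map emulating a barley-like genome:
    7 chromosomes of ~150 cM / ~550 Mb with markers at uniform random
    positions (bp proportional to cM, i.e. a flat recombination landscape).
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for c in range(1, n_chrom + 1):
        cm = np.sort(rng.uniform(0, chrom_length_cM, markers_per_chrom))
        bp = (cm / chrom_length_cM * chrom_length_bp).astype(np.int64)
        for i, (g, b) in enumerate(zip(cm, bp)):
            rows.append((f"chr{c}_m{i}", f"chr{c}", float(g), int(b)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp"]))


DEFAULT_FOUNDERS = [
    ("old_1", "old"), ("old_2", "old"), ("old_3", "old"), ("old_4", "old"),
    ("modern_1", "modern"), ("modern_2", "modern"),
    ("modern_3", "modern"), ("modern_4", "modern"),
]


def simulate_founders(
    genetic_map: GeneticMap,
    maf_range: tuple = (0.1, 0.5),
    rng_seed: int = 0,
) -> FounderPanel:
    """Eight binary founder haplotypes with panel-wide MAF in ``maf_range``.

    For each marker a target frequency f is drawn uniformly on the range and
    the alternate allele is placed on round(8f) founders chosen at random, so
    realized panel frequencies track the range up to rounding.  Markers that
    end up monomorphic (possible when 8f rounds to 0 or 8) are flagged.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    p = genetic_map.n_markers
    if p == 0:
        raise ValueError("empty genetic map")
    rng = np.random.default_rng(rng_seed)
    freqs = rng.uniform(lo, hi, p)
    counts = np.rint(freqs * N_FOUNDERS).astype(int)
    hap = np.zeros((N_FOUNDERS, p), dtype=np.int8)
    for j in range(p):
        carriers = rng.choice(N_FOUNDERS, size=counts[j], replace=False)
        hap[carriers, j] = 1
    mono = (hap.sum(axis=0) == 0) | (hap.sum(axis=0) == N_FOUNDERS)
    ids = [f for f, _ in DEFAULT_FOUNDERS]
    groups = [g for _, g in DEFAULT_FOUNDERS]
    return FounderPanel(ids, groups, hap, mono)


# ---------------------------------------------------------------------------
# Crossing design
# ---------------------------------------------------------------------------

def build_funnel_design(
    panel: FounderPanel, n_lines: int, rng_seed: int = 0
) -> FunnelDesign:
    """Funnel plan: 4 old x modern crosses, the 6 half-diallel F1 pairs,
    and the 3 disjoint four-way pairings; ``n_lines`` DH lines distributed
    as evenly as possible (remainder to funnels in seeded random order)."""
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    old = [i for i, g in enumerate(panel.groups) if g == "old"]
    modern = [i for i, g in enumerate(panel.groups) if g == "modern"]
    if len(old) != 4 or len(modern) != 4:
        raise ValueError("founder panel must have a 4 old + 4 modern structure")
    rng = np.random.default_rng(rng_seed)
    modern_perm = rng.permutation(modern)
    stage1 = [(old[i], int(modern_perm[i])) for i in range(4)]
    stage2 = list(combinations(range(4), 2))  # pairs of stage-1 F1 indices
    stage3 = []
    for a in range(len(stage2)):
        for b in range(a + 1, len(stage2)):
            if not set(stage2[a]) & set(stage2[b]):
                stage3.append((a, b))
    base, extra = divmod(n_lines, len(stage3))
    counts = np.full(len(stage3), base, dtype=int)
    counts[rng.permutation(len(stage3))[:extra]] += 1
    return FunnelDesign(stage1, stage2, stage3, counts.tolist())


# ---------------------------------------------------------------------------
# Meiosis (Haldane)
# ---------------------------------------------------------------------------

def _gamete(
    hap: np.ndarray,
    origin: np.ndarray,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
) -> tuple:
    """One gamete from a (2, p) haplotype pair with aligned origin labels.

    Poisson crossover count per chromosome (mean = length in Morgans),
    uniform crossover placement on the cM axis, no interference."""
    p = genetic_map.n_markers
    gam = np.empty(p, dtype=hap.dtype)
    gorig = np.empty(p, dtype=origin.dtype)
    cm = genetic_map.table["cM"].to_numpy()
    for sl in genetic_map.chrom_slices().values():
        pos = cm[sl]
        length_m = (pos[-1] - pos[0]) / 100.0 if len(pos) > 1 else 0.0
        ncross = rng.poisson(length_m)
        cuts = np.sort(rng.uniform(pos[0], pos[-1], ncross)) if ncross else np.empty(0)
        current = int(rng.integers(2))
        # parent of origin switches at every crossover point
        strand = (current + np.searchsorted(cuts, pos, side="right")) % 2
        cols = np.arange(sl.start, sl.stop)
        gam[sl] = hap[strand, cols]
        gorig[sl] = origin[strand, cols]
    return gam, gorig


def simulate_gamete(
    parent_haplotypes: np.ndarray,
    parent_origin: np.ndarray,
    genetic_map: GeneticMap,
    rng_seed: int = 0,
) -> tuple:
    """Public single-gamete interface (see :func:`_gamete`)."""
    hap = np.asarray(parent_haplotypes)
    origin = np.asarray(parent_origin)
    if hap.shape != (2, genetic_map.n_markers):
        raise ValueError("haplotypes must be (2, p) aligned to the map")
    if origin.shape != hap.shape:
        raise ValueError("origin labels must align with haplotypes")
    rng = np.random.default_rng(rng_seed)
    return _gamete(hap, origin, genetic_map, rng)


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

def simulate_population(
    design: FunnelDesign,
    panel: FounderPanel,
    genetic_map: GeneticMap,
    rng_seed: int = 0,
) -> MagicPopulation:
    """Run the full funnel and DH-finish each eight-way individual.

    Every DH line descends from an independently simulated funnel (fresh
    meioses at every stage), maximizing line independence.
    """
    if panel.n_markers != genetic_map.n_markers:
        raise ValueError("founder panel and map marker counts differ")
    rng = np.random.default_rng(rng_seed)
    p = genetic_map.n_markers
    n = design.n_lines
    dosages = np.empty((n, p), dtype=np.int8)
    origin = np.empty((n, p), dtype=np.int8)
    hap = panel.haplotypes

    def founder_pair(i, j):
        h = np.stack([hap[i], hap[j]])
        o = np.stack([np.full(p, i, np.int8), np.full(p, j, np.int8)])
        return h, o

    row = 0
    line_ids = []
    for funnel_idx, (a, b) in enumerate(design.stage3):
        for _ in range(design.lines_per_funnel[funnel_idx]):
            # stage 1: founders are inbred, so each F1 is deterministic
            f1 = {}
            for s1 in set(design.stage2[a]) | set(design.stage2[b]):
                i, j = design.stage1[s1]
                f1[s1] = founder_pair(i, j)
            # stage 2: four-way crosses via one gamete from each F1
            def fourway(pair):
                g1, o1 = _gamete(*f1[pair[0]], genetic_map, rng)
                g2, o2 = _gamete(*f1[pair[1]], genetic_map, rng)
                return np.stack([g1, g2]), np.stack([o1, o2])
            fw_a = fourway(design.stage2[a])
            fw_b = fourway(design.stage2[b])
            # stage 3: eight-way cross, then one DH gamete doubled
            g1, o1 = _gamete(*fw_a, genetic_map, rng)
            g2, o2 = _gamete(*fw_b, genetic_map, rng)
            eight = (np.stack([g1, g2]), np.stack([o1, o2]))
            dh, dho = _gamete(*eight, genetic_map, rng)
            dosages[row] = 2 * dh
            origin[row] = dho
            line_ids.append(f"L{row + 1:04d}")
            row += 1
    return MagicPopulation(line_ids, dosages, origin, design, rng_seed)


# ---------------------------------------------------------------------------
# Trait architecture and genetic values
# ---------------------------------------------------------------------------

def sample_trait_architecture(
    genetic_map: GeneticMap,
    environments: list,
    n_qtl: int = 200,
    main_var: float = 1.0,
    dev_var: float = 0.25,
    target_h2: dict | None = None,
    dh_covariate_effect: float = 0.0,
    rng_seed: int = 0,
) -> TraitArchitecture:
    """Random polygenic architecture.

    ``dev_var / main_var`` controls GxE: with independent deviations the
    expected cross-environment genetic correlation is
    main_var / (main_var + dev_var)."""
    rng = np.random.default_rng(rng_seed)
    p = genetic_map.n_markers
    if n_qtl > p:
        raise ValueError("more QTLs than markers")
    qtl = np.sort(rng.choice(p, n_qtl, replace=False))
    main = rng.normal(0.0, np.sqrt(main_var / n_qtl), n_qtl)
    dev = rng.normal(0.0, np.sqrt(dev_var / n_qtl), (n_qtl, len(environments)))
    if target_h2 is None:
        target_h2 = {e: 0.5 for e in environments}
    return TraitArchitecture(qtl, main, dev, list(environments), target_h2,
                             dh_covariate_effect)


def simulate_genetic_values(
    pop: MagicPopulation,
    arch: TraitArchitecture,
    rng_seed: int = 0,
) -> tuple:
    """True genetic values per line x environment, plus the per-line
    DH-days covariate (narrow spread: the founders differ by < 4 days)."""
    if arch.qtl_indices.size and arch.qtl_indices.max() >= pop.n_markers:
        raise ValueError("QTL index out of marker range")
    rng = np.random.default_rng(rng_seed)
    Xq = pop.dosages[:, arch.qtl_indices].astype(float)
    effects = arch.main_effects[:, None] + arch.env_deviations  # (q, n_env)
    values = Xq @ effects
    gv = pd.DataFrame(values, index=pop.line_ids, columns=arch.environments)
    dh_days = pd.Series(rng.normal(210.0, 1.2, pop.n_lines), index=pop.line_ids,
                        name="DH")
    return gv, dh_days


# ---------------------------------------------------------------------------
# Field trial
# ---------------------------------------------------------------------------

def simulate_trial(
    values: pd.Series,
    dh_days: pd.Series,
    layout: TrialLayout,
    target_h2: float = 0.5,
    covariate_effect: float = 0.0,
    rep_sd: float | None = None,
    block_sd: float | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Plot table for one environment.

    yield = genetic value + rep effect + block(rep) effect
          + covariate_effect * DH-days + residual,
    with residual variance solved from the line-mean heritability identity
    H2 = sg2 / (sg2 + se2 / r)  =>  se2 = r * sg2 * (1 - H2) / H2.
    Replicate and block effects are Gaussian; defaults scale with the
    genetic SD (rep 0.25x, block 0.5x).
    """
    if not (0 < target_h2 < 1):
        raise ValueError("target_h2 must lie in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    genotypes = list(values.index)
    plots = layout.assign(genotypes, rng)
    sg2 = float(np.var(values.to_numpy(), ddof=1))
    se2 = layout.n_reps * sg2 * (1 - target_h2) / target_h2
    if rep_sd is None:
        rep_sd = 0.25 * np.sqrt(sg2)
    if block_sd is None:
        block_sd = 0.5 * np.sqrt(sg2)
    rep_eff = {r: rng.normal(0, rep_sd) for r in plots["rep"].unique()}
    blk_eff = {
        key: rng.normal(0, block_sd)
        for key in plots[["rep", "block"]].drop_duplicates().itertuples(index=False)
    }
    g = plots["genotype"].map(values)
    dh = plots["genotype"].map(dh_days)
    noise = rng.normal(0, np.sqrt(se2), len(plots))
    gy = (
        g.to_numpy()
        + plots["rep"].map(rep_eff).to_numpy()
        + np.array([blk_eff[(r, b)] for r, b in zip(plots["rep"], plots["block"])])
        + covariate_effect * dh.to_numpy()
        + noise
    )
    out = plots.copy()
    out["DH"] = dh.to_numpy()
    out["GY"] = gy
    return out


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

@dataclass
class MagicDataset:
    """Bundle of everything a downstream analysis needs."""

    genetic_map: GeneticMap
    panel: FounderPanel
    population: MagicPopulation
    architecture: TraitArchitecture
    genetic_values: pd.DataFrame     # lines x environments
    dh_days: pd.Series
    plot_tables: dict                # env -> PlotTable DataFrame

    @property
    def plots(self) -> pd.DataFrame:
        return pd.concat(self.plot_tables.values(), ignore_index=True)


def simulate_magic_dataset(
    n_lines: int = 352,
    markers_per_chrom: int = 300,
    environments: list | None = None,
    target_h2: dict | None = None,
    n_qtl: int = 200,
    main_var: float = 1.0,
    dev_var: float = 0.25,
    covariate_effect: float = 0.0,
    block_size: int = 16,
    rng_seed: int = 0,
) -> MagicDataset:
    """End-to-end synthetic study: map -> founders -> funnels -> DH lines ->
    genetic values -> alpha-lattice plot tables, all from one seed.

    Defaults emulate the study conditions downstream stages assume: 352 DH
    lines from 8 founders, a 7-chromosome slow-LD genome, multiple
    environments with heterogeneous heritability and two-replicate lattices.
    """
    if environments is None:
        environments = ["E1", "E2", "E3"]
    if target_h2 is None:
        target_h2 = {e: h for e, h in zip(environments, [0.66, 0.47, 0.12] * 10)}
    ss = np.random.SeedSequence(rng_seed)
    seeds = [int(s) for s in ss.generate_state(6 + len(environments))]
    gmap = default_map(markers_per_chrom=markers_per_chrom, rng_seed=seeds[0])
    n_qtl = min(n_qtl, gmap.n_markers)
    panel = simulate_founders(gmap, rng_seed=seeds[1])
    design = build_funnel_design(panel, n_lines, rng_seed=seeds[2])
    pop = simulate_population(design, panel, gmap, rng_seed=seeds[3])
    arch = sample_trait_architecture(
        gmap, environments, n_qtl=n_qtl, main_var=main_var, dev_var=dev_var,
        target_h2=target_h2, dh_covariate_effect=covariate_effect,
        rng_seed=seeds[4],
    )
    gv, dh_days = simulate_genetic_values(pop, arch, rng_seed=seeds[5])
    plot_tables = {}
    for k, env in enumerate(environments):
        layout = TrialLayout(environment=env, n_reps=2, block_size=block_size)
        plot_tables[env] = simulate_trial(
            gv[env], dh_days, layout, target_h2=target_h2[env],
            covariate_effect=covariate_effect, rng_seed=seeds[6 + k],
        )
    return MagicDataset(gmap, panel, pop, arch, gv, dh_days, plot_tables)
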