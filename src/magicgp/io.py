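"""File formats, configuration and the pipeline driver.

Plain-text formats throughout: tab-separated marker maps and dosage
matrices (optional minimal VCF, GT-only), CSV plot tables and result
tables, YAML run configuration, JSON reports.  Every output file starts
with a comment line carrying the config hash and master seed so any
artifact can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lattice, tp_optim, evaluate
from .kernels import qc_and_standardize, grm, squared_euclidean, \
    gaussian_kernel, estimate_bandwidth
from .gp import MEDataset, fit_se_kernel, MultiEnvGP
from .simulate import GeneticMap, simulate_magic_dataset
from .wgr import MCMCConfig, BayesianAlphabetRegressor, TEST_MCMC, PAPER_MCMC

__all__ = [
    "read_genetic_map", "write_genetic_map",
    "read_genotypes", "write_genotypes", "write_vcf",
    "read_plot_table", "write_plot_table",
    "load_config", "run_pipeline",
]

log = logging.getLogger("magicgp")

PLOT_COLUMNS = ["env", "rep", "block", "genotype", "DH", "GY"]


def _header_comment(config_hash: str, seed: int) -> str:
    return f"# magicgp config={config_hash} seed={seed}\n"


def _write_with_header(df: pd.DataFrame, path, config_hash: str, seed: int,
                       sep: str = ",", index: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash, seed))
        df.to_csv(fh, sep=sep, index=index)


# ---------------------------------------------------------------------------
# maps and genotypes
# ---------------------------------------------------------------------------

def write_genetic_map(gmap: GeneticMap, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        gmap.table.to_csv(fh, sep="\t", index=False)


def read_genetic_map(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t", comment="#"))


def write_genotypes(dosages: pd.DataFrame, path, header: str = "") -> None:
    """Line x marker dosage matrix, tab-separated, line ids in column 1."""
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        dosages.to_csv(fh, sep="\t", index=True, index_label="line")


def write_matrix(M, line_ids, path) -> None:
    """Symmetric matrix (kernel or distances) as TSV with line-id
    header row and column."""
    pd.DataFrame(np.asarray(M), index=line_ids, columns=line_ids).to_csv(
        path, sep="\t", index_label="line")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def _read_genotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df


def _read_genotypes_vcf(path) -> pd.DataFrame:
    """Minimal VCF reader: biallelic SNPs, GT field only.

    Homozygous calls map to dosages {0, 2}, heterozygous to 1, missing
    preserved as NaN; multi-allelic sites are skipped (count logged)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:          # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, rows = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
        dose = np.where(gt == 0, 0.0,
                        np.where(gt == 1, 1.0,
                                 np.where(gt == 3, 2.0, np.nan)))
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        rows.append(dose)
    if skipped:
        log.info("skipped %d multi-allelic sites", skipped)
    mat = np.array(rows).T if rows else np.empty((len(samples), 0))
    return pd.DataFrame(mat, index=samples, columns=marker_ids)


def read_genotypes(path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_vcf(dosages: pd.DataFrame, gmap: GeneticMap, path) -> None:
    """Minimal GT-only VCF for homozygous-coded dosage matrices."""
    table = gmap.table.set_index("marker")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in dosages.index) + "\n")
        for m in dosages.columns:
            row = table.loc[m]
            calls = []
            for d in dosages[m]:
                if pd.isna(d):
                    calls.append("./.")
                elif d == 0:
                    calls.append("0/0")
                elif d == 1:
                    calls.append("0/1")
                else:
                    calls.append("1/1")
            fh.write(f"{row['chrom']}\t{int(row['bp'])}\t{m}\tA\tC\t.\tPASS\t."
                     f"\tGT\t" + "\t".join(calls) + "\n")


# ---------------------------------------------------------------------------
# plot tables
# ---------------------------------------------------------------------------

def write_plot_table(plots: pd.DataFrame, path) -> None:
    plots[PLOT_COLUMNS].to_csv(path, index=False)


def read_plot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(PLOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plot table missing columns {sorted(missing)}")
    key = df[["env", "rep", "block", "genotype"]]
    if key.duplicated().any():
        raise ValueError("duplicated (env, rep, block, genotype) plot key")
    # missing GY stays NaN (flagged missing, not dropped)
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 1,
    "outdir": "magicgp_out",
    "stages": ["simulate", "adjust", "fit", "optimize-tp", "crossval",
               "popgen"],
    "simulate": {
        "n_lines": 352, "markers_per_chrom": 300,
        "environments": ["E1", "E2", "E3"],
        "target_h2": None, "n_qtl": 200, "main_var": 1.0, "dev_var": 0.25,
    },
    "mcmc": {"profile": "test"},
    "models": {"se": ["GB", "GK", "BayesA", "BayesB", "BL"],
               "me": ["MM", "MDs", "MDe"]},
    "kernels": ["GB", "GK"],
    "tp": {"n_select": 90, "criteria": ["cdmean", "pev", "rscore",
                                        "entry_to_nearest_entry"]},
    "cv": {"sizes": [80, 160], "n_reps": 10, "me_n_reps": 10},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _mcmc_from_config(cfg: dict) -> MCMCConfig:
    m = cfg.get("mcmc", {})
    profile = m.get("profile", "test")
    if profile == "paper-scale":
        base = PAPER_MCMC
    else:
        base = TEST_MCMC
    return MCMCConfig(m.get("niter", base.niter), m.get("burnin", base.burnin),
                      m.get("thin", base.thin), cfg.get("seed", 0))


def _config_hash(cfg: dict) -> str:
    content = {k: v for k, v in cfg.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(content, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict) -> dict:
    """Execute the requested stages in order; returns a dict of artifact
    paths.  Any stage failure raises after writing an error report."""
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    mcmc = _mcmc_from_config(cfg)
    artifacts = {}
    state = {}

    def stage_log(stage):
        log.info("stage=%s seed=%d config=%s", stage, seed, chash)

    try:
        for stage in cfg["stages"]:
            stage_log(stage)
            if stage == "simulate":
                sim = cfg["simulate"]
                ds = simulate_magic_dataset(
                    n_lines=sim["n_lines"],
                    markers_per_chrom=sim["markers_per_chrom"],
                    environments=sim["environments"],
                    target_h2=sim["target_h2"],
                    n_qtl=sim["n_qtl"], main_var=sim["main_var"],
                    dev_var=sim["dev_var"], rng_seed=seed,
                )
                state["dataset"] = ds
                geno = pd.DataFrame(ds.population.dosages,
                                    index=ds.population.line_ids,
                                    columns=ds.genetic_map.table["marker"])
                state["geno"] = geno
                write_genotypes(geno, outdir / "genotypes.tsv",
                                header=_header_comment(chash, seed))
                write_genetic_map(ds.genetic_map, outdir / "map.tsv",
                                  header=_header_comment(chash, seed))
                _write_with_header(ds.plots, outdir / "plots.csv", chash, seed)
                artifacts["genotypes"] = outdir / "genotypes.tsv"
                artifacts["plots"] = outdir / "plots.csv"
            elif stage == "adjust":
                plots = state["dataset"].plots if "dataset" in state \
                    else read_plot_table(cfg["plots_path"])
                means = lattice.adjusted_means_by_environment(plots)
                std = lattice.standardize_phenotypes(means)
                state["means"] = std
                _write_with_header(std.blups, outdir / "adjusted_means.csv",
                                   chash, seed, index=True)
                report = {"h2": std.h2,
                          "center": std.center.to_dict(),
                          "scale": std.scale.to_dict()}
                (outdir / "variance_report.json").write_text(
                    json.dumps(report, indent=2))
                artifacts["adjusted_means"] = outdir / "adjusted_means.csv"
            elif stage == "fit":
                X = qc_and_standardize(state["geno"])
                state["X"] = X
                K = grm(X)
                D = squared_euclidean(X)
                state["K"], state["D"] = K, D
                y = state["means"].blups.iloc[:, 0].reindex(X.line_ids)
                fits = {}
                for m in cfg["models"]["se"]:
                    if m == "GB":
                        f = fit_se_kernel(K, y.to_numpy(), mcmc)
                        fits[m] = {"sigma_u2": f.sigma_u2_,
                                   "sigma_e2": f.sigma_e2_}
                    elif m == "GK":
                        h, _ = estimate_bandwidth(D, y.to_numpy())
                        f = fit_se_kernel(gaussian_kernel(D, h), y.to_numpy(),
                                          mcmc)
                        fits[m] = {"h": h, "sigma_u2": f.sigma_u2_,
                                   "sigma_e2": f.sigma_e2_}
                    else:
                        name = {"BayesA": "bayes_a", "BayesB": "bayes_b",
                                "BL": "bl"}[m]
                        f = BayesianAlphabetRegressor(
                            model=name, niter=mcmc.niter, burnin=mcmc.burnin,
                            thin=mcmc.thin, seed=mcmc.seed,
                        ).fit(X, (y - y.mean()).to_numpy() / y.std())
                        fits[m] = {"sigma_e2": f.sigma_e2_,
                                   "genetic_var": f.genetic_var_}
                me_fits = {}
                data = MEDataset(state["means"].blups)
                for kern_name in cfg.get("kernels", ["GB"]):
                    if kern_name == "GB":
                        Kme, env_kernels = K, None
                    else:
                        h, _ = estimate_bandwidth(
                            D, data.Y.mean(axis=1).to_numpy())
                        Kme = gaussian_kernel(D, h)
                        # per-environment bandwidths for the MDe deviations
                        env_kernels = []
                        for env in data.env_ids:
                            ye = data.Y[env].to_numpy()
                            he, _ = estimate_bandwidth(D, ye)
                            env_kernels.append(gaussian_kernel(D, he))
                    for m in cfg["models"]["me"]:
                        f = MultiEnvGP(model=m, niter=mcmc.niter,
                                       burnin=mcmc.burnin, thin=mcmc.thin,
                                       seed=mcmc.seed).fit(
                            data, Kme,
                            env_kernels=env_kernels if m == "MDe" else None)
                        me_fits[f"{m}-{kern_name}"] = \
                            f.variance_table_.to_dict("records")
                        _write_with_header(
                            f.gebv_, outdir / f"gebv_{m}_{kern_name}.csv",
                            chash, seed, index=True)
                (outdir / "fit_report.json").write_text(
                    json.dumps({"se": fits, "me": me_fits}, indent=2))
                artifacts["fit_report"] = outdir / "fit_report.json"
            elif stage == "optimize-tp":
                X, K = state["X"], state["K"]
                h2_prelim = max(min(
                    state["means"].h2[list(state["means"].h2)[0]], 0.95), 0.05)
                lam = (1 - h2_prelim) / h2_prelim
                ctx = tp_optim.CriterionContext(K.K, lam, X.line_ids)
                n_sel = min(cfg["tp"]["n_select"], X.n - 2)
                report = {}
                for crit in cfg["tp"]["criteria"]:
                    if crit == "entry_to_nearest_entry":
                        mrd = tp_optim.modified_rogers_distance(X.raw)
                        sel = tp_optim.entry_to_nearest_entry_select(
                            mrd, n_sel, rng_seed=seed)
                        sel.line_ids = list(X.line_ids)
                    else:
                        sel = tp_optim.exchange_optimize(
                            crit, ctx, n_sel, max_iters=5, rng_seed=seed)
                    report[crit] = {"value": sel.value,
                                    "selected": sel.selected_ids,
                                    "trajectory": sel.trajectory}
                    (outdir / f"tp_{crit}.txt").write_text(
                        "\n".join(str(i) for i in sel.selected_ids))
                (outdir / "tp_report.json").write_text(
                    json.dumps(report, indent=2))
                artifacts["tp_report"] = outdir / "tp_report.json"
            elif stage == "crossval":
                X = state["X"]
                y = state["means"].blups.iloc[:, 0].reindex(X.line_ids)
                sweep = evaluate.tp_size_sweep(
                    cfg["models"]["se"], X, y.to_numpy(),
                    sizes=cfg["cv"]["sizes"], n_reps=cfg["cv"]["n_reps"],
                    mcmc=mcmc, rng_seed=seed)
                rows = [{"model": m, "tp_size": s, "mean": r.mean,
                         "sd": r.sd} for (m, s), r in sweep.items()]
                _write_with_header(pd.DataFrame(rows),
                                   outdir / "cv_sweep.csv", chash, seed)
                data = MEDataset(state["means"].blups)
                me_rows = []
                for scheme in ("CV1", "CV2"):
                    if scheme == "CV2" and data.n_envs < 2:
                        continue
                    parts = evaluate.make_me_partitions(
                        data, scheme, n_reps=cfg["cv"]["me_n_reps"],
                        rng_seed=seed)
                    for m in cfg["models"]["me"]:
                        res = evaluate.me_crossval(data, m, state["K"],
                                                   parts, mcmc=mcmc)
                        me_rows.append({"scheme": scheme, "model": m,
                                        "mean": res.mean, "sd": res.sd})
                _write_with_header(pd.DataFrame(me_rows),
                                   outdir / "cv_me.csv", chash, seed)
                artifacts["cv_sweep"] = outdir / "cv_sweep.csv"
                artifacts["cv_me"] = outdir / "cv_me.csv"
            elif stage == "popgen":
                X = state["X"]
                scores, frac = evaluate.run_pca(X)
                pca = pd.DataFrame(scores, index=X.line_ids,
                                   columns=[f"PC{i+1}" for i in
                                            range(scores.shape[1])])
                _write_with_header(pca, outdir / "pca.csv", chash, seed,
                                   index=True)
                gmap = state["dataset"].genetic_map
                ld = evaluate.ld_decay(state["geno"].to_numpy(), gmap)
                _write_with_header(ld.binned, outdir / "ld_decay.csv",
                                   chash, seed)
                artifacts["pca"] = outdir / "pca.csv"
                artifacts["ld_decay"] = outdir / "ld_decay.csv"
            else:
                raise ValueError(f"unknown stage {stage!r}")
    except Exception as exc:
        (outdir / "error_report.json").write_text(json.dumps(
            {"stage": stage, "error": str(exc),
             "type": type(exc).__name__}))
        raise
    return artifacts
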