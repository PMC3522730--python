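"""End-to-end orchestration: QC -> ancestry PCA -> set tests -> per-SNP
tests -> permutation FWER -> report bundle.

Reports mirror the study's presentation: a cohort-characteristics table, a
hierarchical set-test table (overall and per-ethnicity columns), a per-SNP
table restricted to SNPs with at least one contrast p-value below a
threshold (default 0.01), FWER-adjusted p-values per grouping level, and a
JSON run manifest for provenance.

Permutation recomputation at the kernel levels refits the covariate-only
null model on every permuted label vector; at the SNP level the
log-additive 1-df score test is recomputed (vectorised across SNPs), the
score test being the permutation-friendly analogue of the reported Wald
trend test.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geno_io import (GenotypeMatrix, SampleTable, SnpAnnotation, PathwayHierarchy,
                      read_genotypes, read_samples, read_annotation,
                      qc_samples, qc_snps)
from .ancestry import pca_ancestry
from .kernel import (fit_null_logistic, run_set_tests, results_frame,
                     SetTestEngine, DEFAULT_COVARIATES, _projected_gram)
from .snp_assoc import assoc_all_snps, snp_results_frame
from .multiplicity import minp_fwer, DEFAULT_B
from .descriptives import cohort_summary
from scipy.stats import chi2

log = logging.getLogger("pathassoc")

__all__ = ["RunConfig", "run_pipeline", "run_pipeline_frames"]


@dataclass
class RunConfig:
    genotypes: str | Path | None = None
    samples: str | Path | None = None
    annotation: str | Path | None = None
    out_dir: str | Path = "pathassoc_out"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    stratify: bool = True
    n_perm: int = DEFAULT_B
    seed: int | None = None
    snp_p_threshold: float = 0.01
    fwer_levels: tuple[str, ...] = ("pathway", "subpathway", "gene", "snp")
    permutation_scheme: str = "stratified"

    def __post_init__(self):
        if self.n_perm > 0 and self.seed is None:
            raise ValueError("seed is mandatory when permutations are requested")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps({k: str(v) for k, v in vars(cfg).items()}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    gm = read_genotypes(cfg.genotypes)
    samples = read_samples(cfg.samples)
    ann = read_annotation(cfg.annotation)
    return run_pipeline_frames(gm, samples, ann, cfg)


def _kernel_fwer_callback(gm: GenotypeMatrix, samples: SampleTable,
                          sets: dict[str, list[str]], covariates):
    """Per-permutation recomputation of one kernel level (null refit each time)."""
    g_imputed = gm.mean_imputed()
    idx = {label: gm.snp_index(ids) for label, ids in sets.items()}

    def callback(perm_status: np.ndarray) -> np.ndarray:
        out = np.empty((perm_status.shape[0], len(sets)))
        df = samples.table
        for b in range(perm_status.shape[0]):
            perm_samples = SampleTable(df.assign(status=perm_status[b].astype(int)))
            null = fit_null_logistic(perm_samples, covariates)
            from .quadform import quadform_pvalue
            from .kernel import null_spectrum
            for j, label in enumerate(sets):
                block = g_imputed[:, idx[label]]
                lam = null_spectrum(null, block)
                s = block.T @ null.residuals
                q = float(s @ s)
                out[b, j] = 1.0 if lam.size == 0 else quadform_pvalue(q, lam)[0]
        return out

    return callback


def _snp_score_pvalues(gm: GenotypeMatrix, samples: SampleTable, covariates,
                       status_rows: np.ndarray) -> np.ndarray:
    """Vectorised 1-df trend score test p-values, one row per status vector."""
    g = gm.mean_imputed()
    df = samples.table
    out = np.empty((status_rows.shape[0], g.shape[1]))
    for b in range(status_rows.shape[0]):
        perm = SampleTable(df.assign(status=status_rows[b].astype(int)))
        null = fit_null_logistic(perm, covariates)
        u = g.T @ null.residuals
        v = null.weights
        X = null.design
        gv = g * v[:, None]
        xtvx = X.T @ (X * v[:, None])
        xtvg = X.T @ gv
        var = np.einsum("ij,ij->j", g, gv) - np.einsum(
            "ij,ij->j", xtvg, np.linalg.solve(xtvx, xtvg))
        var = np.maximum(var, 1e-300)
        out[b] = chi2.sf(u * u / var, df=1)
    return out


def run_pipeline_frames(gm: GenotypeMatrix, samples: SampleTable,
                        ann: SnpAnnotation, cfg: RunConfig) -> dict:
    """Run every stage on in-memory inputs; writes the report bundle."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> Path:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
        return path

    try:
        return _run_stages(gm, samples, ann, cfg, out_dir, emit, written)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        stage = getattr(exc, "_stage", "unknown")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                exc._stage = name
                raise
        return wrapped
    return deco


def _run_stages(gm, samples, ann, cfg, out_dir, emit, written):
    results: dict = {}

    # --- QC ------------------------------------------------------------
    log.info("stage qc: %d samples x %d SNPs in", gm.n_samples, gm.n_snps)
    gm, sample_log = qc_samples(gm)
    samples = samples.subset(samples.table["sample_id"].isin(gm.sample_ids).to_numpy())
    gm, snp_log = qc_snps(gm, samples)
    exclusions = pd.concat([sample_log.assign(axis="sample"),
                            snp_log.assign(axis="snp")], ignore_index=True)
    emit("exclusions.tsv", exclusions)
    ann_kept = SnpAnnotation(ann.table[ann.table["snp_id"].isin(gm.snp_ids)]
                             .reset_index(drop=True))

    # --- ancestry PCA on AIMs ------------------------------------------
    aims = [s for s in ann_kept.aim_ids if s in gm.snp_ids]
    if aims:
        scores = pca_ancestry(gm.subset(snps=aims), k=2)
        samples = samples.with_ancestry(scores.pc1)
        emit("ancestry.tsv", scores.scores.reset_index())
    hierarchy = PathwayHierarchy.from_annotation(ann_kept)

    # partition check: every candidate SNP in exactly one gene set
    counts = pd.Series([s for ids in hierarchy.genes.values() for s in ids]).value_counts()
    if (counts != 1).any() or set(counts.index) != set(hierarchy.pathway):
        raise ValueError("gene-level sets do not partition the candidate SNPs")

    samples = samples.aligned_to(gm)

    # --- descriptives ---------------------------------------------------
    summary = cohort_summary(samples)
    emit("cohort_summary.tsv", summary.table)
    results["cohort"] = summary

    # --- set-level kernel tests ----------------------------------------
    covs = tuple(c for c in cfg.covariates
                 if c != "ancestry_pc1" or "ancestry_pc1" in samples.table.columns)
    cand_gm = gm.subset(snps=hierarchy.pathway)
    set_results = run_set_tests(cand_gm, samples, hierarchy, covariates=covs)
    if cfg.stratify:
        set_results += run_set_tests(cand_gm, samples, hierarchy, covariates=covs,
                                     strata="ethnicity")
    set_frame = results_frame(set_results)
    emit("set_tests.tsv", set_frame)
    results["set_tests"] = set_frame

    # --- per-SNP tests --------------------------------------------------
    snp_results = assoc_all_snps(cand_gm, samples, covariates=covs)
    if cfg.stratify:
        snp_results += assoc_all_snps(cand_gm, samples, covariates=covs,
                                      strata="ethnicity")
    snp_frame = snp_results_frame(snp_results, ann_kept)
    emit("snp_tests_all.tsv", snp_frame)
    overall = snp_frame[snp_frame["stratum"] == "overall"]
    hits = overall.loc[overall["p_value"] < cfg.snp_p_threshold, "snp"].unique()
    emit("snp_tests_top.tsv", snp_frame[snp_frame["snp"].isin(hits)])
    results["snp_tests"] = snp_frame

    # --- permutation FWER ----------------------------------------------
    fwer_frames = []
    if cfg.n_perm > 0:
        rng = np.random.default_rng(cfg.seed)
        obs_overall = set_frame[(set_frame["stratum"] == "overall") & set_frame["tested"]]
        for level in cfg.fwer_levels:
            sub_seed = int(rng.integers(2 ** 31 - 1))
            if level == "snp":
                obs = _snp_score_pvalues(cand_gm, samples, covs,
                                         samples.status[None, :])[0]
                labels = list(cand_gm.snp_ids)
                cb = lambda perms: _snp_score_pvalues(cand_gm, samples, covs, perms)
            else:
                rows = obs_overall[obs_overall["level"] == level]
                if rows.empty:
                    continue
                obs = rows["p_value"].to_numpy()
                labels = list(rows["set"])
                sets = {lb: hierarchy.level_sets(level)[lb] for lb in labels}
                cb = _kernel_fwer_callback(cand_gm, samples, sets, covs)
            summary = minp_fwer(obs, cfg.n_perm, cb, sub_seed, samples,
                                level=level, test_labels=labels,
                                scheme=cfg.permutation_scheme)
            fwer_frames.append(summary.frame())
        if fwer_frames:
            fwer = pd.concat(fwer_frames, ignore_index=True)
            emit("fwer.tsv", fwer)
            results["fwer"] = fwer

    # --- manifest -------------------------------------------------------
    manifest = {
        "package": "pathassoc",
        "version": __version__,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "config_hash": _config_hash(cfg),
        "n_samples": gm.n_samples,
        "n_candidate_snps": len(hierarchy.pathway),
        "covariates": list(covs),
        "python": sys.version.split()[0],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    written.append(path)
    results["manifest"] = manifest
    results["out_dir"] = out_dir
    return results
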