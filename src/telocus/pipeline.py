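"""End-to-end orchestration: ingest -> dedup -> fit -> reassign -> count ->
correct -> write, plus the bounds workflow, wired to files."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np

from . import __version__
from .annotation import (
    TEAnnotation,
    build_interval_index,
    load_te_annotation,
    write_features_tsv,
)
from .bounds import BoundsReport, compute_bounds, evaluate_estimates
from .counting import (
    UMICountMatrix,
    apply_correction,
    build_correction_matrix,
    count_umis,
    reassign,
    write_mtx,
    write_te_load_tsv,
)
from .dedup import deduplicate
from .ingest import filter_alignments, load_whitelist, read_alignments, build_weight_matrix
from .model import assign_pools, fit_em
from .counting import aggregate_by_subfamily

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_bounds", "load_labels"]


@dataclass
class RunConfig:
    """Run parameters; defaults match the published defaults (20% overlap,
    priors pi=0 / theta=200000, 500 iterations, tolerance 1e-7)."""

    alignments: str
    gtf: str
    whitelist: str
    out_dir: str
    labels: str | None = None
    pooling_mode: str = "pseudobulk"
    reassign_mode: str = "best_exclude"
    min_overlap: float = 0.2
    score_scale: float = 1.0
    pi_prior: float = 0.0
    theta_prior: float = 200000.0
    max_iter: int = 500
    em_tol: float = 1e-7
    tie_tol: float = 1e-12
    seed: int = 0


@dataclass
class PipelineResult:
    matrix_raw: UMICountMatrix
    matrix_corrected: UMICountMatrix
    fitted: "object"
    dedup_report: "object"
    ingest_report: "object"
    out_files: dict[str, str]


def load_labels(path: str) -> dict[str, str]:
    """Two-column TSV: barcode <tab> label."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'barcode<TAB>label'")
            labels[parts[0]] = parts[1]
    return labels


def run_pipeline(config: RunConfig) -> PipelineResult:
    for path in (config.alignments, config.gtf, config.whitelist):
        if not os.path.exists(path):
            raise FileNotFoundError(path)
    if config.pooling_mode == "celltype" and not config.labels:
        raise ValueError("celltype pooling requires a labels TSV")
    labels = load_labels(config.labels) if config.labels else None

    os.makedirs(config.out_dir, exist_ok=True)
    t0 = time.time()
    with open(config.gtf) as fh:
        annotation = load_te_annotation(fh)
    index = build_interval_index(annotation)
    with open(config.whitelist) as fh:
        whitelist = load_whitelist(fh)
    logger.info("annotation: %d loci; whitelist: %d cells", annotation.K, len(whitelist))

    groups = filter_alignments(read_alignments(config.alignments), whitelist)
    matrix = build_weight_matrix(
        groups, index, min_overlap=config.min_overlap, score_scale=config.score_scale
    )
    with open(os.path.join(config.out_dir, "ingest_report.tsv"), "w") as fh:
        matrix.report.to_tsv(fh)
    logger.info("weight matrix: %d fragments x %d features", *matrix.weights.shape)

    matrix, dedup_report = deduplicate(matrix)
    with open(os.path.join(config.out_dir, "dedup_report.tsv"), "w") as fh:
        dedup_report.to_tsv(fh)
    logger.info(
        "dedup: %d -> %d fragments (%d duplicates removed)",
        dedup_report.fragments_in,
        dedup_report.fragments_out,
        dedup_report.duplicates_removed,
    )

    barcodes = sorted(whitelist)
    pools = assign_pools(barcodes, config.pooling_mode, labels)
    fitted = fit_em(
        matrix,
        pools,
        pi_prior=config.pi_prior,
        theta_prior=config.theta_prior,
        max_iter=config.max_iter,
        tol=config.em_tol,
    )
    with open(os.path.join(config.out_dir, "fit_report.tsv"), "w") as fh:
        fitted.fit_report(fh, matrix)
    logger.info(
        "EM: %d iterations, converged=%s, lnL=%.4f, BIC=%.4f",
        fitted.iterations,
        fitted.converged,
        fitted.lnL,
        fitted.BIC,
    )

    rng = np.random.default_rng(config.seed)
    assignments = reassign(
        fitted.posterior,
        matrix,
        strategy=config.reassign_mode,
        tie_tol=config.tie_tol,
        rng=rng,
    )
    feature_meta = dict(annotation.subfamily_of)
    raw = count_umis(assignments, matrix, annotation.locus_ids, barcodes, feature_meta)
    correction = build_correction_matrix(
        assignments, matrix, annotation.locus_ids, barcodes
    )
    corrected = apply_correction(raw, correction)

    out_files = write_mtx(corrected, config.out_dir)
    with open(os.path.join(config.out_dir, "features_annotation.tsv"), "w") as fh:
        write_features_tsv(annotation, fh)

    # TE load: corrected TE UMIs over all feature-assigned UMIs per cell.
    # Canonical-gene UMIs per cell are the deduplicated GX-flagged fragments
    # (those are the ones counted by the upstream gene quantifier).
    te_per_cell = dict(zip(corrected.barcodes, corrected.per_cell_totals()))
    cg_per_cell: dict[str, float] = {b: 0.0 for b in barcodes}
    for i in range(matrix.n_fragments):
        if matrix.gx[i]:
            cg_per_cell[matrix.barcodes[i]] += 1.0
    total_per_cell = {
        b: te_per_cell.get(b, 0.0) + cg_per_cell.get(b, 0.0) for b in barcodes
    }
    with open(os.path.join(config.out_dir, "te_load.tsv"), "w") as fh:
        write_te_load_tsv(fh, te_per_cell, total_per_cell)

    manifest = {
        "tool": "telocus",
        "version": __version__,
        "config": asdict(config),
        "n_loci": annotation.K,
        "n_cells": len(barcodes),
        "fragments_after_dedup": matrix.n_fragments,
        "em_iterations": fitted.iterations,
        "em_converged": fitted.converged,
        "lnL": fitted.lnL,
        "k": fitted.k,
        "n": fitted.n,
        "BIC": fitted.BIC,
        "AIC": fitted.AIC,
        "total_raw_umis": raw.total,
        "total_corrected_umis": corrected.total,
        "elapsed_sec": time.time() - t0,
    }
    manifest_path = os.path.join(config.out_dir, "run_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    out_files["manifest"] = manifest_path

    return PipelineResult(
        matrix_raw=raw,
        matrix_corrected=corrected,
        fitted=fitted,
        dedup_report=dedup_report,
        ingest_report=matrix.report,
        out_files=out_files,
    )


def run_bounds(
    config: RunConfig,
    scope: str = "cell",
    estimates: Mapping[str, float] | None = None,
) -> BoundsReport:
    """Compute feasibility bounds from the same filtered alignments the
    pipeline consumes; optionally classify the provided estimates."""
    with open(config.gtf) as fh:
        annotation = load_te_annotation(fh)
    index = build_interval_index(annotation)
    with open(config.whitelist) as fh:
        whitelist = load_whitelist(fh)
    groups = filter_alignments(read_alignments(config.alignments), whitelist)
    report = compute_bounds(groups, index, min_overlap=config.min_overlap, scope=scope)
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "bounds.tsv"), "w") as fh:
        report.to_tsv(fh)
    if estimates is not None:
        evaluation = evaluate_estimates(estimates, report)
        with open(os.path.join(config.out_dir, "evaluation.tsv"), "w") as fh:
            evaluation.to_tsv(fh)
    return report


def aggregate_matrix(
    matrix: UMICountMatrix, annotation: TEAnnotation, out_dir: str
) -> UMICountMatrix:
    agg = aggregate_by_subfamily(matrix, annotation)
    write_mtx(agg, out_dir)
    return agg
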