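"""Read barcoded alignments, filter to passing cells, and build the initial
fragment x feature weight matrix by intersecting alignments with the TE
annotation.

Column 0 of the weight matrix is the NO_FEATURE component: alignments that
fall below the overlap threshold, or outside the annotation entirely, load
there.  Fragments with no locus candidate at all are excluded from the matrix
but tallied in the run report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
import pysam
import scipy.sparse as sp

from .annotation import IntervalIndex, TELocus

NO_FEATURE = "__no_feature__"

__all__ = [
    "NO_FEATURE",
    "AlignmentRecord",
    "WeightMatrix",
    "IngestReport",
    "read_alignments",
    "load_whitelist",
    "filter_alignments",
    "overlap_fraction",
    "build_weight_matrix",
]


@dataclass
class AlignmentRecord:
    """One alignment of one read; coordinates 0-based half-open."""

    read_name: str
    chrom: str
    start: int
    end: int
    score: float
    cell_barcode: str | None
    umi: str | None
    n_hits: int = 1
    gene_tag: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.read_name}: empty span [{self.start}, {self.end})"
            )


@dataclass
class IngestReport:
    records_read: int = 0
    records_dropped_no_cb_ub: int = 0
    records_dropped_not_whitelisted: int = 0
    fragments_retained: int = 0
    fragments_te_overlapping: int = 0
    fragments_no_feature_only: int = 0

    def to_tsv(self, out_stream: IO[str]) -> None:
        for k, v in vars(self).items():
            out_stream.write(f"{k}\t{v}\n")


@dataclass
class WeightMatrix:
    """Sparse fragments x (NO_FEATURE + loci) alignment-weight matrix.

    Rows are fragments (unique read names); ``weights`` holds q with row
    maximum 1.  ``ambiguous`` is the y indicator (>=2 distinct locus
    candidates), ``gx`` marks fragments carrying a gene (GX) tag on any
    alignment, and ``best_score`` is the fragment's top alignment score
    (used for dedup representative selection).
    """

    weights: sp.csr_matrix
    feature_ids: list[str]
    read_names: np.ndarray
    barcodes: np.ndarray
    umis: np.ndarray
    ambiguous: np.ndarray
    gx: np.ndarray
    best_score: np.ndarray
    report: IngestReport = field(default_factory=IngestReport)

    def __post_init__(self) -> None:
        if self.feature_ids[0] != NO_FEATURE:
            raise ValueError("feature_ids[0] must be the NO_FEATURE column")
        n = self.weights.shape[0]
        for name in ("read_names", "barcodes", "umis", "ambiguous", "gx", "best_score"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of rows")

    @property
    def n_fragments(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    def row_features(self, i: int) -> list[int]:
        """Nonzero column indices of row i."""
        w = self.weights
        return list(w.indices[w.indptr[i] : w.indptr[i + 1]])

    def row_locus_set(self, i: int) -> frozenset[int]:
        """Nonzero *locus* columns of row i (NO_FEATURE excluded)."""
        return frozenset(j for j in self.row_features(i) if j != 0)

    def subset_rows(self, keep: np.ndarray) -> "WeightMatrix":
        return WeightMatrix(
            weights=self.weights[keep].tocsr(),
            feature_ids=self.feature_ids,
            read_names=self.read_names[keep],
            barcodes=self.barcodes[keep],
            umis=self.umis[keep],
            ambiguous=self.ambiguous[keep],
            gx=self.gx[keep],
            best_score=self.best_score[keep],
            report=self.report,
        )


def load_whitelist(stream: IO[str] | Iterable[str]) -> set[str]:
    wl = {line.strip() for line in stream if line.strip()}
    if not wl:
        raise ValueError("barcode whitelist is empty")
    return wl


def read_alignments(path: str) -> Iterator[AlignmentRecord]:
    """Yield mapped alignment records from a SAM/BAM file via pysam."""
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for seg in fh:
                if seg.is_unmapped:
                    continue
                yield AlignmentRecord(
                    read_name=seg.query_name,
                    chrom=seg.reference_name,
                    start=seg.reference_start,
                    end=seg.reference_end,
                    score=float(seg.get_tag("AS")) if seg.has_tag("AS") else 0.0,
                    cell_barcode=seg.get_tag("CB") if seg.has_tag("CB") else None,
                    umi=seg.get_tag("UB") if seg.has_tag("UB") else None,
                    n_hits=int(seg.get_tag("NH")) if seg.has_tag("NH") else 1,
                    gene_tag=seg.get_tag("GX") if seg.has_tag("GX") else None,
                )
    finally:
        pysam.set_verbosity(save)


def filter_alignments(
    records: Iterable[AlignmentRecord],
    barcode_whitelist: set[str],
    report: IngestReport | None = None,
) -> list[tuple[str, list[AlignmentRecord]]]:
    """Keep whitelisted, fully-tagged records and group them by read name.

    Records lacking a CB or UB tag are dropped and counted; output groups are
    emitted in sorted read-name order so downstream processing is
    deterministic regardless of the input sort.
    """
    if not barcode_whitelist:
        raise ValueError("barcode whitelist is empty")
    report = report if report is not None else IngestReport()
    groups: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        report.records_read += 1
        if not rec.cell_barcode or not rec.umi:
            report.records_dropped_no_cb_ub += 1
            continue
        if rec.cell_barcode not in barcode_whitelist:
            report.records_dropped_not_whitelisted += 1
            continue
        groups.setdefault(rec.read_name, []).append(rec)
    out = sorted(groups.items())
    report.fragments_retained = len(out)
    return out


def overlap_fraction(record: AlignmentRecord, locus: TELocus) -> float:
    """Fraction of the record span covered by the locus's merged intervals."""
    if record.chrom != locus.chrom:
        return 0.0
    span = record.end - record.start
    ov = 0
    for s, e in locus.intervals:
        ov += max(0, min(e, record.end) - max(s, record.start))
    return ov / span


def build_weight_matrix(
    read_groups: Iterable[tuple[str, list[AlignmentRecord]]],
    index: IntervalIndex,
    min_overlap: float = 0.2,
    score_scale: float = 1.0,
    report: IngestReport | None = None,
) -> WeightMatrix:
    """Assign each alignment to loci meeting the overlap threshold and compute
    per-fragment weights q = exp((AS - AS_best) / score_scale).

    Multiple alignments of a fragment to the same locus keep only the
    max-weight one.  With min_overlap == 0, any alignment intersecting a locus
    by at least one base contributes a candidate.
    """
    annotation = index.annotation
    col_of = {lid: j + 1 for j, lid in enumerate(annotation.locus_ids)}
    feature_ids = [NO_FEATURE] + annotation.locus_ids

    rows: list[dict[int, float]] = []
    names: list[str] = []
    cbs: list[str] = []
    ubs: list[str] = []
    ys: list[int] = []
    gxs: list[bool] = []
    best_scores: list[float] = []
    report = report if report is not None else IngestReport()

    for read_name, alns in read_groups:
        if not alns:
            raise RuntimeError(f"fragment {read_name!r} has zero alignments")
        # feature column -> best raw score among this fragment's alignments
        cand: dict[int, float] = {}
        gx_flag = False
        for rec in alns:
            if rec.gene_tag:
                gx_flag = True
            overlaps = index.query_overlaps(rec.chrom, rec.start, rec.end)
            span = rec.end - rec.start
            hit = False
            for lid, ov in overlaps.items():
                frac = ov / span
                if frac >= min_overlap and ov > 0:
                    col = col_of[lid]
                    if rec.score > cand.get(col, -math.inf):
                        cand[col] = rec.score
                    hit = True
            if not hit:
                if rec.score > cand.get(0, -math.inf):
                    cand[0] = rec.score
        locus_cols = [c for c in cand if c != 0]
        if not locus_cols:
            report.fragments_no_feature_only += 1
            continue
        as_max = max(cand.values())
        row = {
            c: math.exp((s - as_max) / score_scale) for c, s in cand.items()
        }
        rows.append(row)
        names.append(read_name)
        cbs.append(alns[0].cell_barcode)
        ubs.append(alns[0].umi)
        ys.append(1 if len(locus_cols) >= 2 else 0)
        gxs.append(gx_flag)
        best_scores.append(as_max)

    report.fragments_te_overlapping = len(rows)
    n = len(rows)
    k1 = len(feature_ids)
    data: list[float] = []
    indices: list[int] = []
    indptr = [0]
    for row in rows:
        for c in sorted(row):
            indices.append(c)
            data.append(row[c])
        indptr.append(len(indices))
    weights = sp.csr_matrix(
        (np.array(data), np.array(indices, dtype=np.int32), np.array(indptr, dtype=np.int64)),
        shape=(n, k1),
    )
    return WeightMatrix(
        weights=weights,
        feature_ids=feature_ids,
        read_names=np.array(names, dtype=object),
        barcodes=np.array(cbs, dtype=object),
        umis=np.array(ubs, dtype=object),
        ambiguous=np.array(ys, dtype=np.int8),
        gx=np.array(gxs, dtype=bool),
        best_score=np.array(best_scores, dtype=float),
        report=report,
    )
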