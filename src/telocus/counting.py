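"""Turn posterior membership weights into final read assignments and per-cell
UMI count matrices; correct for canonical-gene double counting; aggregate to
subfamilies; compute TE load.

The normative reassignment strategy is ``best_exclude``: keep the single
highest-posterior alignment, exclude the fragment when two or more candidates
tie for the maximum (within ``tie_tol``).  ``best_random`` breaks ties with a
seeded RNG and ``average`` distributes the posterior fractionally (rounded
only at serialization).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .annotation import TEAnnotation
from .ingest import NO_FEATURE, WeightMatrix

logger = logging.getLogger(__name__)

EXCLUDED = "__excluded__"

STRATEGIES = ("best_exclude", "best_random", "average")

__all__ = [
    "EXCLUDED",
    "STRATEGIES",
    "Assignment",
    "UMICountMatrix",
    "reassign",
    "count_umis",
    "build_correction_matrix",
    "apply_correction",
    "aggregate_by_subfamily",
    "te_load",
    "write_mtx",
    "read_mtx",
]


@dataclass
class Assignment:
    fragment: int
    feature: str  # locus_id, NO_FEATURE, or EXCLUDED
    posterior: float
    # fractional weights for the "average" strategy; None otherwise
    fractions: dict[str, float] | None = None


@dataclass
class UMICountMatrix:
    """features x cells sparse count matrix (float internally to allow the
    fractional ``average`` strategy; integral for best_exclude)."""

    features: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix
    feature_meta: dict[str, str] = field(default_factory=dict)  # feature -> subfamily

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.features), len(self.barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.features)}, {len(self.barcodes)})"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def per_cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def per_feature_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


def reassign(
    posterior: sp.csr_matrix,
    matrix: WeightMatrix,
    strategy: str = "best_exclude",
    tie_tol: float = 1e-12,
    rng: np.random.Generator | None = None,
) -> list[Assignment]:
    """One Assignment per fragment from its posterior row.

    best_exclude: unique argmax within tie_tol, else EXCLUDED.
    best_random: ties broken uniformly at random (seeded rng required for
    reproducibility).  average: fractional assignment over the full row.
    """
    if strategy not in STRATEGIES:
        raise ValueError(
            f"unknown reassignment strategy {strategy!r}; supported: {', '.join(STRATEGIES)}"
        )
    if strategy == "best_random" and rng is None:
        rng = np.random.default_rng()
    X = posterior
    out: list[Assignment] = []
    fid = matrix.feature_ids
    for i in range(X.shape[0]):
        lo, hi = X.indptr[i], X.indptr[i + 1]
        cols = X.indices[lo:hi]
        vals = X.data[lo:hi]
        if len(cols) == 0:
            raise ValueError(f"fragment {i} has an empty posterior row")
        if strategy == "average":
            out.append(
                Assignment(
                    fragment=i,
                    feature="",
                    posterior=float(vals.max()),
                    fractions={fid[c]: float(v) for c, v in zip(cols, vals)},
                )
            )
            continue
        vmax = vals.max()
        tied = np.flatnonzero(vals >= vmax - tie_tol)
        if len(tied) == 1:
            c = cols[tied[0]]
            out.append(Assignment(fragment=i, feature=fid[c], posterior=float(vmax)))
        elif strategy == "best_random":
            c = cols[rng.choice(tied)]
            out.append(Assignment(fragment=i, feature=fid[c], posterior=float(vmax)))
        else:
            out.append(Assignment(fragment=i, feature=EXCLUDED, posterior=float(vmax)))
    return out


def _tally(
    pairs: list[tuple[str, str, float]],
    feature_order: Sequence[str],
    barcode_order: Sequence[str],
) -> sp.csr_matrix:
    fidx = {f: r for r, f in enumerate(feature_order)}
    bidx = {b: c for c, b in enumerate(barcode_order)}
    rows, cols, vals = [], [], []
    for f, b, v in pairs:
        rows.append(fidx[f])
        cols.append(bidx[b])
        vals.append(v)
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(feature_order), len(barcode_order))
    )


def count_umis(
    assignments: list[Assignment],
    matrix: WeightMatrix,
    feature_order: Sequence[str],
    barcode_order: Sequence[str],
    feature_meta: Mapping[str, str] | None = None,
) -> UMICountMatrix:
    """counts[f, c] = fragments with barcode c assigned to locus f.

    EXCLUDED and NO_FEATURE assignments contribute nothing.  Fractional
    (average-strategy) assignments accumulate their locus fractions.
    """
    known = set(feature_order)
    pairs: list[tuple[str, str, float]] = []
    for a in assignments:
        cb = matrix.barcodes[a.fragment]
        if a.fractions is not None:
            for f, v in a.fractions.items():
                if f in known and v > 0:
                    pairs.append((f, cb, v))
        elif a.feature in known:
            pairs.append((a.feature, cb, 1.0))
    counts = _tally(pairs, feature_order, barcode_order)
    return UMICountMatrix(
        features=list(feature_order),
        barcodes=list(barcode_order),
        counts=counts,
        feature_meta=dict(feature_meta or {}),
    )


def build_correction_matrix(
    assignments: list[Assignment],
    matrix: WeightMatrix,
    feature_order: Sequence[str],
    barcode_order: Sequence[str],
) -> UMICountMatrix:
    """correction[f, c] = fragments assigned to f in cell c whose GX flag is
    set (i.e. also counted by the canonical-gene quantifier)."""
    known = set(feature_order)
    pairs: list[tuple[str, str, float]] = []
    for a in assignments:
        if not matrix.gx[a.fragment]:
            continue
        cb = matrix.barcodes[a.fragment]
        if a.fractions is not None:
            for f, v in a.fractions.items():
                if f in known and v > 0:
                    pairs.append((f, cb, v))
        elif a.feature in known:
            pairs.append((a.feature, cb, 1.0))
    return UMICountMatrix(
        features=list(feature_order),
        barcodes=list(barcode_order),
        counts=_tally(pairs, feature_order, barcode_order),
    )


def apply_correction(
    te_counts: UMICountMatrix, correction: UMICountMatrix
) -> UMICountMatrix:
    """Entrywise ``counts - correction`` floored at 0 (warning when floored)."""
    if (
        te_counts.features != correction.features
        or te_counts.barcodes != correction.barcodes
    ):
        raise ValueError("count and correction matrices are not aligned")
    diff = (te_counts.counts - correction.counts).tocsr()
    if diff.nnz and diff.data.min() < 0:
        n_neg = int((diff.data < 0).sum())
        logger.warning(
            "correction exceeds counts in %d entries; flooring at zero", n_neg
        )
        diff.data = np.maximum(diff.data, 0.0)
    diff.eliminate_zeros()
    return UMICountMatrix(
        features=list(te_counts.features),
        barcodes=list(te_counts.barcodes),
        counts=diff,
        feature_meta=dict(te_counts.feature_meta),
    )


def aggregate_by_subfamily(
    corrected: UMICountMatrix, annotation: TEAnnotation
) -> UMICountMatrix:
    """Sum member-locus rows into one row per subfamily (column totals kept)."""
    missing = [f for f in corrected.features if f not in annotation.subfamily_of]
    if missing:
        raise KeyError(f"loci missing from subfamily map: {missing[:5]}")
    subfams = list(dict.fromkeys(annotation.subfamily_of[f] for f in corrected.features))
    sidx = {s: r for r, s in enumerate(subfams)}
    rows = np.array(
        [sidx[annotation.subfamily_of[f]] for f in corrected.features], dtype=np.int64
    )
    agg = sp.csr_matrix(
        (np.ones(len(rows)), (rows, np.arange(len(rows)))),
        shape=(len(subfams), len(corrected.features)),
    )
    return UMICountMatrix(
        features=subfams,
        barcodes=list(corrected.barcodes),
        counts=(agg @ corrected.counts).tocsr(),
    )


def te_load(
    te_counts_per_cell: Mapping[str, float],
    total_counts_per_cell: Mapping[str, float],
) -> dict[str, float]:
    """Per-cell fraction of feature-assigned UMIs that derive from TE loci.

    Cells with zero total counts are omitted with a warning.
    """
    out: dict[str, float] = {}
    skipped = 0
    for cell, total in total_counts_per_cell.items():
        te = te_counts_per_cell.get(cell, 0.0)
        if total <= 0:
            skipped += 1
            continue
        if te > total:
            raise ValueError(f"cell {cell!r}: TE counts {te} exceed total {total}")
        out[cell] = te / total
    if skipped:
        logger.warning("%d cells omitted from TE load (zero total counts)", skipped)
    return out


def write_te_load_tsv(
    out_stream: IO[str],
    te_counts_per_cell: Mapping[str, float],
    total_counts_per_cell: Mapping[str, float],
) -> None:
    loads = te_load(te_counts_per_cell, total_counts_per_cell)
    out_stream.write("barcode\tte_umis\ttotal_umis\tload_pct\n")
    for cell in loads:
        te = te_counts_per_cell.get(cell, 0.0)
        tot = total_counts_per_cell[cell]
        out_stream.write(f"{cell}\t{te:g}\t{tot:g}\t{100.0 * loads[cell]:.6f}\n")


def write_mtx(matrix: UMICountMatrix, out_dir: str) -> dict[str, str]:
    """Write matrix.mtx / features.tsv / barcodes.tsv (10x triple-file layout).

    Coordinate indices are 1-based; values are integers when the matrix is
    integral (fractional averages are rounded only here).
    """
    os.makedirs(out_dir, exist_ok=True)
    mtx_path = os.path.join(out_dir, "matrix.mtx")
    coo = matrix.counts.tocoo()
    data = coo.data
    if np.allclose(data, np.round(data)):
        coo = sp.coo_matrix(
            (np.round(data).astype(np.int64), (coo.row, coo.col)), shape=coo.shape
        )
    else:
        coo = sp.coo_matrix(
            (np.round(data).astype(np.int64), (coo.row, coo.col)), shape=coo.shape
        )
        logger.warning("fractional counts rounded to integers for MTX output")
    scipy.io.mmwrite(mtx_path, coo, field="integer")
    # mmwrite may append .mtx; normalize
    if not os.path.exists(mtx_path) and os.path.exists(mtx_path + ".mtx"):
        os.rename(mtx_path + ".mtx", mtx_path)
    feat_path = os.path.join(out_dir, "features.tsv")
    with open(feat_path, "w") as fh:
        for f in matrix.features:
            sub = matrix.feature_meta.get(f, f)
            fh.write(f"{f}\t{sub}\tTE\n")
    bc_path = os.path.join(out_dir, "barcodes.tsv")
    with open(bc_path, "w") as fh:
        for b in matrix.barcodes:
            fh.write(b + "\n")
    return {"matrix": mtx_path, "features": feat_path, "barcodes": bc_path}


def read_mtx(out_dir: str) -> UMICountMatrix:
    """Read back a matrix written by :func:`write_mtx` (lossless round-trip)."""
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(out_dir, "matrix.mtx")))
    with open(os.path.join(out_dir, "features.tsv")) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    features = [r[0] for r in rows]
    meta = {r[0]: r[1] for r in rows if len(r) > 1}
    with open(os.path.join(out_dir, "barcodes.tsv")) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    return UMICountMatrix(
        features=features, barcodes=barcodes, counts=counts, feature_meta=meta
    )
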