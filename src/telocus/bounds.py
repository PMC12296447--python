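"""Feasibility bounds on true UMI counts, computed directly from the raw
alignments, and classification of count estimates against them.

Upper bound: number of distinct (cell barcode, UMI) pairs having at least one
alignment overlapping a TE locus at the configured overlap fraction.  Lower
bound: the same, restricted to uniquely aligned reads (NH == 1).  Bounds are
reported per sample, per cell, or per locus; at locus scope a multimapped UMI
counts toward every locus it could overlap (upper) and none (lower).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping

from .annotation import IntervalIndex
from .ingest import AlignmentRecord

__all__ = ["BoundsReport", "EvaluationReport", "compute_bounds", "evaluate_estimates"]

SCOPES = ("sample", "cell", "locus")
SAMPLE_KEY = "__sample__"


@dataclass
class BoundsReport:
    scope: str
    rows: dict[str, tuple[int, int]]  # key -> (lower, upper)

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        for key, (lo, hi) in self.rows.items():
            if not (0 <= lo <= hi):
                raise ValueError(f"{key}: invalid bounds ({lo}, {hi})")

    def to_tsv(self, out_stream: IO[str]) -> None:
        out_stream.write("key\tlower_bound\tupper_bound\n")
        for key in sorted(self.rows):
            lo, hi = self.rows[key]
            out_stream.write(f"{key}\t{lo}\t{hi}\n")


@dataclass
class EvaluationReport:
    scope: str
    labels: dict[str, tuple[float, int, int, str]]  # key -> (est, lo, hi, label)
    fraction_below: float
    fraction_within: float
    fraction_above: float

    def to_tsv(self, out_stream: IO[str]) -> None:
        out_stream.write("key\testimate\tlower_bound\tupper_bound\tlabel\n")
        for key in sorted(self.labels):
            est, lo, hi, lab = self.labels[key]
            out_stream.write(f"{key}\t{est:g}\t{lo}\t{hi}\t{lab}\n")
        out_stream.write(
            f"#summary\tbelow={self.fraction_below:.6f}\t"
            f"within={self.fraction_within:.6f}\tabove={self.fraction_above:.6f}\n"
        )


def compute_bounds(
    read_groups: Iterable[tuple[str, list[AlignmentRecord]]],
    index: IntervalIndex,
    min_overlap: float = 0.2,
    scope: str = "sample",
) -> BoundsReport:
    """Distinct-UMI feasibility bounds at the given overlap criterion.

    ``read_groups`` must be the same filtered, name-grouped alignments that
    feed the weight matrix, so the bounds are computed on the pipeline's own
    input.  Uniqueness of a fragment is NH == 1 on its alignments.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    upper: dict[str, set[tuple[str, str]]] = {}
    lower: dict[str, set[tuple[str, str]]] = {}

    def _add(bucket: dict[str, set], key: str, cb: str, umi: str) -> None:
        bucket.setdefault(key, set()).add((cb, umi))

    for _name, alns in read_groups:
        cb = alns[0].cell_barcode
        umi = alns[0].umi
        unique = all(r.n_hits == 1 for r in alns) and len(alns) == 1
        hit_loci: set[str] = set()
        for rec in alns:
            span = rec.end - rec.start
            for lid, ov in index.query_overlaps(rec.chrom, rec.start, rec.end).items():
                if ov > 0 and ov / span >= min_overlap:
                    hit_loci.add(lid)
        if not hit_loci:
            continue
        if scope == "sample":
            _add(upper, SAMPLE_KEY, cb, umi)
            if unique:
                _add(lower, SAMPLE_KEY, cb, umi)
        elif scope == "cell":
            _add(upper, cb, cb, umi)
            if unique:
                _add(lower, cb, cb, umi)
        else:  # locus
            for lid in hit_loci:
                _add(upper, lid, cb, umi)
            if unique:
                # a unique fragment has exactly one locus candidate
                for lid in hit_loci:
                    _add(lower, lid, cb, umi)

    keys = set(upper) | set(lower)
    if scope == "sample":
        keys.add(SAMPLE_KEY)
    rows = {
        k: (len(lower.get(k, ())), len(upper.get(k, ()))) for k in keys
    }
    return BoundsReport(scope=scope, rows=rows)


def evaluate_estimates(
    estimates: Mapping[str, float], bounds: BoundsReport
) -> EvaluationReport:
    """Label each estimate below/within/above its feasibility interval.

    Keys missing from the bounds are treated as (0, 0) with a warning; keys
    in the bounds but absent from the estimates are evaluated at 0.
    """
    import logging

    logger = logging.getLogger(__name__)
    labels: dict[str, tuple[float, int, int, str]] = {}
    keys = set(estimates) | set(bounds.rows)
    for key in keys:
        if key not in bounds.rows:
            logger.warning("estimate key %r has no bounds; using (0, 0)", key)
            lo, hi = 0, 0
        else:
            lo, hi = bounds.rows[key]
        est = float(estimates.get(key, 0.0))
        if est < lo:
            lab = "below"
        elif est > hi:
            lab = "above"
        else:
            lab = "within"
        labels[key] = (est, lo, hi, lab)
    n = len(labels)
    if n == 0:
        return EvaluationReport("sample", {}, 0.0, 0.0, 0.0)
    counts = {"below": 0, "within": 0, "above": 0}
    for _, _, _, lab in labels.values():
        counts[lab] += 1
    return EvaluationReport(
        scope=bounds.scope,
        labels=labels,
        fraction_below=counts["below"] / n,
        fraction_within=counts["within"] / n,
        fraction_above=counts["above"] / n,
    )
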