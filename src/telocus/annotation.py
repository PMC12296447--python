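"""Locus-level TE annotation: GTF parsing, interval indexing, subfamily lookups.

Coordinates are 1-based closed in GTF; internally every interval is stored
0-based half-open so overlap lengths are simple differences.  Strand is parsed
and kept but ignored for overlap queries (droplet protocols are quantified
unstranded here).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

__all__ = [
    "TELocus",
    "TEAnnotation",
    "IntervalIndex",
    "GTFParseError",
    "load_te_annotation",
    "write_gtf",
    "build_interval_index",
    "subfamily_members",
]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GTFParseError(ValueError):
    """Raised for malformed GTF input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class TELocus:
    """One TE insertion: a set of merged exonic intervals on one chromosome.

    ``intervals`` are 0-based half-open, sorted, and non-overlapping.
    """

    locus_id: str
    subfamily: str
    chrom: str
    intervals: list[tuple[int, int]]
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"locus {self.locus_id}: empty interval list")
        self.intervals = _merge_intervals(self.intervals)

    @property
    def span(self) -> tuple[int, int]:
        return (self.intervals[0][0], self.intervals[-1][1])

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class TEAnnotation:
    loci: list[TELocus]
    subfamily_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate locus_id(s): {dupes}")
        if not self.subfamily_of:
            self.subfamily_of = {loc.locus_id: loc.subfamily for loc in self.loci}
        self._by_id = {loc.locus_id: loc for loc in self.loci}

    @property
    def K(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def __getitem__(self, locus_id: str) -> TELocus:
        return self._by_id[locus_id]

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    @property
    def subfamilies(self) -> list[str]:
        seen: dict[str, None] = {}
        for loc in self.loci:
            seen.setdefault(loc.subfamily)
        return list(seen)


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if s > e:
            raise ValueError(f"interval start > end: ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def load_te_annotation(
    gtf_stream: IO[str] | Iterable[str],
    feature_attribute: str = "locus",
) -> TEAnnotation:
    """Parse GTF rows, grouping rows by ``feature_attribute`` into loci.

    Falls back to ``gene_id`` when the configured attribute is missing on a
    row.  Rows sharing the grouping value are merged into a single multi-exon
    locus; a locus spanning two chromosomes is an error.
    """
    raw: dict[str, dict] = {}
    n_rows = 0
    for lineno, line in enumerate(gtf_stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GTFParseError(
                f"expected 9 tab-separated columns, got {len(fields)}", lineno
            )
        chrom, _source, _feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
        try:
            start = int(start_s)
            end = int(end_s)
        except ValueError:
            raise GTFParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno)
        if start < 1 or end < start:
            raise GTFParseError(f"bad coordinate range {start}-{end}", lineno)
        attrs = _parse_attributes(attrs_s)
        locus_id = attrs.get(feature_attribute) or attrs.get("gene_id")
        if locus_id is None:
            raise GTFParseError(
                f"missing grouping attribute {feature_attribute!r} (and gene_id fallback)",
                lineno,
            )
        subfam = attrs.get("subfamily") or attrs.get("family") or locus_id
        entry = raw.setdefault(
            locus_id,
            {"chrom": chrom, "strand": strand, "subfamily": subfam, "intervals": []},
        )
        if entry["chrom"] != chrom:
            raise GTFParseError(
                f"locus {locus_id!r} appears on both {entry['chrom']!r} and {chrom!r}",
                lineno,
            )
        # GTF is 1-based closed; store 0-based half-open.
        entry["intervals"].append((start - 1, end))
        n_rows += 1
    if n_rows == 0:
        raise GTFParseError("no features parsed")
    loci = [
        TELocus(
            locus_id=lid,
            subfamily=e["subfamily"],
            chrom=e["chrom"],
            intervals=e["intervals"],
            strand=e["strand"],
        )
        for lid, e in raw.items()
    ]
    return TEAnnotation(loci=loci)


def write_gtf(annotation: TEAnnotation, out_stream: IO[str], source: str = "telocus") -> None:
    """Serialize an annotation back to GTF (1-based closed coordinates)."""
    for loc in annotation.loci:
        for s, e in loc.intervals:
            attrs = f'locus "{loc.locus_id}"; subfamily "{loc.subfamily}"; gene_id "{loc.locus_id}";'
            out_stream.write(
                "\t".join(
                    [
                        loc.chrom,
                        source,
                        "exon",
                        str(s + 1),
                        str(e),
                        ".",
                        loc.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


class IntervalIndex:
    """Per-chromosome overlap index over annotation intervals.

    Intervals per chromosome are kept as parallel sorted start/end arrays; a
    query binary-searches on start and filters by end.  Overlapping loci are
    tolerated: every intersecting locus is reported.
    """

    def __init__(self, annotation: TEAnnotation):
        self.annotation = annotation
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]] = {}
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for loc in annotation.loci:
            for s, e in loc.intervals:
                per_chrom.setdefault(loc.chrom, []).append((s, e, loc.locus_id))
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            # running max of ends lets us bound the left scan
            maxend = np.maximum.accumulate(ends)
            ids = [lid for _, _, lid in ivs]
            self._chrom[chrom] = (starts, ends, maxend, ids)

    def query(self, chrom: str, start: int, end: int) -> set[str]:
        """Locus ids whose intervals intersect [start, end) (0-based half-open)."""
        if chrom not in self._chrom or end <= start:
            return set()
        starts, ends, maxend, ids = self._chrom[chrom]
        hi = int(np.searchsorted(starts, end, side="left"))
        hits: set[str] = set()
        for i in range(hi - 1, -1, -1):
            if maxend[i] <= start:
                break
            if ends[i] > start:
                hits.add(ids[i])
        return hits

    def query_overlaps(self, chrom: str, start: int, end: int) -> dict[str, int]:
        """Map locus_id -> overlapped bases with [start, end) over merged intervals."""
        hits = self.query(chrom, start, end)
        out: dict[str, int] = {}
        for lid in hits:
            loc = self.annotation[lid]
            ov = 0
            for s, e in loc.intervals:
                ov += max(0, min(e, end) - max(s, start))
            if ov > 0:
                out[lid] = ov
        return out


def build_interval_index(annotation: TEAnnotation) -> IntervalIndex:
    return IntervalIndex(annotation)


def subfamily_members(annotation: TEAnnotation, subfamily: str) -> list[str]:
    """All locus ids belonging to ``subfamily`` (annotation order)."""
    return [loc.locus_id for loc in annotation.loci if loc.subfamily == subfamily]


def write_features_tsv(annotation: TEAnnotation, out_stream: IO[str]) -> None:
    """Feature table used alongside MTX output: id, subfamily, chrom, span."""
    for loc in annotation.loci:
        s, e = loc.span
        out_stream.write(f"{loc.locus_id}\t{loc.subfamily}\t{loc.chrom}\t{s + 1}-{e}\n")
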