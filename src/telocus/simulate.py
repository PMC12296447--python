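"""Alignment-level scRNA-seq fixture generator with known ground truth.

Simulation starts at the alignment level (the pipeline's input is an
alignment file): barcoded, UMI-tagged reads with PCR duplicates sharing
CB+UMI, multimapped reads whose decoy loci are drawn from the same subfamily
with reduced alignment scores, optional canonical-gene (GX) overlap, and
reads falling outside the annotation.  Fixed seed gives byte-identical SAM
text and ground truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import TEAnnotation, TELocus, write_gtf

__all__ = ["SimulationConfig", "GroundTruth", "simulate_annotation", "simulate_reads"]

READ_LENGTH = 90
LOCUS_LENGTH = 1000
LOCUS_SPACING = 3000
TRUE_ALIGNMENT_SCORE = 50
NULL_CHROM = "chrNULL"
NULL_CHROM_LEN = 1_000_000


@dataclass
class SimulationConfig:
    n_loci: int = 20
    n_subfamilies: int = 4
    n_cells: int = 20
    n_pools: int = 1
    pool_labels: list[str] | None = None  # label per cell; overrides n_pools
    pi_truth: np.ndarray | None = None  # (n_pools, n_loci), rows sum to 1
    mean_fragments_per_cell: float = 100.0
    ambiguous_fraction: float = 0.4
    max_decoys_per_read: int = 3
    score_gap_range: tuple[int, int] = (0, 5)
    duplication_rate: float = 0.3  # expected extra PCR copies per molecule
    umi_length: int = 12
    gx_rate: float = 0.0
    no_feature_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < self.n_subfamilies or self.n_subfamilies < 1:
            raise ValueError("need n_loci >= n_subfamilies >= 1")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        for name in ("ambiguous_fraction", "gx_rate", "no_feature_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.duplication_rate < 0:
            raise ValueError("duplication_rate must be >= 0")
        lo, hi = self.score_gap_range
        if lo < 0 or hi < lo:
            raise ValueError("score_gap_range must satisfy 0 <= lo <= hi")
        if self.pool_labels is not None:
            if len(self.pool_labels) != self.n_cells:
                raise ValueError("pool_labels must have one label per cell")
            self.n_pools = len(dict.fromkeys(self.pool_labels))
        if self.pi_truth is not None:
            self.pi_truth = np.asarray(self.pi_truth, dtype=float)
            if self.pi_truth.shape != (self.n_pools, self.n_loci):
                raise ValueError("pi_truth must have shape (n_pools, n_loci)")
            if not np.allclose(self.pi_truth.sum(axis=1), 1.0):
                raise ValueError("pi_truth rows must sum to 1")


@dataclass
class GroundTruth:
    barcodes: list[str]
    labels: dict[str, str]  # barcode -> pool label
    locus_ids: list[str]
    pi_truth: np.ndarray  # (n_pools, n_loci)
    pool_ids: list[str]
    molecules: list[tuple[str, str | None, str]]  # (barcode, locus or None, umi)
    true_counts: np.ndarray  # (n_loci, n_cells) TE molecules only
    read_truth: dict[str, str | None] = field(default_factory=dict)

    @property
    def n_te_molecules(self) -> int:
        return int(self.true_counts.sum())


def simulate_annotation(config: SimulationConfig) -> TEAnnotation:
    """Synthetic single-exon loci on one chromosome, grouped into subfamilies
    in contiguous blocks (decoy draws stay within subfamily)."""
    loci: list[TELocus] = []
    # spread subfamily sizes as evenly as possible
    base = config.n_loci // config.n_subfamilies
    extra = config.n_loci % config.n_subfamilies
    idx = 0
    for s in range(config.n_subfamilies):
        size = base + (1 if s < extra else 0)
        subfam = f"SF{s + 1}"
        for _ in range(size):
            start = idx * LOCUS_SPACING + 1000
            loci.append(
                TELocus(
                    locus_id=f"{subfam}_L{idx + 1}",
                    subfamily=subfam,
                    chrom="chrT1",
                    intervals=[(start, start + LOCUS_LENGTH)],
                    strand="+",
                )
            )
            idx += 1
    return TEAnnotation(loci=loci)


def annotation_gtf_text(annotation: TEAnnotation) -> str:
    buf = io.StringIO()
    write_gtf(annotation, buf)
    return buf.getvalue()


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _n_copies(rng: np.random.Generator, duplication_rate: float) -> int:
    """1 + Geometric number of extra PCR copies with mean == duplication_rate."""
    if duplication_rate == 0:
        return 1
    p = 1.0 / (1.0 + duplication_rate)
    return int(rng.geometric(p))  # support >= 1, mean 1 + duplication_rate


def simulate_reads(
    config: SimulationConfig, annotation: TEAnnotation
) -> tuple[str, GroundTruth]:
    """Emit SAM text (CB/UB/AS/NH and optional GX tags) plus ground truth.

    Every emitted read's candidate set contains its true locus; the true
    alignment keeps the top score and decoys are penalized by a draw from
    ``score_gap_range``.
    """
    rng = np.random.default_rng(config.seed)
    locus_ids = annotation.locus_ids
    if len(locus_ids) != config.n_loci:
        raise ValueError("annotation does not match config.n_loci")

    barcodes = sorted({_random_seq(rng, 16) for _ in range(config.n_cells)})
    while len(barcodes) < config.n_cells:  # barcode collision: redraw
        barcodes = sorted(set(barcodes) | {_random_seq(rng, 16)})

    if config.pool_labels is not None:
        labels = {b: config.pool_labels[i] for i, b in enumerate(barcodes)}
    else:
        labels = {
            b: f"type{(i % config.n_pools) + 1}" for i, b in enumerate(barcodes)
        }
    pool_ids = list(dict.fromkeys(labels[b] for b in barcodes))
    pool_of = {b: pool_ids.index(labels[b]) for b in barcodes}

    if config.pi_truth is not None:
        pi_truth = config.pi_truth
    else:
        pi_truth = rng.dirichlet(np.ones(config.n_loci), size=len(pool_ids))

    members: dict[str, list[str]] = {}
    for lid in locus_ids:
        members.setdefault(annotation.subfamily_of[lid], []).append(lid)
    locus_index = {lid: j for j, lid in enumerate(locus_ids)}

    lines: list[str] = []
    chrom_len = config.n_loci * LOCUS_SPACING + 2 * LOCUS_LENGTH + 1000
    lines.append("@HD\tVN:1.6\tSO:unknown")
    lines.append(f"@SQ\tSN:chrT1\tLN:{chrom_len}")
    lines.append(f"@SQ\tSN:{NULL_CHROM}\tLN:{NULL_CHROM_LEN}")

    molecules: list[tuple[str, str | None, str]] = []
    true_counts = np.zeros((config.n_loci, config.n_cells), dtype=np.int64)
    read_truth: dict[str, str | None] = {}
    read_counter = 0

    def _pos_in(locus: TELocus) -> int:
        s, e = locus.span
        return int(rng.integers(s, e - READ_LENGTH + 1))

    for ci, cb in enumerate(barcodes):
        n_mol = int(rng.poisson(config.mean_fragments_per_cell))
        for _ in range(n_mol):
            umi = _random_seq(rng, config.umi_length)
            if rng.random() < config.no_feature_rate:
                true_locus: str | None = None
            else:
                j = int(rng.choice(config.n_loci, p=pi_truth[pool_of[cb]]))
                true_locus = locus_ids[j]
                true_counts[j, ci] += 1
            molecules.append((cb, true_locus, umi))
            gx = true_locus is not None and rng.random() < config.gx_rate
            for _copy in range(_n_copies(rng, config.duplication_rate)):
                read_counter += 1
                name = f"read{read_counter:08d}"
                read_truth[name] = true_locus
                if true_locus is None:
                    pos = int(rng.integers(0, NULL_CHROM_LEN - READ_LENGTH))
                    alns = [(NULL_CHROM, pos, TRUE_ALIGNMENT_SCORE)]
                else:
                    loc = annotation[true_locus]
                    alns = [(loc.chrom, _pos_in(loc), TRUE_ALIGNMENT_SCORE)]
                    pool_mates = [
                        m
                        for m in members[annotation.subfamily_of[true_locus]]
                        if m != true_locus
                    ]
                    if pool_mates and rng.random() < config.ambiguous_fraction:
                        n_dec = int(
                            rng.integers(
                                1, min(config.max_decoys_per_read, len(pool_mates)) + 1
                            )
                        )
                        decoys = rng.choice(len(pool_mates), size=n_dec, replace=False)
                        lo, hi = config.score_gap_range
                        for di in decoys:
                            dloc = annotation[pool_mates[int(di)]]
                            gap = int(rng.integers(lo, hi + 1))
                            alns.append(
                                (dloc.chrom, _pos_in(dloc), TRUE_ALIGNMENT_SCORE - gap)
                            )
                nh = len(alns)
                for ai, (chrom, pos, score) in enumerate(alns):
                    flag = 0 if ai == 0 else 256
                    mapq = 255 if nh == 1 else 3
                    tags = [
                        f"NH:i:{nh}",
                        f"AS:i:{score}",
                        f"CB:Z:{cb}",
                        f"UB:Z:{umi}",
                    ]
                    if gx and ai == 0:
                        tags.append("GX:Z:GENE1")
                    lines.append(
                        "\t".join(
                            [
                                name,
                                str(flag),
                                chrom,
                                str(pos + 1),
                                str(mapq),
                                f"{READ_LENGTH}M",
                                "*",
                                "0",
                                "0",
                                "*",
                                "*",
                            ]
                            + tags
                        )
                    )

    sam_text = "\n".join(lines) + "\n"
    truth = GroundTruth(
        barcodes=barcodes,
        labels=labels,
        locus_ids=list(locus_ids),
        pi_truth=pi_truth,
        pool_ids=pool_ids,
        molecules=molecules,
        true_counts=true_counts,
        read_truth=read_truth,
    )
    return sam_text, truth


def whitelist_text(truth: GroundTruth) -> str:
    return "\n".join(truth.barcodes) + "\n"


def labels_text(truth: GroundTruth) -> str:
    return "".join(f"{b}\t{truth.labels[b]}\n" for b in truth.barcodes)


def truth_counts_mtx_text(truth: GroundTruth) -> str:
    """Ground-truth molecule counts as MatrixMarket coordinate text."""
    rows, cols = np.nonzero(truth.true_counts)
    out = ["%%MatrixMarket matrix coordinate integer general"]
    out.append(f"{truth.true_counts.shape[0]} {truth.true_counts.shape[1]} {len(rows)}")
    for r, c in zip(rows, cols):
        out.append(f"{r + 1} {c + 1} {truth.true_counts[r, c]}")
    return "\n".join(out) + "\n"
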