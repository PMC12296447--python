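"""Multimapper-aware UMI deduplication.

Fragments sharing a (cell barcode, UMI) key are binned; within a bin an
undirected graph connects fragments whose candidate locus sets intersect
(the NO_FEATURE column never creates an edge).  Each connected component is
one molecule: its most informative fragment is retained as the
representative and the rest are removed as PCR duplicates.  A bin with
multiple components is kept as multiple molecules (UMI collision).

Representative selection (the original criterion is unspecified): highest
best-alignment score, then fewest candidate loci, then lexicographically
smallest read name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

import networkx as nx
import numpy as np

from .ingest import WeightMatrix

__all__ = [
    "UMIGroup",
    "DuplicateComponent",
    "DedupReport",
    "group_by_barcode_umi",
    "build_umi_graph",
    "components_and_representatives",
    "deduplicate",
]


@dataclass
class UMIGroup:
    key: tuple[str, str]
    members: list[int]


@dataclass
class DuplicateComponent:
    fragments: frozenset[int]
    representative: int

    def __post_init__(self) -> None:
        if self.representative not in self.fragments:
            raise ValueError("representative not in component")


@dataclass
class DedupReport:
    fragments_in: int = 0
    fragments_out: int = 0
    n_groups: int = 0
    n_components: int = 0
    duplicates_removed: int = 0
    # group size -> total components seen over groups of that size
    group_histogram: dict[int, int] = field(default_factory=dict)

    def to_tsv(self, out_stream: IO[str]) -> None:
        for k in ("fragments_in", "fragments_out", "n_groups", "n_components", "duplicates_removed"):
            out_stream.write(f"{k}\t{getattr(self, k)}\n")
        for size in sorted(self.group_histogram):
            out_stream.write(f"group_size_{size}_components\t{self.group_histogram[size]}\n")


def group_by_barcode_umi(matrix: WeightMatrix) -> list[UMIGroup]:
    """Partition matrix rows by (CB, UB); singleton groups allowed."""
    bins: dict[tuple[str, str], list[int]] = {}
    for i in range(matrix.n_fragments):
        bins.setdefault((matrix.barcodes[i], matrix.umis[i]), []).append(i)
    return [UMIGroup(key=k, members=v) for k, v in sorted(bins.items())]


def build_umi_graph(group: UMIGroup, matrix: WeightMatrix) -> nx.Graph:
    """Node per fragment; edge where candidate locus sets intersect.

    Edge weight = number of shared loci.  O(members x loci) via a
    locus -> fragments inverted index rather than all-pairs set intersection.
    """
    if not group.members:
        raise ValueError("empty UMI group")
    g = nx.Graph()
    g.add_nodes_from(group.members)
    by_locus: dict[int, list[int]] = {}
    for i in group.members:
        for j in matrix.row_locus_set(i):
            by_locus.setdefault(j, []).append(i)
    shared: dict[tuple[int, int], int] = {}
    for frags in by_locus.values():
        for a_idx in range(len(frags)):
            for b_idx in range(a_idx + 1, len(frags)):
                e = (frags[a_idx], frags[b_idx])
                shared[e] = shared.get(e, 0) + 1
    for (u, v), w in shared.items():
        g.add_edge(u, v, weight=w)
    return g


def _representative(component: set[int], matrix: WeightMatrix) -> int:
    """Highest best score, then fewest candidate loci, then smallest name."""
    return min(
        component,
        key=lambda i: (
            -matrix.best_score[i],
            len(matrix.row_locus_set(i)),
            matrix.read_names[i],
        ),
    )


def components_and_representatives(
    graph: nx.Graph, matrix: WeightMatrix
) -> list[DuplicateComponent]:
    comps = []
    for nodes in nx.connected_components(graph):
        rep = _representative(nodes, matrix)
        comps.append(DuplicateComponent(fragments=frozenset(nodes), representative=rep))
    comps.sort(key=lambda c: min(c.fragments))
    return comps


def deduplicate(matrix: WeightMatrix) -> tuple[WeightMatrix, DedupReport]:
    """Remove PCR duplicates; retained rows are component representatives."""
    report = DedupReport(fragments_in=matrix.n_fragments)
    keep: list[int] = []
    groups = group_by_barcode_umi(matrix)
    report.n_groups = len(groups)
    for group in groups:
        if len(group.members) == 1:
            comps = [
                DuplicateComponent(
                    fragments=frozenset(group.members),
                    representative=group.members[0],
                )
            ]
        else:
            graph = build_umi_graph(group, matrix)
            comps = components_and_representatives(graph, matrix)
        report.n_components += len(comps)
        size = len(group.members)
        report.group_histogram[size] = report.group_histogram.get(size, 0) + len(comps)
        keep.extend(c.representative for c in comps)
    keep_arr = np.array(sorted(keep), dtype=np.int64)
    out = matrix.subset_rows(keep_arr)
    report.fragments_out = len(keep_arr)
    report.duplicates_removed = report.fragments_in - report.fragments_out
    return out, report
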