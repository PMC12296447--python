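import numpy as np
import pytest
import scipy.sparse as sp

from telocus.annotation import TEAnnotation, TELocus
from telocus.ingest import NO_FEATURE, WeightMatrix


def make_weight_matrix(rows, n_loci=None, barcodes=None, umis=None, gx=None, scores=None):
    """Build a WeightMatrix from a list of {feature_name: weight} dicts.

    Feature names: "NF" for the NO_FEATURE column, anything else is a locus.
    Row max is rescaled to 1 if needed; y is derived from the locus count.
    """
    locus_names = []
    for row in rows:
        for f in row:
            if f != "NF" and f not in locus_names:
                locus_names.append(f)
    if n_loci is not None:
        while len(locus_names) < n_loci:
            locus_names.append(f"pad{len(locus_names)}")
    feature_ids = [NO_FEATURE] + locus_names
    col = {"NF": 0, **{f: j + 1 for j, f in enumerate(locus_names)}}
    n = len(rows)
    dense = np.zeros((n, len(feature_ids)))
    ys = np.zeros(n, dtype=np.int8)
    for i, row in enumerate(rows):
        mx = max(row.values())
        for f, w in row.items():
            dense[i, col[f]] = w / mx
        ys[i] = 1 if sum(1 for f in row if f != "NF") >= 2 else 0
    return WeightMatrix(
        weights=sp.csr_matrix(dense),
        feature_ids=feature_ids,
        read_names=np.array([f"r{i:04d}" for i in range(n)], dtype=object),
        barcodes=np.array(
            barcodes if barcodes is not None else ["cellA"] * n, dtype=object
        ),
        umis=np.array(umis if umis is not None else [f"u{i}" for i in range(n)], dtype=object),
        ambiguous=ys,
        gx=np.array(gx if gx is not None else [False] * n, dtype=bool),
        best_score=np.array(scores if scores is not None else [50.0] * n, dtype=float),
    )


def random_weight_matrix(rng, n_frag, n_loci, n_cells=1, nf_rate=0.2, max_cand=4):
    """Random valid WeightMatrix for property tests."""
    rows = []
    barcodes = []
    for _ in range(n_frag):
        k = int(rng.integers(1, min(max_cand, n_loci) + 1))
        cols = rng.choice(n_loci, size=k, replace=False)
        row = {f"L{c}": float(w) for c, w in zip(cols, rng.random(k) * 0.9 + 0.1)}
        if rng.random() < nf_rate:
            row["NF"] = float(rng.random() * 0.5 + 0.1)
        rows.append(row)
        barcodes.append(f"cell{int(rng.integers(n_cells))}")
    return make_weight_matrix(rows, n_loci=n_loci, barcodes=barcodes)


@pytest.fixture
def toy_annotation():
    return TEAnnotation(
        loci=[
            TELocus("L1", "HERVH", "chr1", [(1000, 2000)], "+"),
            TELocus("L2", "HERVH", "chr1", [(5000, 6000)], "-"),
            TELocus("L3", "MER4", "chr2", [(100, 400), (700, 900)], "+"),
        ]
    )


def write_sim_dataset(tmp_path, config):
    """Run the simulator and write its artifacts; returns (paths dict, truth, annotation)."""
    from telocus.simulate import (
        annotation_gtf_text,
        labels_text,
        simulate_annotation,
        simulate_reads,
        whitelist_text,
    )

    annotation = simulate_annotation(config)
    sam_text, truth = simulate_reads(config, annotation)
    paths = {}
    for name, text in [
        ("reads.sam", sam_text),
        ("annotation.gtf", annotation_gtf_text(annotation)),
        ("whitelist.txt", whitelist_text(truth)),
        ("labels.tsv", labels_text(truth)),
    ]:
        p = tmp_path / name
        p.write_text(text)
        paths[name.split(".")[0]] = str(p)
    return paths, truth, annotation
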