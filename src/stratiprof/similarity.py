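"""Whole-metagenome similarity by reciprocal read matching, plus clustering.

Two samples are compared by the fraction of reads of one that have a
qualifying match (>= 95% identity over >= 50 overlapping bases) among the
reads of the other, computed reciprocally on seeded subsets and averaged.
The similarity matrix is turned into a dendrogram by agglomerative
clustering (complete linkage by default) on euclidean distances between
similarity rows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import SampleReadSet
from .overlap import OverlapMatcher


def _subset(reads: list[str], size: int, rng: np.random.Generator) -> list[str]:
    if len(reads) <= size:
        if len(reads) < size:
            warnings.warn(f"subset {size} exceeds available reads ({len(reads)}); using all")
        return list(reads)
    idx = rng.choice(len(reads), size=size, replace=False)
    return [reads[i] for i in idx]


def reciprocal_similarity(
    readset_a: SampleReadSet,
    readset_b: SampleReadSet,
    subset_size: int = 2_000_000,
    min_len: int = 50,
    min_identity: float = 95.0,
    seed: int = 0,
) -> tuple[float, float, float]:
    """(s_AB, s_BA, mean): fractions of subset reads with a reciprocal match.

    Reads shorter than ``min_len`` are excluded before subsetting; subsets
    are drawn with a seeded generator.
    """
    a = [r for r in readset_a.reads if len(r) >= min_len]
    b = [r for r in readset_b.reads if len(r) >= min_len]
    if not a or not b:
        raise ValueError("both read sets must be non-empty after length filtering")
    rng = np.random.default_rng(seed)
    a = _subset(a, subset_size, rng)
    b = _subset(b, subset_size, rng)

    def frac(queries: list[str], targets: list[str]) -> float:
        m = OverlapMatcher([(f"t{i}", s) for i, s in enumerate(targets)])
        hits = sum(m.has_match(q, min_len, min_identity) for q in queries)
        return hits / len(queries)

    s_ab = frac(a, b)
    s_ba = frac(b, a)
    return s_ab, s_ba, 0.5 * (s_ab + s_ba)


def similarity_matrix(
    samples: list[SampleReadSet],
    subset_size: int = 2_000_000,
    min_len: int = 50,
    min_identity: float = 95.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Symmetric mean reciprocal-similarity matrix over all sample pairs."""
    ids = [s.sample_id for s in samples]
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            _, _, mean = reciprocal_similarity(
                samples[i], samples[j], subset_size, min_len, min_identity,
                seed=seed + 1000 * i + j,
            )
            mat.iloc[i, j] = mat.iloc[j, i] = mean
    return mat


def cluster_samples(
    similarity: pd.DataFrame, linkage_method: str = "complete"
) -> tuple[np.ndarray, str]:
    """Cluster samples on euclidean distances between similarity rows.

    Returns the scipy linkage matrix and a newick string with branch
    lengths.  Deterministic for a fixed input (sorted by sample id first,
    so the tree is invariant to input row order).
    """
    if similarity.shape[0] != similarity.shape[1]:
        raise ValueError("similarity matrix must be square")
    sim = similarity.sort_index(axis=0).sort_index(axis=1)
    d = pdist(sim.to_numpy(), metric="euclidean")
    Z = hierarchy.linkage(d, method=linkage_method)
    tree = hierarchy.to_tree(Z)
    labels = list(sim.index)

    def newick(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return Z, f"({newick(tree.left, tree.dist)},{newick(tree.right, tree.dist)});"


def join_order(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    """Merged leaf sets in join order (for topology assertions)."""
    clusters: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(len(labels))}
    merges = []
    for m, (a, b, _, _) in enumerate(Z):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[len(labels) + m] = merged
        merges.append(merged)
    return merges
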