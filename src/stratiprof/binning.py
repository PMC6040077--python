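"""Composition-based contig binning and marker-set completeness.

Contigs are featurized by canonical tetranucleotide frequencies (reverse
complement collapsed, 136 keys), GC, and log-coverage; features are
projected by PCA and clustered density-based (DBSCAN) within taxon groups
— an automatic analogue of interactive PCA-plot binning.  Bin quality is
scored against universal single-copy marker catalogs: completeness is the
fraction of catalog families present, contamination the rate of extra
copies beyond the first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

from .core_io import GenomeRecord, gc_content, reverse_complement

UNCLASSIFIED = "unclassified"


def contig_taxonomy(
    gene_taxa: list[str], contig_length: int, min_length: int = 10_000
) -> str:
    """Majority taxon of a contig's genes, iff strictly > 50% agree.

    Contigs shorter than ``min_length`` or without annotated genes are
    unclassified.
    """
    if contig_length < min_length or not gene_taxa:
        return UNCLASSIFIED
    vc = pd.Series(gene_taxa).value_counts()
    if vc.iloc[0] * 2 > len(gene_taxa):
        return str(vc.index[0])
    return UNCLASSIFIED


def _canonical_keys() -> list[str]:
    keys = []
    seen = set()
    for tup in product("ACGT", repeat=4):
        kmer = "".join(tup)
        canon = min(kmer, reverse_complement(kmer))
        if canon not in seen:
            seen.add(canon)
            keys.append(canon)
    return keys


TNF_KEYS: list[str] = _canonical_keys()  # 136 canonical tetranucleotides
_TNF_POS = {k: i for i, k in enumerate(TNF_KEYS)}
_CANON = {
    "".join(t): _TNF_POS[min("".join(t), reverse_complement("".join(t)))]
    for t in product("ACGT", repeat=4)
}


def tnf(sequence: str) -> np.ndarray:
    """Canonical tetranucleotide frequency vector (sums to 1).

    Sliding 4-mers at step 1; 4-mers containing N are skipped; a 4-mer and
    its reverse complement share one canonical key.
    """
    seq = sequence.upper()
    counts = np.zeros(len(TNF_KEYS))
    n = 0
    for i in range(len(seq) - 3):
        pos = _CANON.get(seq[i : i + 4])
        if pos is not None:
            counts[pos] += 1
            n += 1
    if n == 0:
        raise ValueError("no valid 4-mer in sequence")
    return counts / n


def contig_features(
    contigs: list[GenomeRecord],
    coverage: pd.DataFrame | None = None,
    min_length: int = 1_000,
) -> pd.DataFrame:
    """Per-contig feature table: TNF columns, gc, coverage columns.

    ``coverage``: contigs x samples mean depth (optional).  Contigs below
    ``min_length`` are not featurized.
    """
    rows = {}
    for c in contigs:
        if len(c) < min_length:
            continue
        row = dict(zip(TNF_KEYS, tnf(c.sequence)))
        row["gc"] = gc_content(c.sequence)
        row["length_bp"] = len(c)
        rows[c.id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    if coverage is not None:
        cov = coverage.reindex(df.index).fillna(0.0)
        for col in cov.columns:
            df[f"cov_{col}"] = cov[col]
    return df


def project_features(features: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """PCA of standardized TNF plus standardized GC / log10-coverage axes.

    Component signs are fixed (largest-magnitude loading positive) so the
    projection is deterministic.  All returned axes are standardized to
    unit variance.
    """
    if len(features) < 3:
        raise ValueError("need >= 3 contigs")
    tnf_cols = [c for c in TNF_KEYS if c in features.columns]
    X = features[tnf_cols].to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant TNF columns")
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds feature rank")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    out = pd.DataFrame(
        scores, index=features.index,
        columns=[f"PC{j + 1}" for j in range(n_components)],
    )
    extra = {}
    if "gc" in features.columns:
        extra["gc"] = features["gc"].to_numpy(dtype=float)
    for c in features.columns:
        if c.startswith("cov_"):
            extra[c] = np.log10(features[c].to_numpy(dtype=float) + 0.1)
    for name, v in extra.items():
        s = v.std()
        if s == 0:
            warnings.warn(f"dropping constant feature axis {name}")
            continue
        out[name] = (v - v.mean()) / s
    for j in range(n_components):
        col = f"PC{j + 1}"
        s = out[col].std()
        if s > 0:
            out[col] = (out[col] - out[col].mean()) / s
    return out


@dataclass
class BinAssignment:
    """Contig -> bin map plus per-bin summaries."""

    membership: pd.Series  # contig_id -> bin_id ("unbinned" for noise)
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def contigs_of(self, bin_id: str) -> list[str]:
        return list(self.membership.index[self.membership == bin_id])

    @property
    def bin_ids(self) -> list[str]:
        return sorted(b for b in self.membership.unique() if b != "unbinned")


def _adaptive_eps(
    X: np.ndarray, min_pts: int, floor: float = 0.5, factor: float = 2.0
) -> float:
    """Classic k-dist heuristic: eps from the min_pts-th neighbor distance.

    Well-separated clusters have tiny within-cluster spacing (eps stays at
    the floor, separating them); a lone diffuse cluster — whose noise the
    standardization inflated to unit scale — gets a proportionally larger
    radius and is kept whole.  Using the min_pts-th neighbor (not the 1st)
    keeps the estimate meaningful when contigs are duplicated.
    """
    from scipy.spatial.distance import pdist, squareform

    d = np.sort(squareform(pdist(X)), axis=1)  # column 0 is the self-distance
    k = min(min_pts, d.shape[1] - 1)
    return max(floor, factor * float(np.median(d[:, k])))


def bin_contigs(
    coords: pd.DataFrame,
    taxon_labels: pd.Series | None = None,
    eps: float | None = None,
    min_pts: int = 3,
) -> BinAssignment:
    """Density-cluster projected contigs within each taxon group.

    Unclassified contigs form their own group; DBSCAN noise points are
    left unbinned.  With ``eps=None`` the radius is chosen per group by a
    k-distance heuristic (median nearest-neighbor distance).
    """
    if taxon_labels is None:
        taxon_labels = pd.Series(UNCLASSIFIED, index=coords.index)
    taxon_labels = taxon_labels.reindex(coords.index).fillna(UNCLASSIFIED)
    membership = pd.Series("unbinned", index=coords.index, dtype=object)
    b = 0
    for taxon in sorted(taxon_labels.unique()):
        sub = coords.loc[taxon_labels == taxon]
        if len(sub) < min_pts:
            continue
        group_eps = eps if eps is not None else _adaptive_eps(sub.to_numpy(), min_pts)
        labels = DBSCAN(eps=group_eps, min_samples=min_pts).fit_predict(sub.to_numpy())
        for lab in sorted(set(labels) - {-1}):
            b += 1
            membership.loc[sub.index[labels == lab]] = f"bin_{b:03d}"
    return BinAssignment(membership=membership)


def completeness_contamination(
    gene_families: list[str], catalog: list[str]
) -> tuple[float, float]:
    """Marker-set completeness and contamination of one bin, in percent.

    completeness = 100 * distinct catalog families present / |catalog|;
    contamination = 100 * extra copies beyond the first / |catalog|.
    """
    if not catalog:
        raise ValueError("empty marker catalog")
    cat = set(catalog)
    counts = pd.Series([g for g in gene_families if g in cat]).value_counts()
    completeness = 100.0 * len(counts) / len(cat)
    contamination = 100.0 * float((counts - 1).clip(lower=0).sum()) / len(cat)
    return completeness, contamination


def summarize_bins(
    assignment: BinAssignment,
    contigs: list[GenomeRecord],
    catalog: list[str],
    marker_role: str = "marker",
) -> pd.DataFrame:
    """Per-bin total_bp, mean GC, completeness and contamination."""
    by_id = {c.id: c for c in contigs}
    rows = {}
    for bin_id in assignment.bin_ids:
        members = [by_id[cid] for cid in assignment.contigs_of(bin_id) if cid in by_id]
        fams = [g.family for c in members for g in c.genes if g.role == marker_role]
        comp, cont = completeness_contamination(fams, catalog)
        seq_bp = sum(len(c) for c in members)
        gc = (
            sum(gc_content(c.sequence) * len(c) for c in members) / seq_bp
            if seq_bp
            else float("nan")
        )
        rows[bin_id] = {
            "n_contigs": len(members),
            "total_bp": seq_bp,
            "mean_gc": gc,
            "completeness": comp,
            "contamination": cont,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
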