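"""16S/18S fragment detection, verification, classification, diversity.

The cascade mirrors how small-subunit rRNA fragments are pulled out of raw
shotgun reads: a permissive identity screen against a clustered reference
(recall-oriented), a positional-profile verification step that removes
composition look-alikes (precision-oriented, shuffle-calibrated cutoff),
and a final identity/length classification (>= 80% identity over >= 90
aligned bases) that assigns the best centroid's lineage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .core_io import SampleReadSet, reverse_complement
from .references import DomainProfile, domain_profiles, score_fragment


def _infix_identity(read: str, target: str, kmax: int) -> float:
    """Identity percent of the full read placed in the target (-1 if > kmax)."""
    res = edlib.align(read, target, mode="HW", task="distance", k=kmax)
    d = res["editDistance"]
    if d < 0:
        return -1.0
    return 100.0 * (len(read) - d) / len(read)


def global_identity(a: str, b: str) -> float:
    """End-to-end identity percent between two sequences."""
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 100.0 * (max(len(a), len(b)) - d) / max(len(a), len(b))


@dataclass(frozen=True)
class Centroid:
    sequence: str
    taxonomy: tuple[str, ...]


@dataclass
class Reference16S:
    """Greedy identity-clustered rRNA reference."""

    centroids: list[Centroid]
    radius: float

    def __len__(self) -> int:
        return len(self.centroids)


def build_reference(
    sequences_with_taxonomy: list[tuple[str, tuple[str, ...]]], radius: float = 0.90
) -> Reference16S:
    """Greedy centroid clustering in input order at the given identity radius.

    Each input joins the first centroid it matches at >= radius identity,
    otherwise it becomes a new centroid.  Every input must carry taxonomy.
    """
    if not sequences_with_taxonomy:
        raise ValueError("at least one labeled sequence required")
    centroids: list[Centroid] = []
    for seq, tax in sequences_with_taxonomy:
        if not tax:
            raise ValueError("unlabeled sequence in reference input")
        seq = seq.upper()
        for c in centroids:
            if global_identity(seq, c.sequence) >= 100.0 * radius:
                break
        else:
            centroids.append(Centroid(seq, tuple(tax)))
    return Reference16S(centroids, radius)


def detect_candidates(
    readset: SampleReadSet,
    reference: Reference16S,
    screen_min_identity: float = 70.0,
    screen_min_len: int = 40,
) -> list[int]:
    """Indices of reads passing the permissive rRNA screen (both strands)."""
    if not reference.centroids:
        raise ValueError("empty reference")
    out = []
    for i, read in enumerate(readset.reads):
        if len(read) < screen_min_len:
            continue
        kmax = int(len(read) * (1 - screen_min_identity / 100.0) + 1e-9)
        rc = reverse_complement(read)
        hit = False
        for c in reference.centroids:
            if (
                _infix_identity(read, c.sequence, kmax) >= screen_min_identity
                or _infix_identity(rc, c.sequence, kmax) >= screen_min_identity
            ):
                hit = True
                break
        if hit:
            out.append(i)
    return out


def _best_profile_score(read: str, profiles: dict[str, DomainProfile]):
    """(score, domain) of the best placement of the read on any domain profile.

    The read is placed by infix alignment against each domain's family
    members (which are mutually aligned, so a member offset is a profile
    column offset); the placement with the lowest edit distance per domain
    is scored against the positional log-odds profile.
    """
    best = (-np.inf, None)
    kmax = int(0.45 * len(read))
    for dom, prof in profiles.items():
        placed = None  # (distance, offset, strand sequence)
        for seq in (read, reverse_complement(read)):
            for member in prof.members:
                res = edlib.align(seq, member, mode="HW", task="locations", k=kmax)
                d = res["editDistance"]
                if d < 0:
                    continue
                if placed is None or d < placed[0]:
                    placed = (d, res["locations"][0][0], seq)
        if placed is None:
            continue
        s = score_fragment(placed[2], prof, placed[1])
        if s > best[0]:
            best = (s, dom)
    return best


def verify_candidates(
    readset: SampleReadSet,
    candidate_indices: list[int],
    profiles: dict[str, DomainProfile] | None = None,
    min_fragment: int = 60,
) -> dict[int, str]:
    """Profile-verify candidates; returns {read index: domain label}.

    A read is kept iff its mean per-column log-odds against some domain
    profile reaches the shuffle-calibrated cutoff; the domain is the
    argmax.  Fragments shorter than ``min_fragment`` are rejected (too few
    profile columns for a stable score).
    """
    profiles = profiles or domain_profiles()
    cutoff = next(iter(profiles.values())).cutoff
    verified: dict[int, str] = {}
    for i in candidate_indices:
        read = readset.reads[i]
        if len(read) < min_fragment:
            continue
        score, dom = _best_profile_score(read, profiles)
        if dom is not None and score >= cutoff:
            verified[i] = dom
    return verified


def classify_fragment(
    read: str,
    reference: Reference16S,
    min_identity: float = 80.0,
    min_len: int = 90,
) -> tuple[str, ...] | None:
    """Lineage of the best-identity centroid, or None if below thresholds.

    Aligned length is the full read (infix placement), so reads shorter
    than ``min_len`` are discarded outright.
    """
    if len(read) < min_len:
        return None
    kmax = int(len(read) * (1 - min_identity / 100.0) + 1e-9)
    rc = reverse_complement(read)
    best: tuple[float, tuple[str, ...]] | None = None
    for c in reference.centroids:
        ident = max(
            _infix_identity(read, c.sequence, kmax),
            _infix_identity(rc, c.sequence, kmax),
        )
        if ident < min_identity:
            continue
        key = (-ident, c.taxonomy)
        if best is None or key < best:
            best = key
    return best[1] if best else None


def profile_sample(
    readset: SampleReadSet,
    reference: Reference16S,
    profiles: dict[str, DomainProfile] | None = None,
    **kwargs,
) -> tuple[list[tuple[str, ...]], dict[int, tuple[str, ...]]]:
    """Run the full detect -> verify -> classify cascade on one sample.

    Returns (classified lineages, {read index: lineage}).
    """
    cands = detect_candidates(readset, reference,
                              kwargs.get("screen_min_identity", 70.0),
                              kwargs.get("screen_min_len", 40))
    verified = verify_candidates(readset, cands, profiles)
    assigned: dict[int, tuple[str, ...]] = {}
    for i in verified:
        tax = classify_fragment(readset.reads[i], reference,
                                kwargs.get("min_identity", 80.0),
                                kwargs.get("min_len", 90))
        if tax is not None:
            assigned[i] = tax
    return list(assigned.values()), assigned


RANKS = ("domain", "phylum", "class")


def abundance_table(
    classified: dict[str, list[tuple[str, ...]]],
    rank: str = "phylum",
    proteobacteria_as_class: bool = True,
    display_min_pct: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent composition of classified fragments per sample.

    Returns (full table, display table).  The display table keeps taxa
    reaching ``display_min_pct`` in at least one sample and folds the rest
    into "other".  With rank="phylum", Proteobacteria is reported at class
    resolution when ``proteobacteria_as_class`` is set.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    ridx = RANKS.index(rank)
    cols = {}
    for sample, lineages in classified.items():
        if not lineages:
            warnings.warn(f"sample {sample}: no classified fragments; NA column")
            cols[sample] = pd.Series(dtype=float)
            continue
        labels = []
        for lin in lineages:
            label = lin[ridx] if len(lin) > ridx else lin[-1]
            if (
                proteobacteria_as_class
                and rank == "phylum"
                and len(lin) > 1
                and lin[1] == "Proteobacteria"
                and len(lin) > 2
            ):
                label = lin[2]
            labels.append(label)
        vc = pd.Series(labels).value_counts()
        cols[sample] = 100.0 * vc / vc.sum()
    full = pd.DataFrame(cols).fillna(0.0).sort_index()
    keep = full.index[(full >= display_min_pct).any(axis=1)]
    display = full.loc[keep].copy()
    other = full.drop(index=keep).sum(axis=0)
    if (other > 0).any():
        display.loc["other"] = other
    return full, display


def simpson_diversity(proportions) -> float:
    """Gini–Simpson index 1 - sum(p_i^2) of a proportion vector."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("proportions must sum to 1")
    return float(1.0 - np.sum(p**2))
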