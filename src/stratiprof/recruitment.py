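"""Read recruitment to genomes, RPKG, presence, and depth/season classes.

Recruitment follows the identity/length contract used throughout the
pipeline: a read recruits to a genome iff its best local placement reaches
``min_identity`` percent over at least ``min_aln_len`` aligned columns;
each read is counted once, for its best-hit genome (ties broken by
lexicographic genome id).  Identity is computed as
100 * (read_len - edit_distance) / read_len from an infix alignment of the
full read into the genome, which equals matches/columns for the
substitution-dominated alignments this pipeline deals in.

The matcher is seed-and-verify: exact 21-mers locate candidate loci, edlib
verifies them within a small window.  This is an implementation detail of
the same contract, not a different filter — a read whose best alignment
passes the thresholds but shares no exact seed with its locus can be
missed, which at the identity levels used here (>= 95%) is negligible and
unbiased across genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .core_io import GenomeRecord, SampleReadSet, Season, reverse_complement

_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_ints(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers; k-mers containing N get code -1."""
    codes = _encode(seq).astype(np.int64)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bad = codes > 3
    vals = np.zeros(n, dtype=np.int64)
    invalid = np.zeros(n, dtype=bool)
    for j in range(k):
        vals = vals * 4 + np.where(bad[j : j + n], 0, codes[j : j + n])
        invalid |= bad[j : j + n]
    vals[invalid] = -1
    return vals


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    genome_id: str
    identity_percent: float
    aln_length: int


class ReadRecruiter:
    """Seed-and-verify recruiter over a fixed set of reference genomes."""

    def __init__(self, genomes: list[GenomeRecord], k: int = 21):
        if not genomes:
            raise ValueError("at least one genome required")
        ids = [g.id for g in genomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome ids")
        self.genomes = sorted(genomes, key=lambda g: g.id)
        self.k = k
        self._index: dict[int, list[tuple[int, int]]] = {}
        for gi, g in enumerate(self.genomes):
            for pos, v in enumerate(_kmer_ints(g.sequence, k)):
                if v >= 0:
                    self._index.setdefault(int(v), []).append((gi, pos))

    def _candidates(
        self, read: str, rc: str, max_per_genome: int = 6
    ) -> list[tuple[int, int, bool]]:
        """Seeded (genome index, window start, is_rc) placements for a read."""
        k, L = self.k, len(read)
        if L < k:
            return []
        offsets = sorted({0, (L - k) // 4, (L - k) // 2, 3 * (L - k) // 4, L - k})
        seen: set[tuple[int, int, bool]] = set()
        per_genome: dict[tuple[int, bool], int] = {}
        out: list[tuple[int, int, bool]] = []
        for strand_seq, is_rc in ((read, False), (rc, True)):
            for off in offsets:
                v = 0
                ok = True
                for ch in strand_seq[off : off + k]:
                    c = _CODE[ord(ch)]
                    if c > 3:
                        ok = False
                        break
                    v = v * 4 + int(c)
                if not ok:
                    continue
                for gi, pos in self._index.get(v, ()):
                    key = (gi, pos - off, is_rc)
                    budget = (gi, is_rc)
                    if key in seen or per_genome.get(budget, 0) >= max_per_genome:
                        continue
                    seen.add(key)
                    per_genome[budget] = per_genome.get(budget, 0) + 1
                    out.append(key)
        return out

    def recruit_read(
        self, read: str, min_identity: float = 99.0, min_aln_len: int = 50
    ) -> tuple[str | None, float]:
        """Best-hit genome id and identity for one read (None if unrecruited)."""
        L = len(read)
        if L < min_aln_len:
            return None, 0.0
        kmax = int(math.floor(L * (1.0 - min_identity / 100.0) + 1e-9))
        rc = reverse_complement(read)
        best: tuple[int, str] | None = None  # (distance, genome_id)
        for gi, start, is_rc in self._candidates(read, rc):
            g = self.genomes[gi]
            lo = max(0, start - 8)
            hi = min(len(g.sequence), start + L + 8)
            window = g.sequence[lo:hi]
            q = rc if is_rc else read
            res = edlib.align(q, window, mode="HW", task="distance", k=kmax)
            d = res["editDistance"]
            if d < 0:
                continue
            cand = (d, g.id)
            if best is None or cand < best:
                best = cand
        if best is None:
            return None, 0.0
        return best[1], 100.0 * (L - best[0]) / L

    def recruit(
        self,
        readset: SampleReadSet,
        min_identity: float = 99.0,
        min_aln_len: int = 50,
    ) -> tuple[pd.Series, list[str | None]]:
        """Counts per genome and the per-read best-hit assignment."""
        counts = {g.id: 0 for g in self.genomes}
        assigned: list[str | None] = []
        for read in readset.reads:
            gid, _ = self.recruit_read(read, min_identity, min_aln_len)
            assigned.append(gid)
            if gid is not None:
                counts[gid] += 1
        return pd.Series(counts, name=readset.sample_id), assigned


def rpkg(count: float, genome_length_bp: float, metagenome_bp: float) -> float:
    """Reads per kilobase of genome per gigabase of metagenome."""
    if genome_length_bp <= 0 or metagenome_bp <= 0:
        raise ValueError("genome_length_bp and metagenome_bp must be > 0")
    return count / (genome_length_bp / 1_000.0) / (metagenome_bp / 1e9)


@dataclass
class RecruitmentMatrix:
    """Genomes x samples recruitment result."""

    counts: pd.DataFrame
    rpkg: pd.DataFrame
    presence: pd.DataFrame
    threshold: float

    @property
    def retained_genomes(self) -> list[str]:
        return [g for g in self.presence.index if self.presence.loc[g].any()]


def recruitment_matrix(
    samples: list[SampleReadSet],
    genomes: list[GenomeRecord],
    min_identity: float = 99.0,
    min_aln_len: int = 50,
    rpkg_threshold: float = 3.0,
    recruiter: ReadRecruiter | None = None,
    return_assignments: bool = False,
):
    """Recruit every sample and assemble counts/RPKG/presence matrices."""
    rec = recruiter or ReadRecruiter(genomes)
    glen = {g.id: len(g) for g in rec.genomes}
    counts, assignments = {}, {}
    for s in samples:
        c, a = rec.recruit(s, min_identity, min_aln_len)
        counts[s.sample_id] = c
        assignments[s.sample_id] = a
    counts_df = pd.DataFrame(counts)
    rpkg_df = counts_df.apply(
        lambda col: pd.Series(
            {
                g: rpkg(col[g], glen[g], next(s.total_bp for s in samples
                                              if s.sample_id == col.name))
                for g in counts_df.index
            }
        )
    )
    pres_df, _ = presence(rpkg_df, rpkg_threshold)
    mat = RecruitmentMatrix(counts_df, rpkg_df, pres_df, rpkg_threshold)
    if return_assignments:
        return mat, assignments
    return mat


def presence(
    rpkg_matrix: pd.DataFrame, threshold: float = 3.0
) -> tuple[pd.DataFrame, list[str]]:
    """Presence booleans (rpkg >= threshold, inclusive) and retained genomes.

    A genome is retained iff present in at least one sample.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    pres = rpkg_matrix >= threshold
    retained = [g for g in pres.index if pres.loc[g].any()]
    return pres, retained


STENOBATHIC = "stenobathic"
INTERMEDIATE = "intermediate"
EURYBATHIC = "eurybathic"
ABSENT = "absent"


def classify_depth_range(presence_row, sampled_depths) -> str:
    """Depth-range class from a presence row over the stratified series.

    stenobathic: one depth, or two adjacent in the sampled series;
    eurybathic: all sampled depths; intermediate: anything else occupied.
    """
    row = np.asarray(presence_row, dtype=bool)
    depths = np.asarray(sampled_depths, dtype=float)
    if row.shape != depths.shape:
        raise ValueError(
            f"presence row length {row.size} != sampled depths {depths.size}"
        )
    occ = np.nonzero(row)[0]
    if occ.size == 0:
        return ABSENT
    if occ.size == 1 or (occ.size == 2 and occ[1] - occ[0] == 1):
        return STENOBATHIC
    if occ.size == row.size:
        return EURYBATHIC
    return INTERMEDIATE


ALWAYS = "always"
STRATIFIED_ONLY = "stratified_only"
WINTER_ONLY = "winter_only"


def classify_seasonal_occupancy(stratified_presence, mixed_presence) -> str:
    """Occupancy across the stratified series and the winter mixed pair."""
    s = bool(np.asarray(stratified_presence, dtype=bool).any())
    m = bool(np.asarray(mixed_presence, dtype=bool).any())
    if s and m:
        return ALWAYS
    if s:
        return STRATIFIED_ONLY
    if m:
        return WINTER_ONLY
    return ABSENT


def classify_all(
    matrix: RecruitmentMatrix, samples: list[SampleReadSet]
) -> pd.DataFrame:
    """Per-genome depth-range and seasonal-occupancy classification."""
    strat = sorted(
        (s for s in samples if s.season == Season.STRATIFIED), key=lambda s: s.depth_m
    )
    mixed = [s for s in samples if s.season == Season.MIXED]
    if not strat or not mixed:
        raise ValueError("need at least one stratified and one mixed sample")
    depths = [s.depth_m for s in strat]
    rows = {}
    for g in matrix.presence.index:
        srow = matrix.presence.loc[g, [s.sample_id for s in strat]].to_numpy()
        mrow = matrix.presence.loc[g, [s.sample_id for s in mixed]].to_numpy()
        rows[g] = {
            "depth_range_class": classify_depth_range(srow, depths),
            "seasonal_occupancy": classify_seasonal_occupancy(srow, mrow),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
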