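"""Seeded overlap matching between short sequences.

Matches a query read against a set of target sequences by exact shared
k-mer seeding followed by Hamming comparison over the implied ungapped
overlap — exact under the pipeline's substitution-only error model, and a
tight approximation of local alignment for the >= 95% identity regimes the
pipeline operates in.  Used for read-vs-read sample comparison and for
recruiting reads to short gene references where partial overlaps count.
"""

from __future__ import annotations

from dataclasses import dataclass


from .core_io import reverse_complement


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class OverlapHit:
    target_id: str
    overlap: int
    mismatches: int

    @property
    def identity_percent(self) -> float:
        return 100.0 * (self.overlap - self.mismatches) / self.overlap

    @property
    def matches(self) -> int:
        return self.overlap - self.mismatches


class OverlapMatcher:
    """Index of target sequences queried with ungapped overlap matching."""

    def __init__(self, targets: list[tuple[str, str]], k: int = 15,
                 probe_step: int = 10):
        """targets: list of (target_id, sequence); ids must be unique."""
        ids = [t for t, _ in targets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate target ids")
        self.k = k
        self.probe_step = probe_step
        self.targets = dict(targets)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in targets:
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" not in kmer:
                    self._index.setdefault(kmer, []).append((tid, pos))

    def _seed_offsets(self, read: str) -> dict[tuple[str, int, bool], None]:
        """Candidate (target_id, read_start_in_target, is_rc) placements."""
        k = self.k
        out: dict[tuple[str, int, bool], None] = {}
        for seq, is_rc in ((read, False), (reverse_complement(read), True)):
            L = len(seq)
            if L < k:
                continue
            probes = list(range(0, L - k + 1, self.probe_step))
            if probes[-1] != L - k:
                probes.append(L - k)
            for off in probes:
                for tid, pos in self._index.get(seq[off : off + k], ()):
                    out[(tid, pos - off, is_rc)] = None
        return out

    def best_hit(
        self, read: str, min_overlap: int = 50, min_identity: float = 95.0
    ) -> OverlapHit | None:
        """Best qualifying overlap hit (max matches; ties by target id)."""
        best: tuple[int, str, OverlapHit] | None = None
        for (tid, start, is_rc) in self._seed_offsets(read):
            q = reverse_complement(read) if is_rc else read
            t = self.targets[tid]
            q0 = max(0, -start)
            t0 = max(0, start)
            n = min(len(q) - q0, len(t) - t0)
            if n < min_overlap:
                continue
            mm = _hamming(q[q0 : q0 + n], t[t0 : t0 + n])
            if 100.0 * (n - mm) / n < min_identity:
                continue
            hit = OverlapHit(tid, n, mm)
            key = (-hit.matches, tid, hit)
            if best is None or key[:2] < (best[0], best[1]):
                best = (-hit.matches, tid, hit)
        return best[2] if best else None

    def has_match(
        self, read: str, min_overlap: int = 50, min_identity: float = 95.0
    ) -> bool:
        """Whether any qualifying overlap exists (early exit)."""
        for (tid, start, is_rc) in self._seed_offsets(read):
            q = reverse_complement(read) if is_rc else read
            t = self.targets[tid]
            q0 = max(0, -start)
            t0 = max(0, start)
            n = min(len(q) - q0, len(t) - t0)
            if n < min_overlap:
                continue
            mm = _hamming(q[q0 : q0 + n], t[t0 : t0 + n])
            if 100.0 * (n - mm) / n >= min_identity:
                return True
        return False
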