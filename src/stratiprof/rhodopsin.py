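"""Rhodopsin detection, spectral tuning, and per-genome abundance.

Rhodopsin genes are found on contigs >= 5 kb by translated comparison of
all six reading frames against the bundled exemplar protein.  The spectral
class is read from a single tuning residue at the exemplar-aligned
position (L -> green, Q -> blue).  Community rhodopsin content is
estimated from raw reads as length-normalized rhodopsin recruitment over
length-normalized recA+radA recruitment: since recA/radA are universal and
single copy, the ratio is rhodopsin genes per genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .core_io import GenomeRecord, SampleReadSet, reverse_complement
from .overlap import OverlapMatcher
from .references import (
    TUNING_POSITION,
    TUNING_RULE,
    rhodopsin_exemplar_protein,
)

MIN_CONTIG_LENGTH = 5_000


@dataclass
class RhodopsinGene:
    id: str
    source_contig: str
    sequence: str  # nucleotide, coding strand
    protein: str
    tuning_residue: str
    spectral_class: str
    taxon_label: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


def spectral_class(
    sequence: str,
    reference_protein: str | None = None,
    tuning_position: int | None = None,
    min_identity: float = 40.0,
) -> tuple[str, str]:
    """(class, residue) from the tuning position of an aligned rhodopsin.

    ``sequence`` may be nucleotide (translated in frame 0) or protein.
    Returns ("unknown", "") when the alignment to the reference fails the
    identity floor or does not cover the tuning position.
    """
    ref = reference_protein or rhodopsin_exemplar_protein()
    pos = TUNING_POSITION if tuning_position is None else tuning_position
    prot = sequence
    if set(sequence.upper()) <= set("ACGTN"):
        prot = str(Seq(sequence).translate()).rstrip("*")
    res = edlib.align(ref, prot, mode="NW", task="path")
    d = res["editDistance"]
    ident = 100.0 * (max(len(ref), len(prot)) - d) / max(len(ref), len(prot))
    if ident < min_identity:
        return "unknown", ""
    qi = ti = 0  # qi walks ref, ti walks prot
    aligned = None
    for n, op in _cigar_ops(res["cigar"]):
        for _ in range(n):
            if op in ("=", "X", "M"):
                if qi == pos:
                    aligned = ti
                qi += 1
                ti += 1
            elif op == "I":  # in ref only (deletion in prot)
                if qi == pos:
                    aligned = None  # tuning column deleted
                qi += 1
            elif op == "D":
                ti += 1
            if qi > pos and aligned is not None:
                break
    if aligned is None or aligned >= len(prot):
        return "unknown", ""
    residue = prot[aligned]
    return TUNING_RULE.get(residue, "unknown"), residue


def _cigar_ops(cigar: str):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield int(n), ch
            n = ""


def _six_frames(seq: str):
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for off in range(3):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            yield strand, off, str(Seq(sub).translate())


def find_rhodopsins(
    contigs: list[GenomeRecord],
    exemplar_protein: str | None = None,
    min_identity: float = 60.0,
    min_contig_length: int = MIN_CONTIG_LENGTH,
) -> list[RhodopsinGene]:
    """Translated search for rhodopsin genes on contigs >= 5 kb.

    A gene is called where some reading frame contains a region matching
    the exemplar protein at >= ``min_identity`` percent over the
    exemplar's full length (infix placement).
    """
    ex = exemplar_protein or rhodopsin_exemplar_protein()
    kmax = int(len(ex) * (1 - min_identity / 100.0))
    out: list[RhodopsinGene] = []
    for contig in contigs:
        if len(contig) < min_contig_length:
            continue
        hits = []
        for strand, off, prot in _six_frames(contig.sequence):
            res = edlib.align(ex, prot, mode="HW", task="locations", k=kmax)
            if res["editDistance"] < 0:
                continue
            for loc in res["locations"]:
                hits.append((res["editDistance"], strand, off, loc[0], loc[1]))
        # keep non-overlapping best hits (usually one per contig)
        hits.sort()
        taken: list[tuple[int, int]] = []
        for d, strand, off, a0, a1 in hits:
            nt0 = off + 3 * a0
            nt1 = off + 3 * (a1 + 1)
            if strand == "-":
                nt0, nt1 = len(contig) - nt1, len(contig) - nt0
            if any(not (nt1 <= s or nt0 >= e) for s, e in taken):
                continue
            taken.append((nt0, nt1))
            nt = contig.sequence[nt0:nt1]
            if strand == "-":
                nt = reverse_complement(nt)
            prot_seq = str(Seq(nt).translate())
            cls, residue = spectral_class(prot_seq, ex)
            out.append(
                RhodopsinGene(
                    id=f"{contig.id}_rho{len(taken)}",
                    source_contig=contig.id,
                    sequence=nt,
                    protein=prot_seq,
                    tuning_residue=residue,
                    spectral_class=cls,
                    taxon_label=contig.taxonomy[1] if len(contig.taxonomy) > 1 else "",
                )
            )
    return out


@dataclass(frozen=True)
class RhodopsinAbundance:
    sample_id: str
    rhodopsins_per_genome: float
    rhodopsin_read_count: int
    reca_read_count: int
    rada_read_count: int


def rhodopsins_per_genome(
    readset: SampleReadSet,
    rhodopsin_refs: list[tuple[str, str]],
    reca_refs: list[tuple[str, str]],
    rada_refs: list[tuple[str, str]],
    exclusion_refs: list[tuple[str, str]] | None = None,
    min_identity: float = 99.0,
    min_aln_len: int = 50,
) -> RhodopsinAbundance:
    """Estimated rhodopsin genes per genome in one sample.

    Rhodopsin read recruitment is normalized by the number and length of
    the single-copy housekeeping genes recA and radA:

        estimate = (rhodopsin reads / eff_rho)
                 / ((recA + radA reads) / (eff_recA + eff_radA))

    where eff is the per-gene *effective length* — the number of read
    start positions yielding a qualifying overlap, mean gene length +
    mean read length - 2*min_aln_len + 1.  Since every genome carries one
    recA and one radA, the denominator estimates total genome (cell)
    coverage and the ratio is rhodopsin gene copies per genome.

    Reads are matched best-hit against all references jointly (plus any
    viral/eukaryotic exclusion references, whose reads are discarded).
    Raises if no recA/radA read is found (sample too shallow to
    normalize).
    """
    if not rhodopsin_refs or not reca_refs or not rada_refs:
        raise ValueError("all three reference sets must be non-empty")
    tagged = (
        [(f"rho|{i}", s) for i, (_, s) in enumerate(rhodopsin_refs)]
        + [(f"recA|{i}", s) for i, (_, s) in enumerate(reca_refs)]
        + [(f"radA|{i}", s) for i, (_, s) in enumerate(rada_refs)]
        + [(f"excl|{i}", s) for i, (_, s) in enumerate(exclusion_refs or [])]
    )
    matcher = OverlapMatcher(tagged, k=21)
    n = {"rho": 0, "recA": 0, "radA": 0, "excl": 0}
    for read in readset.reads:
        hit = matcher.best_hit(read, min_aln_len, min_identity)
        if hit is not None:
            n[hit.target_id.split("|")[0]] += 1
    reca_rada_reads = n["recA"] + n["radA"]
    if reca_rada_reads == 0:
        raise ValueError(
            f"sample {readset.sample_id}: no recA/radA reads; "
            "cannot normalize rhodopsin abundance"
        )
    mean_read = readset.total_bp / len(readset)

    def eff(refset: list[tuple[str, str]]) -> float:
        mean_gene = np.mean([len(s) for _, s in refset])
        return mean_gene + mean_read - 2 * min_aln_len + 1

    estimate = (n["rho"] / eff(rhodopsin_refs)) / (
        reca_rada_reads / (eff(reca_refs) + eff(rada_refs))
    )
    return RhodopsinAbundance(
        sample_id=readset.sample_id,
        rhodopsins_per_genome=estimate,
        rhodopsin_read_count=n["rho"],
        reca_read_count=n["recA"],
        rada_read_count=n["radA"],
    )


def rhodopsin_recruit(
    readsets: list[SampleReadSet],
    genes: list[RhodopsinGene],
    min_identity: float = 99.0,
    min_aln_len: int = 50,
    keep_rpkg: float = 1.0,
) -> pd.DataFrame:
    """Per-gene per-sample RPKG; genes below ``keep_rpkg`` everywhere dropped.

    RPKG uses the gene length (kb) and the sample's total bp (Gb); the
    keep rule is inclusive (max RPKG >= keep_rpkg retains the gene).
    """
    matcher = OverlapMatcher([(g.id, g.sequence) for g in genes], k=21)
    glen = {g.id: g.length for g in genes}
    cols = {}
    for rs in readsets:
        counts = {g.id: 0 for g in genes}
        for read in rs.reads:
            hit = matcher.best_hit(read, min_aln_len, min_identity)
            if hit is not None:
                counts[hit.target_id] += 1
        gb = rs.total_bp / 1e9
        cols[rs.sample_id] = {
            gid: c / (glen[gid] / 1000.0) / gb for gid, c in counts.items()
        }
    df = pd.DataFrame(cols)
    return df[df.max(axis=1) >= keep_rpkg]
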