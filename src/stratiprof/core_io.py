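"""Readers/writers and shared sequence utilities.

Sequence formats go through Biopython's SeqIO; manifests and gene sidecars
are plain TSV read with pandas. Coordinates are 0-based, half-open
throughout. Read qualities are parsed but ignored: every downstream filter
in the pipeline is identity/length based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

#: closed vocabulary of gene roles
GENE_ROLES = {"rrna16S", "recA", "radA", "rhodopsin", "GH", "marker", "other"}


class Season(str, Enum):
    STRATIFIED = "stratified"
    MIXED = "mixed"


@dataclass(frozen=True)
class Gene:
    """An annotated gene interval on a genome/contig (0-based, half-open)."""

    start: int
    end: int
    strand: str  # '+' or '-'
    role: str
    family: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"bad gene interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.role not in GENE_ROLES:
            raise ValueError(f"unknown gene role {self.role!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A reference genome or assembled contig with optional annotations."""

    id: str
    sequence: str
    taxonomy: tuple[str, ...] = ()
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"genome {self.id}: invalid characters {sorted(bad)} in sequence"
            )
        for g in self.genes:
            if g.end > len(self.sequence):
                raise ValueError(
                    f"genome {self.id}: gene [{g.start}, {g.end}) exceeds "
                    f"sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_sequence(self, gene: Gene) -> str:
        s = self.sequence[gene.start : gene.end]
        return reverse_complement(s) if gene.strand == "-" else s


@dataclass
class SampleReadSet:
    """One metagenome sample: reads plus sampling metadata."""

    sample_id: str
    depth_m: float
    season: Season
    reads: list[str]
    read_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ValueError("depth_m must be >= 0")
        self.season = Season(self.season)
        self.reads = [r.upper() for r in self.reads]
        if self.read_ids is None:
            self.read_ids = [f"{self.sample_id}_r{i}" for i in range(len(self.reads))]
        elif len(self.read_ids) != len(self.reads):
            raise ValueError("read_ids length must match reads")

    @property
    def total_bp(self) -> int:
        return sum(len(r) for r in self.reads)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class NutrientRecord:
    sample_id: str
    total_n_uM: float
    total_p_uM: float
    extras: dict = field(default_factory=dict)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq_or_readset: str | SampleReadSet) -> float:
    """GC percentage, 100*(G+C)/(A+C+G+T); N bases are excluded entirely.

    Raises ValueError on input with no countable (non-N) base.
    """
    if isinstance(seq_or_readset, SampleReadSet):
        seq = "".join(seq_or_readset.reads)
    else:
        seq = seq_or_readset.upper()
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError("no A/C/G/T bases: GC content undefined")
    return 100.0 * gc / acgt


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords (sequence-only).

    Ids must be unique; sequences are uppercased; characters outside
    A,C,G,T,N are rejected.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        records.append(GenomeRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_reads(
    path: str | Path,
    fmt: str,
    sample_id: str = "sample",
    depth_m: float = 0.0,
    season: Season | str = Season.STRATIFIED,
) -> SampleReadSet:
    """Read a FASTQ or FASTA read file into a SampleReadSet.

    Qualities are ignored. Read order is preserved; total_bp is derived.
    """
    if fmt not in ("fastq", "fasta"):
        raise ValueError(f"format must be 'fastq' or 'fasta', got {fmt!r}")
    ids, seqs = [], []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
    except ValueError as exc:  # Biopython flags truncated/mismatched records
        raise ValueError(f"malformed {fmt} near record {len(seqs)}: {exc}") from exc
    return SampleReadSet(
        sample_id=sample_id, depth_m=depth_m, season=season, reads=seqs, read_ids=ids
    )


def write_fastq(readset: SampleReadSet, path: str | Path) -> None:
    """Write reads as FASTQ with uniform placeholder qualities."""
    recs = []
    for rid, seq in zip(readset.read_ids, readset.reads):
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


MANIFEST_COLUMNS = ["sample_id", "depth_m", "season", "path"]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest TSV (sample_id, depth_m, season, path).

    Returns a DataFrame with seasons parsed and stratified rows sorted by
    ascending depth (mixed rows follow, also depth-sorted).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id: {dups}")
    try:
        df["season"] = df["season"].map(lambda s: Season(s))
    except ValueError as exc:
        raise ValueError(f"unknown season label in manifest: {exc}") from exc
    dup = df.duplicated(subset=["season", "depth_m"])
    if dup.any():
        raise ValueError(
            f"duplicate depth within a season series: "
            f"{df.loc[dup, ['season', 'depth_m']].to_dict('records')}"
        )
    order = {Season.STRATIFIED: 0, Season.MIXED: 1}
    df = df.sort_values(
        ["season", "depth_m"], key=lambda c: c.map(order) if c.name == "season" else c
    ).reset_index(drop=True)
    return df


def read_gene_sidecar(path: str | Path) -> dict[str, list[Gene]]:
    """Read a gene sidecar TSV: genome_id, start, end, strand, role, family."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "family": str})
    need = ["genome_id", "start", "end", "strand", "role"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"gene sidecar missing columns: {missing}")
    if "family" not in df.columns:
        df["family"] = ""
    out: dict[str, list[Gene]] = {}
    for row in df.itertuples(index=False):
        fam = "" if pd.isna(row.family) else str(row.family)
        out.setdefault(row.genome_id, []).append(
            Gene(int(row.start), int(row.end), row.strand, row.role, fam)
        )
    return out


def write_gene_sidecar(records: Sequence[GenomeRecord], path: str | Path) -> None:
    rows = [
        (r.id, g.start, g.end, g.strand, g.role, g.family)
        for r in records
        for g in r.genes
    ]
    pd.DataFrame(
        rows, columns=["genome_id", "start", "end", "strand", "role", "family"]
    ).to_csv(path, sep="\t", index=False)


def read_nutrients(path: str | Path) -> list[NutrientRecord]:
    """Read a nutrient table TSV mirroring the field-campaign column names."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    need = ["sample_id", "total_n_uM", "total_p_uM"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"nutrient table missing columns: {missing}")
    extras_cols = [c for c in df.columns if c not in need]
    return [
        NutrientRecord(
            sample_id=row["sample_id"],
            total_n_uM=float(row["total_n_uM"]),
            total_p_uM=float(row["total_p_uM"]),
            extras={c: row[c] for c in extras_cols},
        )
        for _, row in df.iterrows()
    ]


def concat_readsets(a: SampleReadSet, b: SampleReadSet) -> SampleReadSet:
    return SampleReadSet(
        sample_id=a.sample_id,
        depth_m=a.depth_m,
        season=a.season,
        reads=a.reads + b.reads,
        read_ids=list(a.read_ids) + [f"b_{i}" for i in b.read_ids],
    )


def iter_kmers(seq: str, k: int):
    """Yield (pos, kmer) for k-mers free of N."""
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            yield i, kmer
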