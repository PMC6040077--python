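"""Synthetic stratified/mixed water-column studies with known ground truth.

The generator emulates the sampling design the pipeline targets: six
stratified photic-zone samples at 15 m spacing (15–90 m) plus a two-depth
winter-mixing pair (20 and 80 m).  Each genome occupies a Gaussian depth
niche (or a flat, depth-independent one), carries a distinct k-mer
composition from a calibrated Markov model, and receives implanted marker
genes (rRNA, recA/radA, rhodopsin with a declared tuning residue, universal
single-copy markers, glycoside hydrolases).  Reads are drawn
length-weighted with i.i.d. substitution errors; every stochastic choice
flows from one seed.

Truth tables record per-sample abundances, expected RPKG, the depth-range
and seasonal-occupancy class implied by the configuration, per-genome
rhodopsin copy numbers, GH gene counts, and per-read source genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import references as refs
from .core_io import Gene, GenomeRecord, SampleReadSet, Season, reverse_complement

STRATIFIED_DEPTHS = (15.0, 30.0, 45.0, 60.0, 75.0, 90.0)
MIXED_DEPTHS = (20.0, 80.0)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class CompositionModel:
    """Order-k Markov sequence composition calibrated to a GC target.

    transition weights are drawn per genome (from the generation seed) and
    perturb the conditional base probabilities so that genomes with the
    same GC still have distinct tetranucleotide signatures.
    """

    gc_target: float  # percent
    markov_order: int = 2
    perturbation: float = 0.6

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_target < 100.0:
            raise ValueError(f"gc_target must be in (0, 100), got {self.gc_target}")
        if self.markov_order not in (0, 1, 2, 3):
            raise ValueError("markov_order must be in 0..3")
        if self.perturbation < 0:
            raise ValueError("perturbation must be >= 0")


@dataclass(frozen=True)
class NicheSpec:
    """Gaussian depth niche of one genome plus its winter (mixed) abundance.

    peak_relative_abundance 0 encodes a genome absent during stratification
    (a winter-only taxon); flat=True encodes a depth-independent profile.
    """

    genome_id: str
    center_depth_m: float = 45.0
    width_m: float = 5.0
    peak_relative_abundance: float = 1.0
    mixed_abundance: float = 0.0
    flat: bool = False

    def __post_init__(self) -> None:
        if self.width_m < 0:
            raise ValueError("width_m must be >= 0")
        if not 0.0 <= self.peak_relative_abundance <= 1.0:
            raise ValueError("peak_relative_abundance must be in [0, 1]")
        if not 0.0 <= self.mixed_abundance <= 1.0:
            raise ValueError("mixed_abundance must be in [0, 1]")


def depth_profile(niche: NicheSpec, depths) -> np.ndarray:
    """Unnormalized abundance of a niche at each sampled depth.

    Gaussian exp(-(d-center)^2 / (2 width^2)) * peak; width 0 collapses to
    an indicator at the nearest sampled depth; flat niches are equal at all
    depths.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("depths must be nonempty")
    peak = niche.peak_relative_abundance
    if niche.flat:
        return np.full(depths.shape, peak)
    if niche.width_m == 0:
        out = np.zeros(depths.shape)
        out[np.argmin(np.abs(depths - niche.center_depth_m))] = peak
        return out
    z = (depths - niche.center_depth_m) / niche.width_m
    return peak * np.exp(-0.5 * z**2)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


def _conditional_probs(model: CompositionModel, rng: np.random.Generator):
    """Conditional base probabilities per context, calibrated so the chain's
    stationary single-base GC equals gc_target (bisection on a GC tilt)."""
    order = max(model.markov_order, 1) if model.markov_order else 0
    n_ctx = 4**order if order else 1
    g = model.gc_target / 100.0
    base = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    weights = base * np.exp(model.perturbation * rng.standard_normal((n_ctx, 4)))

    gc_mask = np.array([0.0, 1.0, 1.0, 0.0])

    def stationary_gc(t: float) -> float:
        probs = weights * np.exp(t * gc_mask)
        probs /= probs.sum(axis=1, keepdims=True)
        if n_ctx == 1:
            return float(probs[0] @ gc_mask)
        # state = last `order` bases; next state drops the oldest base
        pi = np.full(n_ctx, 1.0 / n_ctx)
        nxt = (np.arange(n_ctx)[:, None] % (4 ** (order - 1))) * 4 + np.arange(4)[None, :]
        for _ in range(200):
            new = np.zeros(n_ctx)
            np.add.at(new, nxt.ravel(), (pi[:, None] * probs).ravel())
            if np.abs(new - pi).max() < 1e-12:
                pi = new
                break
            pi = new
        return float((pi[:, None] * probs).sum(axis=0) @ gc_mask)

    lo, hi = -8.0, 8.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if stationary_gc(mid) < g:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    probs = weights * np.exp(t * gc_mask)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs, order


def generate_genome(
    length: int,
    composition: CompositionModel,
    seed: int,
    genome_id: str = "genome",
    taxonomy: tuple[str, ...] = (),
) -> GenomeRecord:
    """Draw a genome from the calibrated Markov composition model."""
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    probs, order = _conditional_probs(composition, rng)
    cum = probs.cumsum(axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    ctx = 0
    mask = 4 ** (order - 1) if order else 1
    if order == 0:
        out = np.searchsorted(cum[0], u).astype(np.uint8)
        out[out > 3] = 3
    else:
        row_lists = cum  # local alias for speed
        for i in range(length):
            row = row_lists[ctx]
            ui = u[i]
            b = 0
            while row[b] < ui:
                b += 1
            out[i] = b
            ctx = (ctx % mask) * 4 + b
    seq = _BASE_BYTES[out].tobytes().decode()
    return GenomeRecord(id=genome_id, sequence=seq, taxonomy=taxonomy)


# ---------------------------------------------------------------------------
# Marker implantation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerSpec:
    role: str  # from core_io.GENE_ROLES
    family: str
    sequence: str
    strand: str = "+"


def implant_markers(genome: GenomeRecord, marker_specs: list[MarkerSpec]) -> GenomeRecord:
    """Overwrite evenly spaced, non-overlapping genome intervals with markers.

    The genome length is unchanged (markers replace background sequence);
    gene intervals are recorded on the returned copy.
    """
    total = sum(len(m.sequence) for m in marker_specs)
    n = len(marker_specs)
    gap = (len(genome) - total) // (n + 1) if n else 0
    if n and (total >= len(genome) or gap < 1):
        raise ValueError(
            f"cannot place {n} markers totalling {total} bp in a "
            f"{len(genome)} bp genome without overlap"
        )
    seq = list(genome.sequence)
    genes: list[Gene] = list(genome.genes)
    pos = gap
    for m in marker_specs:
        ins = reverse_complement(m.sequence) if m.strand == "-" else m.sequence
        seq[pos : pos + len(ins)] = ins
        genes.append(Gene(pos, pos + len(ins), m.strand, m.role, m.family))
        pos += len(ins) + gap
    return GenomeRecord(
        id=genome.id, sequence="".join(seq), taxonomy=genome.taxonomy, genes=genes
    )


def shred_genome(
    genome: GenomeRecord, window: int = 20_000, min_length: int = 1_000
) -> list[GenomeRecord]:
    """Cut a genome into consecutive windows, remapping gene annotations.

    Genes are kept on a window iff fully contained in it (partially cut
    genes are dropped, mirroring assembly edge losses).
    """
    contigs = []
    for i, start in enumerate(range(0, len(genome), window)):
        end = min(start + window, len(genome))
        if end - start < min_length:
            continue
        genes = [
            Gene(g.start - start, g.end - start, g.strand, g.role, g.family)
            for g in genome.genes
            if g.start >= start and g.end <= end
        ]
        contigs.append(
            GenomeRecord(
                id=f"{genome.id}_c{i:03d}",
                sequence=genome.sequence[start:end],
                taxonomy=genome.taxonomy,
                genes=genes,
            )
        )
    return contigs


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def simulate_metagenome(
    genomes: list[GenomeRecord],
    abundances,
    n_reads: int,
    read_length: int = 150,
    error_rate: float = 0.002,
    seed: int = 0,
    sample_id: str = "sample",
    depth_m: float = 0.0,
    season: Season | str = Season.STRATIFIED,
) -> tuple[SampleReadSet, pd.DataFrame]:
    """Draw reads length-weighted from genomes with i.i.d. substitution errors.

    Returns the read set and a per-read truth table (source_genome,
    position — 0-based start on the source's forward strand, aligned with
    read order).  Reads with more than 10% N are redrawn.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    abundances = np.asarray(abundances, dtype=float)
    if abundances.shape != (len(genomes),) or (abundances < 0).any():
        raise ValueError("abundances must be nonnegative, one per genome")
    if not math.isclose(abundances.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("abundances must sum to 1")
    rng = np.random.default_rng(seed)
    weights = abundances * np.array([len(g) for g in genomes], dtype=float)
    weights /= weights.sum()
    counts = rng.multinomial(n_reads, weights)

    reads: list[str] = []
    sources: list[str] = []
    positions: list[int] = []
    order = np.repeat(np.arange(len(genomes)), counts)
    rng.shuffle(order)
    n_err = rng.binomial(read_length, error_rate, size=n_reads)
    for ridx, gi in enumerate(order):
        g = genomes[gi]
        L = len(g)
        if L < read_length:
            raise ValueError(f"genome {g.id} shorter than read length")
        for _ in range(50):
            pos = int(rng.integers(0, L - read_length + 1))
            frag = g.sequence[pos : pos + read_length]
            if frag.count("N") <= 0.1 * read_length:
                break
        positions.append(pos)
        if rng.random() < 0.5:
            frag = reverse_complement(frag)
        k = n_err[ridx]
        if k:
            arr = list(frag)
            for p in rng.choice(read_length, size=k, replace=False):
                alt = [b for b in "ACGT" if b != arr[p]]
                arr[p] = alt[rng.integers(3)]
            frag = "".join(arr)
        reads.append(frag)
        sources.append(g.id)
    readset = SampleReadSet(
        sample_id=sample_id, depth_m=depth_m, season=season, reads=reads
    )
    truth = pd.DataFrame({"source_genome": sources, "position": positions})
    return readset, truth


# ---------------------------------------------------------------------------
# Study configuration and generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Configuration of one community member."""

    genome_id: str
    length: int = 60_000
    composition: CompositionModel = field(default_factory=lambda: CompositionModel(42.0))
    taxonomy: tuple[str, str, str] = ("Bacteria", "Proteobacteria", "Alphaproteobacteria")
    rhodopsin_copies: int = 1
    rhodopsin_tuning: str = "L"
    gh_families: tuple[str, ...] = ()
    n_other_genes: int = 0
    marker_divergence: float = 0.06
    rrna_divergence: float = 0.02


@dataclass(frozen=True)
class StudyConfig:
    genomes: tuple[GenomeSpec, ...]
    niches: tuple[NicheSpec, ...]
    n_reads_per_sample: int = 20_000
    read_length: int = 150
    error_rate: float = 0.002
    stratified_depths: tuple[float, ...] = STRATIFIED_DEPTHS
    mixed_depths: tuple[float, ...] = MIXED_DEPTHS
    marker_catalog_size: int = 35
    rpkg_presence_threshold: float = 3.0

    def __post_init__(self) -> None:
        gids = [g.genome_id for g in self.genomes]
        nids = [n.genome_id for n in self.niches]
        if sorted(gids) != sorted(nids):
            raise ValueError(
                "genome ids and niche ids must match: "
                f"genomes={sorted(gids)} niches={sorted(nids)}"
            )
        if len(set(gids)) != len(gids):
            raise ValueError("duplicate genome ids in config")


@dataclass
class StudyResult:
    config: StudyConfig
    genomes: list[GenomeRecord]
    samples: list[SampleReadSet]
    truth: dict

    @property
    def stratified_samples(self) -> list[SampleReadSet]:
        return [s for s in self.samples if s.season == Season.STRATIFIED]

    @property
    def mixed_samples(self) -> list[SampleReadSet]:
        return [s for s in self.samples if s.season == Season.MIXED]


def _marker_specs_for(
    spec: GenomeSpec, catalog: list[str], rng: np.random.Generator
) -> list[MarkerSpec]:
    """Per-genome diverged variants of every implanted marker."""
    specs: list[MarkerSpec] = []
    strands = ["+", "-"]

    rrna = refs.mutate_dna(
        refs.family_sequence(spec.taxonomy), spec.rrna_divergence, rng
    )
    specs.append(MarkerSpec("rrna16S", "16S", rrna, "+"))
    for fam in ("recA", "radA"):
        var = refs.mutate_dna(refs.marker_exemplar(fam), spec.marker_divergence, rng)
        specs.append(MarkerSpec(fam, fam, var, strands[len(specs) % 2]))
    for c in range(spec.rhodopsin_copies):
        var = refs.mutate_dna(refs.rhodopsin_gene(spec.rhodopsin_tuning),
                              spec.marker_divergence, rng)
        var = refs.set_tuning_codon(var, spec.rhodopsin_tuning)
        specs.append(MarkerSpec("rhodopsin", "PR", var, "+"))
    for fam in catalog:
        var = refs.mutate_dna(refs.marker_exemplar(fam), spec.marker_divergence, rng)
        specs.append(MarkerSpec("marker", fam, var, strands[len(specs) % 2]))
    for i, fam in enumerate(spec.gh_families):
        var = refs.mutate_dna(refs.marker_exemplar(f"gh:{fam}"), spec.marker_divergence, rng)
        specs.append(MarkerSpec("GH", fam, var, strands[i % 2]))
    for i in range(spec.n_other_genes):
        var = refs.mutate_dna(
            refs.marker_exemplar(f"other:{i:03d}"), spec.marker_divergence, rng
        )
        specs.append(MarkerSpec("other", f"gene{i:03d}", var, strands[i % 2]))
    return specs


def community_abundances(config: StudyConfig) -> pd.DataFrame:
    """Exact per-sample relative abundances implied by the niche configuration.

    Rows: genome ids; columns: sample ids; columns sum to 1 (samples where
    every genome is absent are an error).
    """
    gids = [g.genome_id for g in config.genomes]
    niche = {n.genome_id: n for n in config.niches}
    cols = {}
    for d in config.stratified_depths:
        v = np.array(
            [depth_profile(niche[g], [d])[0] for g in gids]
        )
        if v.sum() == 0:
            raise ValueError(f"no genome present at stratified depth {d}")
        cols[_sid(d, Season.STRATIFIED)] = v / v.sum()
    for d in config.mixed_depths:
        v = np.array([niche[g].mixed_abundance for g in gids])
        if v.sum() == 0:
            raise ValueError(f"no genome present at mixed depth {d}")
        cols[_sid(d, Season.MIXED)] = v / v.sum()
    return pd.DataFrame(cols, index=gids)


def _sid(depth: float, season: Season) -> str:
    tag = "STR" if season == Season.STRATIFIED else "MIX"
    return f"{tag}-{int(depth):03d}m"


def expected_rpkg(config: StudyConfig, abundances: pd.DataFrame) -> pd.DataFrame:
    """Noise-free expected RPKG per genome and sample (exact arithmetic)."""
    lengths = {g.genome_id: g.length for g in config.genomes}
    total_bp = config.n_reads_per_sample * config.read_length
    out = {}
    for col in abundances.columns:
        a = abundances[col]
        w = a * pd.Series(lengths)
        w = w / w.sum()
        counts = w * config.n_reads_per_sample
        out[col] = {
            g: counts[g] / (lengths[g] / 1000.0) / (total_bp / 1e9)
            for g in abundances.index
        }
    return pd.DataFrame(out).loc[abundances.index]


def make_study(config: StudyConfig, seed: int = 0) -> StudyResult:
    """Generate a full stratified + mixed study with truth tables."""
    from .recruitment import classify_depth_range, classify_seasonal_occupancy

    master = np.random.default_rng(seed)
    catalog = refs.marker_catalog(config.marker_catalog_size)

    genomes: list[GenomeRecord] = []
    for spec in config.genomes:
        gseed = int(master.integers(2**31))
        bare = generate_genome(
            spec.length, spec.composition, gseed, spec.genome_id, spec.taxonomy
        )
        mrng = np.random.default_rng(gseed + 1)
        genomes.append(implant_markers(bare, _marker_specs_for(spec, catalog, mrng)))

    abund = community_abundances(config)
    exp_rpkg = expected_rpkg(config, abund)
    presence = exp_rpkg >= config.rpkg_presence_threshold

    strat_cols = [c for c in abund.columns if c.startswith("STR")]
    mixed_cols = [c for c in abund.columns if c.startswith("MIX")]
    classes, occupancy = {}, {}
    for g in abund.index:
        classes[g] = classify_depth_range(
            presence.loc[g, strat_cols].to_numpy(), config.stratified_depths
        )
        occupancy[g] = classify_seasonal_occupancy(
            presence.loc[g, strat_cols].to_numpy(),
            presence.loc[g, mixed_cols].to_numpy(),
        )

    samples: list[SampleReadSet] = []
    read_truth: dict[str, pd.DataFrame] = {}
    depth_season = [(d, Season.STRATIFIED) for d in config.stratified_depths] + [
        (d, Season.MIXED) for d in config.mixed_depths
    ]
    for d, season in depth_season:
        sid = _sid(d, season)
        rs, src = simulate_metagenome(
            genomes,
            abund[sid].to_numpy(),
            config.n_reads_per_sample,
            config.read_length,
            config.error_rate,
            seed=int(master.integers(2**31)),
            sample_id=sid,
            depth_m=d,
            season=season,
        )
        samples.append(rs)
        read_truth[sid] = src

    truth = {
        "abundances": abund,
        "expected_rpkg": exp_rpkg,
        "expected_presence": presence,
        "depth_class": pd.Series(classes, name="depth_range_class"),
        "occupancy": pd.Series(occupancy, name="seasonal_occupancy"),
        "rhodopsin_copies": pd.Series(
            {g.genome_id: g.rhodopsin_copies for g in config.genomes}
        ),
        "rhodopsin_tuning": pd.Series(
            {g.genome_id: g.rhodopsin_tuning for g in config.genomes}
        ),
        "taxonomy": {g.genome_id: g.taxonomy for g in config.genomes},
        "gh_counts": pd.Series(
            {g.genome_id: len(g.gh_families) for g in config.genomes}
        ),
        "read_sources": {s: df["source_genome"].to_numpy() for s, df in read_truth.items()},
        "read_positions": {s: df["position"].to_numpy() for s, df in read_truth.items()},
    }
    return StudyResult(config=config, genomes=genomes, samples=samples, truth=truth)


def default_study_config(
    n_reads_per_sample: int = 20_000, error_rate: float = 0.002
) -> StudyConfig:
    """The default 12-genome study: 8 stenobathic niches (sigma 3–4 m),
    2 eurybathic (flat, present in winter) and 2 winter-only genomes."""
    taxa = refs.REFERENCE_TAXA
    gh_menu = [("GH13",), ("GH16", "GH3"), (), ("GH13", "GH13"), ("GH29",), ()]
    specs, niches = [], []
    centers = [15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 22.5, 67.5]
    for i, c in enumerate(centers):
        gid = f"g{i + 1:02d}"
        specs.append(
            GenomeSpec(
                genome_id=gid,
                composition=CompositionModel(36.0 + 2.5 * i, markov_order=2),
                taxonomy=taxa[i],
                rhodopsin_copies=1 if i % 3 else 2,
                rhodopsin_tuning="L" if i % 2 == 0 else "Q",
                gh_families=gh_menu[i % len(gh_menu)],
                n_other_genes=4,
            )
        )
        sigma = 3.0 if c in STRATIFIED_DEPTHS else 4.0
        niches.append(NicheSpec(gid, center_depth_m=c, width_m=sigma,
                                peak_relative_abundance=1.0, mixed_abundance=0.0))
    for j in range(2):  # eurybathic, present in both seasons
        gid = f"g{9 + j:02d}"
        specs.append(
            GenomeSpec(
                genome_id=gid,
                composition=CompositionModel(45.0 + 5 * j, markov_order=2),
                taxonomy=taxa[8 + j],
                rhodopsin_copies=1,
                rhodopsin_tuning="Q" if j else "L",
                gh_families=("GH3",),
                n_other_genes=4,
            )
        )
        niches.append(NicheSpec(gid, flat=True, peak_relative_abundance=0.3,
                                mixed_abundance=0.3))
    for j in range(2):  # winter-only bloomers
        gid = f"g{11 + j:02d}"
        specs.append(
            GenomeSpec(
                genome_id=gid,
                composition=CompositionModel(38.0 + 8 * j, markov_order=2),
                taxonomy=taxa[10 + j],
                rhodopsin_copies=0,
                gh_families=("GH13",),
                n_other_genes=4,
            )
        )
        niches.append(NicheSpec(gid, peak_relative_abundance=0.0,
                                mixed_abundance=0.5))
    return StudyConfig(
        genomes=tuple(specs),
        niches=tuple(niches),
        n_reads_per_sample=n_reads_per_sample,
        error_rate=error_rate,
    )
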