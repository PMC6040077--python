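"""End-to-end self-benchmarks of the pipeline on synthetic studies.

Each function generates a study with known ground truth, runs the relevant
pipeline stage from scratch, and returns the recovery/error metrics.  These
are the package's own quality gates; they are reused by the test suite and
the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import references as refs
from .binning import bin_contigs, contig_features, project_features
from .core_io import Season
from .recruitment import classify_all, recruitment_matrix
from .rhodopsin import rhodopsins_per_genome
from .similarity import cluster_samples, join_order, similarity_matrix
from .synthetic import (
    CompositionModel,
    MarkerSpec,
    default_study_config,
    generate_genome,
    implant_markers,
    make_study,
    shred_genome,
    simulate_metagenome,
)
from .taxonomy import build_reference, profile_sample


@dataclass
class RecoveryResult:
    depth_class_recovery: float
    occupancy_recovery: float
    recruitment_specificity: float
    n_labels: int
    n_recruited_reads: int
    per_seed: list[dict] = field(default_factory=list)
    first_study: object = None
    first_matrix: object = None


def depth_class_recovery(
    base_seed: int, n_seeds: int = 5, n_reads_per_sample: int = 20_000,
    error_rate: float = 0.002,
) -> RecoveryResult:
    """Depth-range/occupancy label recovery and read-level specificity.

    Runs the default stratified+mixed study across seeds, recruits all
    samples at the 99%/50 bp filter, applies the 3-RPKG presence rule and
    the depth/season classifiers, and scores them against the generator's
    truth tables.
    """
    ok_depth = ok_occ = n_labels = 0
    ok_reads = n_reads = 0
    per_seed = []
    first_study = first_matrix = None
    for i in range(n_seeds):
        study = make_study(
            default_study_config(n_reads_per_sample, error_rate),
            seed=base_seed + i,
        )
        mat, assignments = recruitment_matrix(
            study.samples, study.genomes, return_assignments=True
        )
        classes = classify_all(mat, study.samples)
        d_ok = int((classes["depth_range_class"] == study.truth["depth_class"]).sum())
        o_ok = int((classes["seasonal_occupancy"] == study.truth["occupancy"]).sum())
        r_ok = r_n = 0
        for s in study.samples:
            src = study.truth["read_sources"][s.sample_id]
            for true_g, got_g in zip(src, assignments[s.sample_id]):
                if got_g is not None:
                    r_n += 1
                    r_ok += got_g == true_g
        per_seed.append(
            {"seed": base_seed + i, "depth_ok": d_ok, "occ_ok": o_ok,
             "reads_ok": r_ok, "reads_recruited": r_n}
        )
        ok_depth += d_ok
        ok_occ += o_ok
        n_labels += len(classes)
        ok_reads += r_ok
        n_reads += r_n
        if first_study is None:
            first_study, first_matrix = study, mat
    return RecoveryResult(
        depth_class_recovery=ok_depth / n_labels,
        occupancy_recovery=ok_occ / n_labels,
        recruitment_specificity=ok_reads / n_reads,
        n_labels=n_labels,
        n_recruited_reads=n_reads,
        per_seed=per_seed,
        first_study=first_study,
        first_matrix=first_matrix,
    )


def cascade_metrics(
    seed: int, n_reads_per_sample: int = 6_000, n_samples: int = 2
) -> dict:
    """Recall and false-positive survival of the 16S cascade.

    Positives are reads fully contained in an implanted rRNA gene;
    negatives are reads not overlapping it at all (partially overlapping
    reads are scored on neither side).  Recall additionally requires the
    classified lineage to match the source genome's truth taxonomy.
    """
    study = make_study(
        default_study_config(n_reads_per_sample), seed=seed
    )
    reference = build_reference([(s, t) for t, s in refs.synthetic_16s_family()])
    profiles = refs.domain_profiles()
    gene_span = {
        g.id: next((x.start, x.end) for x in g.genes if x.role == "rrna16S")
        for g in study.genomes
    }
    tax = study.truth["taxonomy"]
    tp = pos = fp = neg = 0
    for s in study.samples[:n_samples]:
        src = study.truth["read_sources"][s.sample_id]
        position = study.truth["read_positions"][s.sample_id]
        _, assigned = profile_sample(s, reference, profiles)
        for i, (g, p) in enumerate(zip(src, position)):
            a, b = gene_span[g]
            L = len(s.reads[i])
            inside = a <= p and p + L <= b
            outside = p + L <= a or p >= b
            if inside:
                pos += 1
                tp += assigned.get(i) == tax[g]
            elif outside:
                neg += 1
                fp += i in assigned
    return {
        "recall": tp / pos,
        "false_positive_rate": fp / neg,
        "n_positive": pos,
        "n_negative": neg,
    }


def binning_metrics(seed: int, window: int = 20_000) -> dict:
    """ARI and per-bin precision of composition binning on 3 genomes
    (pairwise GC separation >= 10 points) cut into 20 kb windows."""
    from sklearn.metrics import adjusted_rand_score

    genomes = [
        generate_genome(
            200_000, CompositionModel(gc, markov_order=2),
            seed=seed * 10 + i, genome_id=f"g{i}",
        )
        for i, gc in enumerate([35.0, 45.0, 55.0])
    ]
    contigs = [c for g in genomes for c in shred_genome(g, window)]
    coords = project_features(contig_features(contigs))
    ba = bin_contigs(coords)
    truth = pd.Series({c.id: c.id.split("_")[0] for c in contigs})
    pred = ba.membership[truth.index]
    precisions = []
    for b in ba.bin_ids:
        members = truth[ba.contigs_of(b)]
        precisions.append(members.value_counts().iloc[0] / len(members))
    return {
        "ari": adjusted_rand_score(truth, pred),
        "min_bin_precision": min(precisions) if precisions else 0.0,
        "n_bins": len(ba.bin_ids),
    }


def _marker_community(n: int, frac_rho: float, seed: int, genome_length: int = 20_000):
    rng = np.random.default_rng(seed)
    genomes = []
    for i in range(n):
        g = generate_genome(
            genome_length, CompositionModel(38.0 + (i % 8), markov_order=1),
            seed=seed * 1_000 + i, genome_id=f"g{i:02d}",
        )
        specs = []
        if i < round(frac_rho * n):
            v = refs.set_tuning_codon(
                refs.mutate_dna(refs.rhodopsin_gene("L"), 0.06, rng), "L"
            )
            specs.append(MarkerSpec("rhodopsin", "PR", v, "+"))
        for fam, strand in (("recA", "+"), ("radA", "-")):
            specs.append(
                MarkerSpec(fam, fam, refs.mutate_dna(refs.marker_exemplar(fam), 0.06, rng), strand)
            )
        genomes.append(implant_markers(g, specs))
    return genomes


def rhodopsin_estimator_metrics(
    base_seed: int, n_genomes: int, rho_fraction: float,
    n_seeds: int = 10, n_reads: int = 12_000,
) -> dict:
    """Mean rhodopsins-per-genome estimate vs. truth, with its 3-sigma
    binomial error (delta method on the read counts, averaged over seeds)."""
    truth = round(rho_fraction * n_genomes) / n_genomes
    ests, variances = [], []
    for i in range(n_seeds):
        genomes = _marker_community(n_genomes, rho_fraction, base_seed + i)
        readset, _ = simulate_metagenome(
            genomes, np.full(n_genomes, 1.0 / n_genomes), n_reads,
            seed=base_seed + 500 + i, sample_id=f"rho{i}",
        )
        out = {"rhodopsin": [], "recA": [], "radA": []}
        for g in genomes:
            for gene in g.genes:
                if gene.role in out:
                    out[gene.role].append((f"{g.id}_{gene.role}", g.gene_sequence(gene)))
        est = rhodopsins_per_genome(
            readset, out["rhodopsin"], out["recA"], out["radA"]
        )
        ests.append(est.rhodopsins_per_genome)
        n_rho = max(est.rhodopsin_read_count, 1)
        n_hk = est.reca_read_count + est.rada_read_count
        variances.append(est.rhodopsins_per_genome**2 * (1 / n_rho + 1 / n_hk))
    mean = float(np.mean(ests))
    sigma_mean = float(np.sqrt(np.sum(variances)) / n_seeds)
    return {
        "truth": truth,
        "estimate": mean,
        "sigma": sigma_mean,
        "within_3_sigma": abs(mean - truth) <= 3 * sigma_mean,
        "per_seed": ests,
    }


def similarity_metrics(study, subset_size: int = 800, seed: int = 0) -> dict:
    """Dendrogram topology check: the two winter-mixing samples must join
    each other before joining any stratified sample."""
    sim = similarity_matrix(study.samples, subset_size=subset_size, seed=seed)
    Z, newick = cluster_samples(sim)
    labels = sorted(sim.index)
    merges = join_order(Z, labels)
    mixed = frozenset(
        s.sample_id for s in study.samples if s.season == Season.MIXED
    )
    first_with_mixed = next(m for m in merges if m & mixed)
    return {
        "mixed_pair_joins_first": first_with_mixed == mixed,
        "similarity": sim,
        "newick": newick,
    }
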