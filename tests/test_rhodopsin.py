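"""Rhodopsin detection, spectral tuning, and abundance estimation."""

import numpy as np
import pytest

from stratiprof import references as refs
from stratiprof.core_io import SampleReadSet
from stratiprof.rhodopsin import (
    find_rhodopsins,
    rhodopsin_recruit,
    rhodopsins_per_genome,
    spectral_class,
)
from stratiprof.synthetic import (
    CompositionModel,
    MarkerSpec,
    generate_genome,
    implant_markers,
    simulate_metagenome,
)

# synonymous codon swaps (same amino acid, different codon)
_SYNONYM = {"CTG": "CTA", "CAG": "CAA", "GCT": "GCC", "GGT": "GGA"}


def _synonymize(gene_nt: str, every: int = 5) -> str:
    codons = [gene_nt[i : i + 3] for i in range(0, len(gene_nt), 3)]
    for i in range(0, len(codons), every):
        codons[i] = _SYNONYM.get(codons[i], codons[i])
    return "".join(codons)


class TestSpectralClass:
    def test_tuning_rule(self):
        assert spectral_class(refs.rhodopsin_gene("L")) == ("green", "L")
        assert spectral_class(refs.rhodopsin_gene("Q")) == ("blue", "Q")

    def test_other_residue_unknown(self):
        cls, residue = spectral_class(refs.rhodopsin_gene("M"))
        assert cls == "unknown" and residue == "M"

    def test_invariant_to_synonymous_changes(self):
        for tuning in ("L", "Q"):
            gene = refs.rhodopsin_gene(tuning)
            assert spectral_class(_synonymize(gene)) == spectral_class(gene)

    def test_unalignable_sequence_unknown(self):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=250))
        cls, _ = spectral_class(junk)
        assert cls == "unknown"

    def test_diverged_variant_still_classified(self):
        rng = np.random.default_rng(1)
        var = refs.set_tuning_codon(
            refs.mutate_dna(refs.rhodopsin_gene("Q"), 0.06, rng), "Q"
        )
        assert spectral_class(var)[0] == "blue"


@pytest.fixture(scope="module")
def contig_with_rhodopsins():
    g = generate_genome(12_000, CompositionModel(45.0), seed=60, genome_id="c1")
    rng = np.random.default_rng(2)
    varl = refs.set_tuning_codon(refs.mutate_dna(refs.rhodopsin_gene("L"), 0.05, rng), "L")
    varq = refs.set_tuning_codon(refs.mutate_dna(refs.rhodopsin_gene("Q"), 0.05, rng), "Q")
    return implant_markers(g, [
        MarkerSpec("rhodopsin", "PR", varl, "+"),
        MarkerSpec("rhodopsin", "PR", varq, "-"),
    ])


class TestFindRhodopsins:
    def test_implanted_genes_found_with_correct_coordinates(self, contig_with_rhodopsins):
        contig = contig_with_rhodopsins
        found = find_rhodopsins([contig])
        assert len(found) == 2
        assert {f.spectral_class for f in found} == {"green", "blue"}
        # each call overlaps an implanted interval and recovers ~full length
        for f in found:
            gene_seq = f.sequence
            hit = any(
                contig.gene_sequence(g).find(gene_seq[30:60]) >= 0
                for g in contig.genes
            )
            assert hit
            assert abs(len(gene_seq) - 747) <= 9

    def test_short_contig_skipped(self):
        g = generate_genome(10_000, CompositionModel(45.0), seed=61, genome_id="c4")
        short = type(g)(id="s", sequence=g.sequence[:4_000])
        with_gene = implant_markers(
            short, [MarkerSpec("rhodopsin", "PR", refs.rhodopsin_gene("L"), "+")]
        )
        assert find_rhodopsins([with_gene]) == []

    def test_background_contig_clean(self):
        g = generate_genome(12_000, CompositionModel(45.0), seed=62, genome_id="c5")
        assert find_rhodopsins([g]) == []


def _marker_community(n: int, frac_rho: float, seed: int):
    rng = np.random.default_rng(seed)
    genomes = []
    for i in range(n):
        g = generate_genome(
            20_000, CompositionModel(38.0 + (i % 8), markov_order=1),
            seed=seed * 1_000 + i, genome_id=f"g{i:02d}",
        )
        specs = []
        if i < round(frac_rho * n):
            v = refs.set_tuning_codon(
                refs.mutate_dna(refs.rhodopsin_gene("L"), 0.06, rng), "L"
            )
            specs.append(MarkerSpec("rhodopsin", "PR", v, "+"))
        for fam, strand in (("recA", "+"), ("radA", "-")):
            specs.append(MarkerSpec(fam, fam,
                                    refs.mutate_dna(refs.marker_exemplar(fam), 0.06, rng),
                                    strand))
        genomes.append(implant_markers(g, specs))
    return genomes


def _refsets(genomes):
    out = {"rhodopsin": [], "recA": [], "radA": []}
    for g in genomes:
        for gene in g.genes:
            if gene.role in out:
                out[gene.role].append((f"{g.id}_{gene.role}", g.gene_sequence(gene)))
    return out


class TestRhodopsinsPerGenome:
    def test_single_copy_community_estimates_one(self):
        genomes = _marker_community(12, 1.0, seed=3)
        rs, _ = simulate_metagenome(genomes, np.full(12, 1 / 12), 15_000, seed=70)
        r = _refsets(genomes)
        est = rhodopsins_per_genome(rs, r["rhodopsin"], r["recA"], r["radA"])
        sigma = est.rhodopsins_per_genome * np.sqrt(
            1 / est.rhodopsin_read_count
            + 1 / (est.reca_read_count + est.rada_read_count)
        )
        assert est.rhodopsins_per_genome == pytest.approx(1.0, abs=max(3 * sigma, 0.1))

    def test_absent_rhodopsins_give_zero(self):
        genomes = _marker_community(6, 0.0, seed=4)
        donors = _marker_community(2, 1.0, seed=5)  # supply refs only
        rs, _ = simulate_metagenome(genomes, np.full(6, 1 / 6), 4_000, seed=71)
        r = _refsets(genomes)
        rho_refs = _refsets(donors)["rhodopsin"]
        est = rhodopsins_per_genome(rs, rho_refs, r["recA"], r["radA"])
        assert est.rhodopsins_per_genome == 0.0
        assert est.rhodopsin_read_count == 0

    def test_no_housekeeping_reads_is_error(self):
        genomes = _marker_community(2, 1.0, seed=6)
        rs = SampleReadSet("empty-ish", 0, "mixed", ["ACGT" * 40])
        r = _refsets(genomes)
        with pytest.raises(ValueError, match="recA/radA"):
            rhodopsins_per_genome(rs, r["rhodopsin"], r["recA"], r["radA"])

    def test_empty_reference_set_rejected(self):
        rs = SampleReadSet("s", 0, "mixed", ["ACGT" * 40])
        with pytest.raises(ValueError, match="non-empty"):
            rhodopsins_per_genome(rs, [], [("a", "ACGT" * 30)], [("b", "ACGT" * 30)])


class TestRhodopsinRecruit:
    def test_silent_gene_dropped_and_boundary_kept(self, small_study):
        """A gene recruiting nothing is dropped; the keep rule is inclusive."""
        from stratiprof.rhodopsin import RhodopsinGene

        genes = []
        for g in small_study.genomes[:2]:
            for gene in g.genes:
                if gene.role == "rhodopsin":
                    genes.append(
                        RhodopsinGene(
                            id=f"{g.id}_rho", source_contig=g.id,
                            sequence=g.gene_sequence(gene), protein="",
                            tuning_residue="L", spectral_class="green",
                        )
                    )
                    break
        rng = np.random.default_rng(7)
        silent = RhodopsinGene(
            id="zz_silent", source_contig="none",
            sequence=refs.random_dna(rng, 750), protein="",
            tuning_residue="Q", spectral_class="blue",
        )
        df = rhodopsin_recruit(small_study.samples, genes + [silent])
        assert "zz_silent" not in df.index
        assert len(df) >= 1

    def test_profile_peaks_at_host_niche_center(self, small_study):
        from stratiprof.rhodopsin import RhodopsinGene

        host = next(g for g in small_study.genomes if g.id == "g03")  # 45 m niche
        gene = next(x for x in host.genes if x.role == "rhodopsin")
        rho = RhodopsinGene(id="g03_rho", source_contig="g03",
                            sequence=host.gene_sequence(gene), protein="",
                            tuning_residue="L", spectral_class="green")
        strat = small_study.stratified_samples
        df = rhodopsin_recruit(strat, [rho])
        profile = df.loc["g03_rho"]
        best_sample = profile.idxmax()
        depth = next(s.depth_m for s in strat if s.sample_id == best_sample)
        assert depth == 45.0

    def test_exact_rpkg_boundary_inclusive(self):
        """10 reads x 100 bp, one matching a 500 bp gene: RPKG = 2e6 exactly;
        a keep threshold equal to that value retains the gene."""
        from stratiprof.rhodopsin import RhodopsinGene

        rng = np.random.default_rng(8)
        gene_seq = refs.random_dna(rng, 500)
        reads = [gene_seq[100:200]] + [refs.random_dna(rng, 100) for _ in range(9)]
        rs = SampleReadSet("s", 0, "mixed", reads)
        gene = RhodopsinGene(id="g", source_contig="c", sequence=gene_seq,
                             protein="", tuning_residue="L", spectral_class="green")
        df = rhodopsin_recruit([rs], [gene], keep_rpkg=2e6)
        assert df.loc["g", "s"] == pytest.approx(2e6)
        df2 = rhodopsin_recruit([rs], [gene], keep_rpkg=2e6 + 1)
        assert "g" not in df2.index
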