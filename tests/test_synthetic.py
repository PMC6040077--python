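"""Synthetic community generator: composition, niches, reads, truth tables."""

import numpy as np
import pytest
from scipy import stats

from stratiprof import references as refs
from stratiprof.binning import tnf
from stratiprof.core_io import Season, gc_content
from stratiprof.synthetic import (
    CompositionModel,
    GenomeSpec,
    MarkerSpec,
    NicheSpec,
    StudyConfig,
    default_study_config,
    depth_profile,
    generate_genome,
    implant_markers,
    make_study,
    simulate_metagenome,
)

STRAT = [15.0, 30.0, 45.0, 60.0, 75.0, 90.0]


class TestGenerateGenome:
    def test_gc_hits_realistic_target(self):
        g = generate_genome(200_000, CompositionModel(38.6, markov_order=2), seed=1)
        assert 36.6 <= gc_content(g.sequence) <= 40.6

    def test_deterministic_given_seed(self):
        a = generate_genome(20_000, CompositionModel(45.0), seed=9)
        b = generate_genome(20_000, CompositionModel(45.0), seed=9)
        assert a.sequence == b.sequence

    def test_order0_gc_matches_binomial_expectation(self):
        # 1 Mb draw at p(GC)=0.5: 3 sigma of the binomial is ~0.15%
        g = generate_genome(1_000_000, CompositionModel(50.0, markov_order=0), seed=2)
        assert gc_content(g.sequence) == pytest.approx(50.0, abs=0.5)

    @pytest.mark.parametrize("bad_gc", [0.0, 100.0, -5.0, 120.0])
    def test_infeasible_gc_rejected(self, bad_gc):
        with pytest.raises(ValueError):
            CompositionModel(bad_gc)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="10 kb"):
            generate_genome(5_000, CompositionModel(50.0), seed=0)

    def test_composition_separation_enables_binning(self):
        # genomes 10 GC points apart: inter-genome TNF distance must exceed
        # the within-genome window-to-window distance
        a = generate_genome(60_000, CompositionModel(35.0, markov_order=2), seed=3)
        b = generate_genome(60_000, CompositionModel(45.0, markov_order=2), seed=4)
        ta, tb = tnf(a.sequence), tnf(b.sequence)
        inter = np.linalg.norm(ta - tb)
        wins = [tnf(a.sequence[i : i + 20_000]) for i in range(0, 60_000, 20_000)]
        intra = max(np.linalg.norm(w - ta) for w in wins)
        assert inter > intra


class TestDepthProfile:
    def test_zero_width_is_indicator_at_nearest_depth(self):
        v = depth_profile(NicheSpec("g", 45.0, 0.0, 1.0), STRAT)
        assert v[2] == 1.0 and v.sum() == 1.0

    def test_flat_profile_equal_everywhere(self):
        v = depth_profile(NicheSpec("g", flat=True, peak_relative_abundance=0.4), STRAT)
        assert np.allclose(v, 0.4)

    def test_symmetric_about_center(self):
        v = depth_profile(NicheSpec("g", 45.0, 10.0, 1.0), [30.0, 45.0, 60.0])
        assert v[0] == pytest.approx(v[2]) and v[1] == v.max()

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError):
            NicheSpec("g", 45.0, -1.0)

    def test_empty_depths_rejected(self):
        with pytest.raises(ValueError):
            depth_profile(NicheSpec("g"), [])


class TestImplantMarkers:
    def test_markers_recorded_and_recoverable(self):
        g = generate_genome(20_000, CompositionModel(42.0), seed=5)
        specs = [
            MarkerSpec("recA", "recA", refs.marker_exemplar("recA"), "+"),
            MarkerSpec("radA", "radA", refs.marker_exemplar("radA"), "-"),
            MarkerSpec("rhodopsin", "PR", refs.rhodopsin_gene("L"), "+"),
        ]
        out = implant_markers(g, specs)
        assert len(out.genes) == 3
        assert len(out) == len(g)
        for gene, spec in zip(out.genes, specs):
            assert out.gene_sequence(gene) == spec.sequence
            assert gene.role == spec.role

    def test_overfull_genome_rejected(self):
        g = generate_genome(10_000, CompositionModel(42.0), seed=6)
        specs = [
            MarkerSpec("other", f"x{i}", refs.marker_exemplar(f"other:{i}"), "+")
            for i in range(30)
        ]
        with pytest.raises(ValueError, match="without overlap"):
            implant_markers(g, specs)


@pytest.fixture(scope="module")
def two_genomes():
    return [
        generate_genome(20_000, CompositionModel(40.0), seed=11, genome_id="a"),
        generate_genome(20_000, CompositionModel(50.0), seed=12, genome_id="b"),
    ]


class TestSimulateMetagenome:
    def test_zero_error_reads_are_exact_substrings(self, two_genomes):
        rs, truth = simulate_metagenome(two_genomes, [0.5, 0.5], 200,
                                        error_rate=0.0, seed=1)
        by_id = {g.id: g.sequence for g in two_genomes}
        from stratiprof.core_io import reverse_complement
        for read, (src, pos) in zip(rs.reads, truth.itertuples(index=False)):
            frag = by_id[src][pos : pos + 150]
            assert read in (frag, reverse_complement(frag))

    def test_degenerate_abundance_uses_single_genome(self, two_genomes):
        _, truth = simulate_metagenome(two_genomes, [1.0, 0.0], 100, seed=2)
        assert set(truth["source_genome"]) == {"a"}

    def test_read_counts_match_binomial_oracle(self, two_genomes):
        # equal abundance and length: counts ~ Bin(10000, 0.5)
        _, truth = simulate_metagenome(two_genomes, [0.5, 0.5], 10_000, seed=3)
        n_a = (truth["source_genome"] == "a").sum()
        sigma = np.sqrt(10_000 * 0.25)
        assert abs(n_a - 5_000) <= 3 * sigma

    def test_error_rate_matches_binomial_identity_model(self, two_genomes):
        # mismatch counts vs truth fragment follow Bin(150, e)
        e = 0.01
        rs, truth = simulate_metagenome(two_genomes, [1.0, 0.0], 2_000,
                                        error_rate=e, seed=4)
        from stratiprof.core_io import reverse_complement
        seq = two_genomes[0].sequence
        frac_ok = 0
        for read, (_, pos) in zip(rs.reads, truth.itertuples(index=False)):
            frag = seq[pos : pos + 150]
            mm = min(
                sum(a != b for a, b in zip(read, frag)),
                sum(a != b for a, b in zip(read, reverse_complement(frag))),
            )
            frac_ok += mm <= 1
        expected = stats.binom.cdf(1, 150, e)
        sigma = np.sqrt(expected * (1 - expected) / 2_000)
        assert frac_ok / 2_000 == pytest.approx(expected, abs=3 * sigma)

    def test_invalid_inputs_rejected(self, two_genomes):
        with pytest.raises(ValueError):
            simulate_metagenome(two_genomes, [0.5, 0.5], 0, seed=0)
        with pytest.raises(ValueError):
            simulate_metagenome(two_genomes, [0.5, 0.5], 10, error_rate=0.5, seed=0)
        with pytest.raises(ValueError):
            simulate_metagenome(two_genomes, [0.9, 0.3], 10, seed=0)


class TestMakeStudy:
    def test_default_study_layout(self, small_study):
        depths = {
            (s.season.value, s.depth_m) for s in small_study.samples
        }
        assert depths == {("stratified", d) for d in STRAT} | {
            ("mixed", 20.0), ("mixed", 80.0)
        }
        assert len(small_study.genomes) == 12

    def test_truth_classes_follow_niche_design(self, small_study):
        dc = small_study.truth["depth_class"]
        occ = small_study.truth["occupancy"]
        assert (dc.loc[[f"g{i:02d}" for i in range(1, 9)]] == "stenobathic").all()
        assert (dc.loc[["g09", "g10"]] == "eurybathic").all()
        assert (occ.loc[["g09", "g10"]] == "always").all()
        assert (occ.loc[["g11", "g12"]] == "winter_only").all()

    def test_abundance_columns_normalized(self, small_study):
        ab = small_study.truth["abundances"]
        assert np.allclose(ab.sum(axis=0), 1.0)

    def test_determinism_bytewise(self):
        cfg = default_study_config(n_reads_per_sample=300)
        s1 = make_study(cfg, seed=42)
        s2 = make_study(cfg, seed=42)
        assert s1.genomes[0].sequence == s2.genomes[0].sequence
        assert s1.samples[3].reads == s2.samples[3].reads

    def test_mismatched_niche_ids_rejected(self):
        cfg = default_study_config()
        with pytest.raises(ValueError, match="must match"):
            StudyConfig(genomes=cfg.genomes, niches=cfg.niches[:-1])
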