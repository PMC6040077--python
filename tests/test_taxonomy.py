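"""16S reference clustering, detection cascade, tables, and diversity."""

import numpy as np
import pytest

from stratiprof import references as refs
from stratiprof.core_io import SampleReadSet
from stratiprof.taxonomy import (
    abundance_table,
    build_reference,
    classify_fragment,
    detect_candidates,
    global_identity,
    simpson_diversity,
    verify_candidates,
)


@pytest.fixture(scope="module")
def reference():
    return build_reference([(s, t) for t, s in refs.synthetic_16s_family()])


@pytest.fixture(scope="module")
def profiles():
    return refs.domain_profiles()


class TestBuildReference:
    def test_identical_sequences_collapse(self):
        seq = refs.synthetic_16s_family()[0][1]
        ref = build_reference([(seq, ("B",)), (seq, ("B",))])
        assert len(ref) == 1

    def test_distant_pair_stays_separate(self):
        fam = refs.synthetic_16s_family()
        a, b = fam[0][1], fam[-1][1]  # different domains, ~<80% identity
        assert global_identity(a, b) < 90.0
        ref = build_reference([(a, ("A",)), (b, ("B",))])
        assert len(ref) == 2

    def test_unlabeled_sequence_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            build_reference([("ACGT" * 100, ())])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_reference([])

    def test_cluster_count_matches_allpairs_oracle(self, reference):
        """For well-separated inputs, greedy clustering keeps every input:
        brute-force all-pairs identity is the oracle."""
        fam = refs.synthetic_16s_family()
        n = len(fam)
        for i in range(n):
            for j in range(i + 1, n):
                assert global_identity(fam[i][1], fam[j][1]) < 90.0
        assert len(reference) == n
        # permutation leaves the count unchanged
        perm = build_reference([(s, t) for t, s in reversed(fam)])
        assert len(perm) == n


def _readset(reads):
    return SampleReadSet("s", 0, "mixed", reads)


class TestDetectCandidates:
    def test_true_fragment_detected(self, reference):
        frag = refs.synthetic_16s_family()[3][1][200:350]
        idx = detect_candidates(_readset([frag]), reference)
        assert idx == [0]

    def test_random_reads_never_pass_screen(self, reference):
        rng = np.random.default_rng(13)
        reads = [refs.random_dna(rng, 150, gc=0.40) for _ in range(1000)]
        assert detect_candidates(_readset(reads), reference) == []

    def test_short_read_skipped(self, reference):
        frag = refs.synthetic_16s_family()[0][1][100:130]  # 30 bp < 40
        assert detect_candidates(_readset([frag]), reference) == []


class TestVerifyCandidates:
    def test_true_fragment_verified_with_correct_domain(self, reference, profiles):
        fam = refs.synthetic_16s_family()
        reads = [fam[0][1][300:450], fam[-1][1][300:450]]  # Bacteria, Eukaryota
        rs = _readset(reads)
        ver = verify_candidates(rs, [0, 1], profiles)
        assert ver.get(0) == "Bacteria" and ver.get(1) == "Eukaryota"

    def test_shuffled_fragments_rejected_at_calibrated_cutoff(self, profiles):
        """Mononucleotide shuffles keep composition but lose positional
        signal: at the 1% calibrated cutoff at most a few percent pass."""
        rng = np.random.default_rng(14)
        fam = refs.synthetic_16s_family()
        shuffled = []
        for _ in range(300):
            seq = fam[rng.integers(len(fam))][1]
            off = int(rng.integers(0, len(seq) - 150))
            frag = list(seq[off : off + 150])
            rng.shuffle(frag)
            shuffled.append("".join(frag))
        rs = _readset(shuffled)
        ver = verify_candidates(rs, list(range(300)), profiles)
        assert len(ver) / 300 <= 0.03

    def test_fragment_shorter_than_window_rejected(self, profiles):
        frag = refs.synthetic_16s_family()[0][1][100:150]  # 50 bp < 60
        ver = verify_candidates(_readset([frag]), [0], profiles)
        assert ver == {}


class TestClassifyFragment:
    def test_identity_and_length_thresholds(self, reference, mutator):
        tax, seq = refs.synthetic_16s_family()[2]
        base = seq[400:500]  # 100 bp
        # 15 substitutions -> 85% identity: classified
        assert classify_fragment(mutator(base, list(range(0, 90, 6))), reference)
        # 80 bp at high identity: discarded on length
        assert classify_fragment(seq[400:480], reference) is None
        # 21 substitutions -> 79% identity: discarded
        assert (
            classify_fragment(mutator(base, list(range(0, 84, 4))), reference) is None
        )

    def test_correct_lineage_assigned(self, reference):
        tax, seq = refs.synthetic_16s_family()[5]
        assert classify_fragment(seq[650:800], reference) == tax


class TestAbundanceTable:
    def test_percentages_and_other_folding(self):
        lineages = (
            [("Bacteria", "Cyanobacteria", "Cyanophyceae")] * 60
            + [("Bacteria", "Bacteroidetes", "Flavobacteriia")] * 39
            + [("Archaea", "Euryarchaeota", "Thermoplasmata")] * 1
        )
        full, display = abundance_table({"s1": lineages, "s2": lineages})
        assert full["s1"].sum() == pytest.approx(100.0)
        assert full.loc["Cyanobacteria", "s1"] == pytest.approx(60.0)
        # 1% taxon is kept (>= 1% rule is inclusive)
        assert "Euryarchaeota" in display.index

    def test_sub_percent_taxon_folded_into_other(self):
        lineages = [("Bacteria", "Cyanobacteria", "Cyanophyceae")] * 995 + [
            ("Bacteria", "Chloroflexi", "Anaerolineae")
        ] * 5
        _, display = abundance_table({"s1": lineages})
        assert "Chloroflexi" not in display.index
        assert display.loc["other", "s1"] == pytest.approx(0.5)

    def test_proteobacteria_split_to_class(self):
        lineages = [
            ("Bacteria", "Proteobacteria", "Alphaproteobacteria"),
            ("Bacteria", "Proteobacteria", "Gammaproteobacteria"),
        ]
        full, _ = abundance_table({"s1": lineages})
        assert "Proteobacteria" not in full.index
        assert set(full.index) == {"Alphaproteobacteria", "Gammaproteobacteria"}

    def test_empty_sample_warns_and_gives_na(self):
        with pytest.warns(UserWarning, match="no classified"):
            full, _ = abundance_table({"s1": [], "s2": [("Bacteria", "X", "Y")]})
        assert full["s1"].sum() == 0.0


class TestSimpson:
    @pytest.mark.parametrize(
        "p,expected",
        [([1.0], 0.0), ([0.25] * 4, 0.75), ([0.5, 0.5], 0.5)],
    )
    def test_values(self, p, expected):
        assert simpson_diversity(p) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            simpson_diversity([1.2, -0.2])

    def test_monotone_in_richness(self):
        prev = -1.0
        for k in range(1, 10):
            d = simpson_diversity([1.0 / k] * k)
            assert d > prev
            prev = d

    def test_matches_skbio_gini_simpson(self):
        from skbio.diversity.alpha import simpson

        counts = np.array([5, 3, 9, 1, 7])
        assert simpson_diversity(counts / counts.sum()) == pytest.approx(
            simpson(counts)
        )
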