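"""Synthetic reference sets bundled with the package.

Everything in this module is *synthetic*: deterministic sequence families
generated at import/call time from fixed seeds, standing in for curated
databases (an rRNA reference set, housekeeping-gene exemplars, a rhodopsin
exemplar with its spectral-tuning position, universal single-copy marker
catalogs). The 16S/18S family is built by descent from a common ancestor
with conserved and variable position classes, so all members are mutually
aligned by construction and positional profiles need no external aligner.

The families are versioned implicitly by their seeds: changing a seed
changes every downstream reference, so the seeds here are treated as part
of the package's public contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype="S1")
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_FAMILY_SEED = 20151015  # fixed: part of the reference contract

# (domain, phylum, class) leaves of the synthetic 16S/18S family.  One leaf
# per class keeps greedy 90%-identity clustering from merging taxa.
REFERENCE_TAXA: list[tuple[str, str, str]] = [
    ("Bacteria", "Proteobacteria", "Alphaproteobacteria"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria"),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria"),
    ("Bacteria", "Cyanobacteria", "Cyanophyceae"),
    ("Bacteria", "Bacteroidetes", "Flavobacteriia"),
    ("Bacteria", "Bacteroidetes", "Sphingobacteriia"),
    ("Bacteria", "Actinobacteria", "Acidimicrobiia"),
    ("Bacteria", "Verrucomicrobia", "Verrucomicrobiae"),
    ("Bacteria", "Chloroflexi", "Anaerolineae"),
    ("Bacteria", "Firmicutes", "Bacilli"),
    ("Archaea", "Thaumarchaeota", "Nitrososphaeria"),
    ("Archaea", "Euryarchaeota", "Thermoplasmata"),
    ("Archaea", "Euryarchaeota", "Halobacteria"),
    ("Eukaryota", "Chlorophyta", "Mamiellophyceae"),
    ("Eukaryota", "Haptophyta", "Prymnesiophyceae"),
]

RRNA_LENGTH = 1200
#: fraction of positions treated as evolutionarily conserved
_CONSERVED_FRACTION = 0.6
# per-branch substitution probabilities (variable, conserved positions)
_RATES = {"domain": (0.50, 0.06), "phylum": (0.30, 0.02), "class": (0.18, 0.01)}


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return b"".join(rng.choice(BASES, size=length, p=p)).decode()


def mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation at i.i.d. per-base rate (to a different base)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([choices[rng.integers(3)]])
    return arr.tobytes().decode()


def _mutate_masked(
    seq: np.ndarray, mask_var: np.ndarray, rate_var: float, rate_cons: float,
    rng: np.random.Generator,
) -> np.ndarray:
    rates = np.where(mask_var, rate_var, rate_cons)
    hit = rng.random(seq.size) < rates
    out = seq.copy()
    for i in np.nonzero(hit)[0]:
        choices = [b for b in b"ACGT" if bytes([b]) != out[i]]
        out[i] = bytes([choices[rng.integers(3)]])
    return out


@lru_cache(maxsize=None)
def synthetic_16s_family() -> list[tuple[tuple[str, str, str], str]]:
    """The bundled small-subunit rRNA reference family (synthetic).

    Returns one (taxonomy, sequence) pair per leaf in REFERENCE_TAXA; all
    sequences are positionally aligned (equal length, substitution-only
    descent from one ancestor).
    """
    rng = np.random.default_rng(_FAMILY_SEED)
    ancestor = np.frombuffer(random_dna(rng, RRNA_LENGTH).encode(), dtype="S1").copy()
    mask_var = rng.random(RRNA_LENGTH) >= _CONSERVED_FRACTION

    domains: dict[str, np.ndarray] = {}
    for dom in ("Bacteria", "Archaea", "Eukaryota"):
        domains[dom] = _mutate_masked(ancestor, mask_var, *_RATES["domain"], rng)
    phyla: dict[tuple[str, str], np.ndarray] = {}
    out: list[tuple[tuple[str, str, str], str]] = []
    for dom, phy, cls in REFERENCE_TAXA:
        if (dom, phy) not in phyla:
            phyla[(dom, phy)] = _mutate_masked(domains[dom], mask_var, *_RATES["phylum"], rng)
        leaf = _mutate_masked(phyla[(dom, phy)], mask_var, *_RATES["class"], rng)
        out.append(((dom, phy, cls), leaf.tobytes().decode()))
    return out


def family_sequence(taxonomy: tuple[str, str, str]) -> str:
    for tax, seq in synthetic_16s_family():
        if tax == taxonomy:
            return seq
    raise KeyError(f"taxonomy {taxonomy} not in reference family")


# ---------------------------------------------------------------------------
# Housekeeping / marker gene exemplars (synthetic)
# ---------------------------------------------------------------------------

RECA_LENGTH = 1047
RADA_LENGTH = 1047
MARKER_GENE_LENGTH = 450


@lru_cache(maxsize=None)
def marker_exemplar(family: str) -> str:
    """Deterministic synthetic nucleotide exemplar for a marker family.

    Recognised families: 'recA', 'radA', and any universal single-copy
    marker name (e.g. 'uscg007').
    """
    length = {"recA": RECA_LENGTH, "radA": RADA_LENGTH}.get(family, MARKER_GENE_LENGTH)
    digest = hashlib.sha256(f"marker:{family}".encode()).digest()
    seed = int.from_bytes(digest[:4], "little") % (2**31)
    rng = np.random.default_rng(seed)
    return random_dna(rng, length, gc=0.45)


def marker_catalog(size: int = 35) -> list[str]:
    """Universal single-copy marker catalogs (35- and 111-family defaults)."""
    if size not in (35, 111):
        raise ValueError("marker catalogs are defined for sizes 35 and 111")
    return [f"uscg{i:03d}" for i in range(1, size + 1)]


# ---------------------------------------------------------------------------
# Rhodopsin exemplar (synthetic) and spectral tuning convention
# ---------------------------------------------------------------------------

RHODOPSIN_AA_LENGTH = 249
#: 0-based index of the spectral-tuning residue in the exemplar protein
TUNING_POSITION = 104
#: residue -> absorption class at the tuning position
TUNING_RULE = {"L": "green", "Q": "blue"}

_CODON = {  # one deterministic codon per amino acid (reverse translation)
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


@lru_cache(maxsize=None)
def rhodopsin_exemplar_protein() -> str:
    """Synthetic rhodopsin exemplar protein; tuning residue left as 'L'."""
    rng = np.random.default_rng(_FAMILY_SEED + 1)
    aa = [AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), RHODOPSIN_AA_LENGTH)]
    aa[0] = "M"
    aa[TUNING_POSITION] = "L"
    return "".join(aa)


def rhodopsin_gene(tuning: str = "L") -> str:
    """Nucleotide exemplar of the rhodopsin gene with the given tuning residue."""
    prot = list(rhodopsin_exemplar_protein())
    prot[TUNING_POSITION] = tuning
    return "".join(_CODON[a] for a in prot)


def set_tuning_codon(gene_nt: str, tuning: str) -> str:
    """Overwrite the tuning codon of a rhodopsin gene variant (frame 0)."""
    i = TUNING_POSITION * 3
    return gene_nt[:i] + _CODON[tuning] + gene_nt[i + 3 :]


# ---------------------------------------------------------------------------
# Domain verification profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainProfile:
    """Positional log-odds profile of one domain's rRNA family.

    Members are the domain's family sequences; because the family is
    positionally aligned by construction, an infix placement of a read on
    any member gives the read's column offset in the profile directly.
    """

    domain: str
    consensus: str
    members: tuple[str, ...]
    log_odds: np.ndarray  # shape (4, L), base order ACGT
    cutoff: float  # mean per-column log-odds a read must reach

    @property
    def length(self) -> int:
        return len(self.consensus)


_B2I = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T byte -> row


def _profile_from(members: list[str], pseudocount: float = 0.8):
    L = len(members[0])
    counts = np.full((4, L), pseudocount)
    for seq in members:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for b, row in _B2I.items():
            counts[row, arr == b] += 1
    probs = counts / counts.sum(axis=0, keepdims=True)
    log_odds = np.log(probs / 0.25)
    consensus = b"".join(BASES[i] for i in probs.argmax(axis=0)).decode()
    return consensus, log_odds


def score_fragment(fragment: str, profile: DomainProfile, offset: int) -> float:
    """Mean per-column log-odds of a fragment placed at `offset` on the profile."""
    arr = np.frombuffer(fragment.encode(), dtype=np.uint8)
    end = min(offset + arr.size, profile.length)
    if offset < 0 or end <= offset:
        return -np.inf
    cols = np.arange(offset, end)
    rows = np.array([_B2I.get(b, -1) for b in arr[: end - offset]])
    ok = rows >= 0
    if not ok.any():
        return -np.inf
    return float(profile.log_odds[rows[ok], cols[ok]].mean())


@lru_cache(maxsize=None)
def domain_profiles(
    fragment_length: int = 150, null_draws: int = 600, fp_rate: float = 0.01
) -> dict[str, DomainProfile]:
    """Build per-domain verification profiles with a shuffle-calibrated cutoff.

    The cutoff is the (1 - fp_rate) quantile of mean log-odds scores of
    mononucleotide-shuffled family fragments placed at their true offsets —
    i.e. at most `fp_rate` of composition-matched non-rRNA fragments pass.
    """
    fam = synthetic_16s_family()
    by_domain: dict[str, list[str]] = {}
    for (dom, _, _), seq in fam:
        by_domain.setdefault(dom, []).append(seq)

    profiles: dict[str, DomainProfile] = {}
    raw = {dom: _profile_from(members) for dom, members in by_domain.items()}

    rng = np.random.default_rng(_FAMILY_SEED + 2)
    null_scores: list[float] = []
    seqs = [s for _, s in fam]
    tmp = {
        d: DomainProfile(d, c, tuple(by_domain[d]), lo, -np.inf)
        for d, (c, lo) in raw.items()
    }
    from .taxonomy import _best_profile_score  # placement shared with verify

    for _ in range(null_draws):
        src = seqs[rng.integers(len(seqs))]
        off = int(rng.integers(0, len(src) - fragment_length + 1))
        frag = list(src[off : off + fragment_length])
        rng.shuffle(frag)
        frag = "".join(frag)
        null_scores.append(_best_profile_score(frag, tmp)[0])
    cutoff = float(np.quantile(null_scores, 1 - fp_rate))

    for dom, (cons, lo) in raw.items():
        profiles[dom] = DomainProfile(dom, cons, tuple(by_domain[dom]), lo, cutoff)
    return profiles
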