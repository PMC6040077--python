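# Methods

This note documents the models and procedures implemented in `stratiprof`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Recruitment and the RPKG statistic

A read recruits to a genome when its best local placement reaches
`min_identity` (default 99%) over at least `min_aln_len` (default 50)
aligned bases; both strands are searched and each read is counted once for
its best-hit genome, with ties broken by lexicographic genome id so reruns
are deterministic. All keep-thresholds are inclusive (≥ 99%, ≥ 50 bp,
RPKG ≥ 3).

*Identity convention.* Identity is computed as
100 · (read length − edit distance) / read length from an infix alignment
of the full read in the genome. For the substitution-dominated alignments
this pipeline deals in (reads are simulated without indels, and real short
reads at ≥ 99% identity contain at most one or two edits), this equals
matches / alignment columns, the convention of mainstream aligners. The
full-read infix contract means a read must be alignable end-to-end inside
the reference; reads hanging over contig ends are not recovered, a
negligible loss at 150 bp against ≥ 10 kb references.

*Implementation.* The recruiter is seed-and-verify: exact 21-mers at five
probe offsets (both strands) locate candidate loci, and edlib verifies each
distinct (genome, locus, strand) placement inside a small window with the
edit-distance ceiling implied by the identity threshold. Missing a true
placement requires every error-free probe k-mer to be absent from the
index, which at ≥ 99% identity is vanishingly rare and unbiased across
genomes. rRNA regions are not masked before recruitment; conserved rRNA
stretches can in principle recruit reads across taxa, which the best-hit
rule and the 99% filter keep to a negligible rate (measured, not assumed:
the specificity benchmark scores every recruited read against the
simulator's truth).

RPKG = count / (genome kb) / (metagenome Gb), with the metagenome size
taken as total sequenced bases of the sample, not read count. A genome is
*present* where RPKG ≥ 3 and *retained* if present in ≥ 1 sample.

*Depth classes.* Over the sorted stratified series: absent (no depth),
stenobathic (one depth, or two adjacent), eurybathic (all depths),
intermediate (anything else). Two occupied depths separated by a
sub-threshold dip are intermediate, not stenobathic — strict adjacency.
Seasonal occupancy compares any-presence in the stratified series against
any-presence in the mixed pair: always / stratified_only / winter_only /
absent.

## Synthetic studies and their truth tables

The generator emulates the study design the pipeline targets: six
stratified samples at 15, 30, 45, 60, 75, 90 m and a mixed winter pair at
20 and 80 m, default 150 bp reads.

- **Composition.** Each genome is drawn from an order-k Markov chain
  (k ≤ 3, default 2) whose per-context weights are randomly perturbed per
  genome (log-normal, scale 0.6) and then tilted by bisection so the
  chain's stationary GC equals the target; realized GC of a 100 kb draw
  sits well within ±2 GC points of target. The perturbation gives genomes
  distinct tetranucleotide signatures even at equal GC.
- **Niches.** Gaussian in depth: abundance ∝ exp(−(d−c)²/2σ²), with σ = 0
  collapsing to an indicator at the nearest sampled depth and a flat flag
  for depth-independent (eurybathic) taxa. A winter-only taxon has
  stratified peak 0 and positive mixed abundance. Per-sample community
  abundances are normalized to sum to 1.
- **Reads.** Length-weighted multinomial sampling of (genome, position,
  strand), i.i.d. substitution errors at `error_rate` (default 0.002, no
  indels — so identity arithmetic is exact), reads with > 10% N redrawn.
  Every read's source genome and position are recorded.
- **Markers.** Each genome receives per-genome diverged variants (default
  6% substitution) of shared synthetic exemplars: one rRNA copy (2%
  diverged from its taxon's reference leaf), recA and radA (1047 bp), 0–2
  rhodopsins (747 bp) with a declared tuning codon re-imposed after
  divergence, the 35-family single-copy catalog (450 bp each), GH and
  filler genes. Markers are placed evenly spaced, non-overlapping,
  alternating strands, replacing background sequence.
- **Truth labels.** Depth-range and occupancy truth is obtained by applying
  the presence rule and classifiers to the *exact expected* RPKG implied by
  the configuration (noise-free arithmetic), not to niche geometry alone: a
  wide Gaussian's tail can legitimately exceed 3 RPKG at a third depth, and
  a truth label that ignored this would be self-inconsistent. The default
  stenobathic niches use σ = 3 m (on-grid centers) and σ = 4 m (mid-grid
  centers), for which the expected profile is genuinely one or two adjacent
  depths.

Default study: 12 genomes × 60 kb — eight stenobathic, two eurybathic
(also present in winter), two winter-only — with GC spread 36–53.5% and
distinct reference taxa per genome. The benchmark tier runs 20 000 reads
per sample; this is a desk-scale stand-in for multi-Gb metagenomes chosen
so the dominant genome reaches ~50× coverage and presence calls are far
from the threshold.

*What the generator does not emulate:* indels and quality profiles,
paired-end structure, strain microdiversity clouds, chimeras, uneven
coverage (GC bias), and genuinely novel taxa absent from the reference
family. Passing benchmarks therefore demonstrate the correctness of the
statistics and the recovery machinery under the stated error model, not
performance on real assemblies of high-microdiversity populations.

## Bundled reference sets

All reference material is synthetic and generated deterministically at run
time from fixed seeds that are part of the package contract
(`stratiprof.references`); per-family seeds derive from SHA-256 of the
family name, so families are mutually independent.

The rRNA family descends from one 1200 bp ancestor through
domain → phylum → class branches with separate substitution rates for
conserved (60%) and variable positions; one leaf per class, 15 leaves over
three domains, pairwise identity ≤ 87.6%. Because descent is
substitution-only, all members are positionally aligned by construction —
the family is its own multiple alignment.

The rhodopsin exemplar is a 249-aa synthetic protein with the
spectral-tuning residue fixed at position 105 (1-based); L → green,
Q → blue, anything else unknown. Nucleotide exemplars reverse-translate
with a fixed codon per amino acid.

## 16S cascade

1. **Detect** (recall-oriented): candidate iff the full read places at
   ≥ 70% identity on some reference centroid, read ≥ 40 bp. This replaces a
   database-size-dependent E-value screen with an identity screen at
   equivalent permissiveness.
2. **Verify** (precision-oriented): the read is placed by infix alignment
   against each domain's family members (member offset = profile column
   offset) and scored as mean per-column log-odds against the domain's
   positional base-frequency profile (pseudocount 0.8). The cutoff is
   calibrated once, at profile build, as the 99th percentile of scores of
   mononucleotide-shuffled family fragments — composition-matched nulls —
   so ≤ 1% of non-rRNA look-alikes pass. Fragments under 60 bp are
   rejected (too few columns for a stable score).
3. **Classify**: best-identity centroid at ≥ 80% identity over ≥ 90
   aligned bases; the centroid's full lineage is assigned and tables are
   cut at the requested rank. Reference building is greedy
   centroid clustering in input order at a 90% identity radius.

Abundance tables report percent of classified fragments; at phylum rank
Proteobacteria is expanded to class resolution (flag-controlled); display
tables keep taxa ≥ 1% in ≥ 1 sample and fold the remainder into "other".
Diversity is the Gini–Simpson index D = 1 − Σpᵢ², bounded [0, 1).

## Sample similarity and clustering

Two samples are compared by the fraction of reads of one with a qualifying
match among the reads of the other — ≥ 95% identity over an overlap of
≥ 50 bases — computed reciprocally on seeded subsets and averaged. Matching
is seeded by shared 15-mers and scored by Hamming identity over the implied
ungapped overlap; under the substitution-only error model this is exact,
and it reproduces the intended boundary behaviors (self-similarity 1 at
zero error; containment asymmetry). End-to-end alignment of reads sampled
at shifted positions would score near zero for every pair and carry no
signal. Reads shorter than 50 bp are excluded before subsetting.

The similarity matrix is clustered with complete linkage (flag-exposed) on
euclidean distances between its rows; rows are sorted by sample id first,
so the dendrogram is invariant to input order. Newick output carries branch
lengths.

## Binning

Contigs ≥ 1 kb are featurized: canonical TNF (4-mers pooled with their
reverse complements, 136 keys, N-containing 4-mers skipped, normalized to
sum 1), GC, and per-sample log10(coverage + 0.1). TNF columns are
standardized and projected by PCA (component signs fixed by the largest
loading); GC and coverage join as standardized axes. Contigs ≥ 10 kb
receive a taxon label when strictly > 50% of their genes agree; binning
then runs DBSCAN within each taxon group (unclassified is its own group).

The original procedure this codifies was interactive inspection of PCA
plots; an automatic analogue needs a radius, and a fixed eps cannot serve
both well-separated multi-genome groups (tiny within-cluster spacing) and
a lone genome whose standardized noise spans unit scale. With `eps=None`
the radius comes from the classic k-dist heuristic — twice the median
distance to the min_pts-th neighbor, floored at 0.5 — computed per group.
Using the min_pts-th neighbor (not the first) keeps the estimate meaningful
when contigs are duplicated. Identically composed genomes can still merge
into one bin; that failure mode is deliberate and is flagged by the marker
screen: completeness = 100 · |distinct catalog families| / |catalog|,
contamination = 100 · (extra copies beyond the first) / |catalog| — a
simplified duplicated-marker estimator in the spirit of standard MAG QC
tools, against 35- or 111-family catalogs.

## Rhodopsins

Detection translates all six frames of contigs ≥ 5 kb and places the
exemplar protein by infix alignment at ≥ 60% identity over its full
length; overlapping hits keep the best. The spectral class reads the
residue aligned to the exemplar's tuning position (global protein
alignment, 40% identity floor): L → green, Q → blue, else unknown;
synonymous nucleotide changes cannot affect it.

The per-genome abundance estimator normalizes rhodopsin recruitment by
recA+radA recruitment. Because recA and radA are universal and single-copy,
their read density estimates total genome coverage, and the ratio of
length-normalized densities is rhodopsin gene copies per genome:

estimate = (rhodopsin reads / eff_rho) / ((recA+radA reads) / (eff_recA + eff_radA))

where eff = mean gene length + mean read length − 2·min_aln_len + 1 is the
per-gene *effective length* — the number of read start positions that can
produce a qualifying ≥ 50 bp overlap. Normalizing by per-gene effective
length (rather than summed reference length, which cancels the gene count
and always returns ≈ 1) makes the estimator unbiased under length-weighted
sampling; the synthetic benchmarks recover the 1.0 and 0.65
copies-per-genome regimes within binomial error. Reads best-hitting an
optional viral/eukaryotic exclusion reference are discarded; a sample with
zero recA/radA reads raises (too shallow to normalize). Per-gene
recruitment profiles use the same overlap contract at ≥ 99%/50 bp, RPKG
with the gene length in the denominator, and an inclusive ≥ 1 RPKG keep
rule.

## Functional profiles

EQ = 1000 · GH genes / genes analyzed, per taxon and sample group; genes
count only on contigs ≥ 5 kb. NORM = EQ · (taxon 16S share / 100): the
text defining NORM names the normalizer but not the operator, and
multiplication (community-weighted contribution) is used because NORM is
presented as a community-level quantity; division would inflate rare taxa.
Both modes are exposed (`mode="divide"`). Sample groups default to
UP = {15, 30}, DCM = {45, 60}, LP = {75, 90}, MIX = {20, 80} (meters) and
are configurable. Category matrices are row-standardized with the n−1
denominator; zero-variance rows become NA with a warning.

## Environmental metrics

N:P = total N / total P (µM), reported rounded half-away-from-zero to two
decimals. Recomputing the bundled water-column table from its printed
Total N and Total P reproduces the stratified-series and 1000 m columns
exactly; the two winter columns differ by up to 0.8 because the printed
ratios there were evidently computed from unrounded measurements — the
tests pin only the exactly reproducible columns and bound the winter
discrepancy. Cytometry: N = (n · 1000)/(q · t) cells/mL with q in µL/min
and t in minutes; a seconds→minutes helper is provided since acquisitions
are usually quoted in seconds.

## Numerical and testing choices

- All randomness flows from explicit seeds (numpy Generator); study
  generation is byte-reproducible.
- Benchmark problem sizes (package defaults): 5 seeds × 8 samples ×
  20 000 reads for recovery/specificity; 2 samples × 6 000 reads for the
  16S cascade; 3 × 200 kb genomes in 20 kb windows for binning; 10 seeds ×
  12 000 reads per rhodopsin regime. Statistical assertions use 3σ bounds
  computed from the realized counts, never fixed margins.
- Property tests (hypothesis, derandomized) cover GC reverse-complement
  invariance, TNF canonicalization, RPKG linearity, and N:P scale
  invariance. scikit-bio's Gini–Simpson implementation serves as an
  independent cross-check of the diversity formula.

## Known limitations

- The recruiter's full-read infix contract under-counts reads at contig
  edges and does not model paired-end information.
- The 16S verification profile is built from the bundled synthetic family;
  with a user-supplied real reference the profile step requires the
  reference to be aligned (or falls back to the consensus of a cluster).
- Binning uses a single global projection; very uneven bin sizes or
  coverage-only separation (identical composition) depend on the
  differential-coverage axes and may merge, flagged via contamination.
- The rhodopsin estimator assumes recA/radA are present exactly once per
  genome; lineages violating that bias the denominator accordingly.
- Assembly, gene prediction, and external database annotation are out of
  scope: contigs, gene intervals, taxonomy and family labels are inputs.
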