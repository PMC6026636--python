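# Methods

## The classification model

The classifier follows the two-comparator design of k-mer fingerprint
taxonomic profilers. A pre-computation phase scans every reference genome
for canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement; windows containing non-ACGT bases are skipped) and assigns
each one to the lowest common ancestor (LCA) of the genomes containing it.
When the containing-genome set equals the node's full leaf set the k-mer
is a **strict** fingerprint — observing it in a read is evidence for
exactly that clade; otherwise it is retained as a **relaxed** fingerprint
at the LCA. Keeping relaxed fingerprints preserves information that a
strict-only index would discard (k-mers shared by a non-clade genome set,
which arise under horizontal transfer or convergent sequence); they are
down-weighted (0.5 vs 1.0, configurable) during candidate scoring, and a
strict-only mode is available. The partition property — each k-mer maps to
exactly one node — holds by construction and is re-verified when an index
is loaded.

Per sample, each read's canonical k-mers are looked up; the candidate is
the deepest node with direct hits (hits at a node implicitly support its
ancestors). Ties at equal depth go to the higher weighted hit count, and a
residual tie is deterministically sent to the tied nodes' LCA as
ambiguous. The second comparator then verifies the whole read: minimum
edit distance (edlib) between the read (either orientation) and windows of
the candidate's leaf genomes around the matched k-mer positions, capped at
8 seed windows per genome; a read with no usable seeds falls back to a
full-genome banded scan. The default acceptance band is ⌈0.1·read length⌉
edits — loose enough for ~1% sequencing error plus reference divergence,
tight enough that random 100 bp sequences are essentially never accepted
(the chance of a chance 21-mer match is ≈ 4⁻²¹ per window, and the
edit-distance check rejects forced random candidates with distance > 10 in
all of 300 simulated attempts in the test suite).

On error-free reads the pipeline is sound by construction: every k-mer of
a read from genome g is present in g, so any assigned node's leaf set
contains g — reads can be assigned above their source, never off its root
path. The test suite asserts zero violations over all fixture samples.

Aggregation applies a presence filter before reporting: a leaf is present
iff it received ≥ `min_reads` accepted reads (default 5) **and** its
distinct matched strict fingerprints cover ≥ `min_fingerprint_frac` of its
strict-fingerprint set (default 0.005). The fingerprint-fraction arm
guards against a few high-identity reads from a relative creating a
spurious presence call; both knobs are logged. Counts accepted at internal
nodes (reads from conserved regions) are redistributed to present
descendant leaves proportionally to their direct counts — a conservative
choice that never moves mass across clade boundaries; mass with no present
descendant stays at the node and is excluded from the percentages. A
"report at node" alternative is available by reading `counts` directly
from the profile. Relative abundance is 100 × leaf mass / total mass over
present leaves, so reported abundances always sum to 100.

## Gene profiling

Resistome/virulome profiling reuses the same comparator against a gene
panel: reads sharing ≥ 1 canonical k-mer with a gene are aligned (banded,
both strands), credited to the best-scoring gene, and contribute a covered
interval at the best location. An exact score tie across genes credits all
tied genes and marks the reads ambiguous, so closely related alleles are
visible rather than silently double-counted. Two quantities are emitted
per gene and sample: breadth of coverage (percent of gene positions
covered by ≥ 1 accepted read — used for presence) and reads per million
(used for fold-change statistics); emitting both lets either convention be
tested downstream. The default presence threshold is coverage ≥ 10% and
≥ 3 reads. Differential calling between cohorts uses
log2((mean_new + c)/(mean_old + c)) with pseudocount c = half the smallest
nonzero value, flags |log2FC| ≥ 2, and attaches a one-tailed
pooled-variance t-test in the direction of the observed difference. No
multiple-testing correction is applied by default (a Benjamini–Hochberg
option exists and its use is logged), matching how such gene panels are
conventionally screened.

## Community statistics

Counts are rarefied to a common depth (multivariate hypergeometric
sampling without replacement; samples below the target depth are dropped
with a logged warning) before the community-level test. The
Dirichlet-Multinomial likelihood is evaluated in the α parameterisation
(αᵢ = πᵢ(1−θ)/θ) via log-gamma functions; θ = 0 is handled as the exact
multinomial limit. Fitting uses method-of-moments initialisation refined
by L-BFGS-B on log α with the analytic digamma gradient; θ is clamped to
[10⁻⁸, 1−10⁻⁸] and a non-converged fit falls back to the moment estimate
with a warning flag. The likelihood-ratio statistic
−2(ℓ̂_pooled − ℓ̂_A − ℓ̂_B) is referenced to χ² with
df = K·(G−1), K = (n_taxa − 1) + 1 free parameters per group. The
log-likelihood is validated against a quadrature oracle (K = 2, N = 5,
agreement to 10⁻⁶) and the closed-form multinomial limit (10⁻⁹).

**Known limitation.** The χ² reference is anti-conservative at small
sample sizes: at the default study design (12 taxa, 10 samples per group,
depth 10⁴, rank-skewed π, θ = 0.02) the measured null rejection rate at
α = 0.05 is ≈ 0.09 (mean statistic 13.1 vs df 12), calibrating to 0.05 by
about 30 samples per group. Users comparing small cohorts should read
borderline p-values accordingly; the test-suite calibration check records
this behaviour.

Chao1 richness (classic S_obs + F1²/2F2; bias-corrected
S_obs + F1(F1−1)/(2(F2+1)), used by default and whenever F2 = 0) is
computed through scikit-bio. Ordination is classical scaling of the
Bray-Curtis matrix: double-center −D²/2, eigendecompose, scale
eigenvectors by √λ for positive eigenvalues; negative eigenvalues are
reported and their axes dropped (verified to reproduce Euclidean inputs
exactly and to match scikit-bio's PCoA eigenvalues). PAM clustering is a
deterministic BUILD + best-improvement SWAP with lowest-index tie-breaks —
no installed package provides k-medoids, so it is implemented here and
checked for permutation invariance. Biplot arrows are the Pearson
correlations of each taxon's abundance with the first two ordination
axes. Clinical 2×2 tables use the two-sided Fisher exact test (verified
against brute-force hypergeometric enumeration), with Pearson χ²
statistics (with/without continuity correction) attached for the cases
where the large-sample test would be preferred; continuous covariates use
the unpaired two-tailed pooled-variance t-test.

## The synthetic study

The generator emulates the statistical structure the pipeline is designed
to detect, not sequencing physics. Defaults: 12 leaf genomes of 50 kb
evolved down a random coalescent-style topology at 0.05 substitutions per
site per branch (enough divergence that most 21-mers are clade-specific);
100 bp single-end reads with 1% uniform substitution error and constant
quality; 50,000 reads per sample; compositions drawn from DM(π, θ) with
rank-skewed π (πᵢ ∝ 1/i — a few dominant genera over a long tail, as in
real infant-gut and surface communities) and θ = 0.02 (overdispersion in
the range reported for stool metagenomes). Stool compositions share one
parameter set across cohorts; skin and environment samples in the new
cohort are tilted toward the tail taxa (total-variation distance ≈ 0.19),
so the study's expected outcome is built in: community tests should fire
for skin/environment and stay null for stool.

Six panel genes of 1 kb are spiked as extra contigs of the most abundant
genome (coverage profiling is position-agnostic, so appending rather than
inserting keeps coordinates simple): three resistance genes at 8–16× the
old-cohort copy number (expected read-frequency log2 fold changes 2.4–3.5
after accounting for contig-length differences), two null genes at equal
copies (expected |log2FC| ≈ 0.5, from the host contig-length difference
alone), and one virulence gene present only in the old cohort. The host
taxon is deliberately excluded from the skin/environment composition
tilt so gene-level fold changes reflect gene content rather than the
community shift. Read ids encode the true source (sample, taxon, contig,
position, strand) — a fixture convention for oracle tests, not a FASTQ
standard.

The clinical table generator reproduces the published cohort margins
exactly (old n = 14, new n = 18; antibiotic exposure 12/2 vs 8/10,
3rd-generation cephalosporin 4/10 vs 0/18, exclusive breast milk 11/3 vs
7/11, TPN 12/2 vs 12/6, any breast milk 11/3 vs 17/1) with
normally distributed continuous covariates; delivery mode is omitted from
the default margins because the published row counts are internally
inconsistent with the cohort sizes. What passing tests show is therefore
that the *computational chain* recovers designed compositions, gene
spikes and contingency structure — not that it handles adapter content,
duplication, GC bias, quality decay, strain-level mixtures or reference
incompleteness, none of which the generator models.

## Problem sizes and determinism

All simulations are seeded; identical configurations produce byte-identical
FASTA/FASTQ/Newick/TSV outputs, and the pipeline caches stage outputs by
content hash so reruns are cheap and reproducible. The analysis drivers
run the full 85-sample design at 10,000 reads per sample; the benchmark
functions use 2–10 samples at up to the default 50,000 reads, 500
replicates for null calibration of the LRT, 100 for power, and 15
replicates for the null-gene flag rate — sizes chosen so each check is
statistically meaningful at desk scale. The classifier benchmark
(abundance recovery) uses spike-free samples: spiked gene cassettes are
deliberately absent from the reference genomes, so their reads are
correctly unclassifiable and would otherwise distort the truth
denominator.
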