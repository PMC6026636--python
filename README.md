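# fingertax

Phylogeny-aware k-mer fingerprint taxonomic classification, resistome /
virulome coverage profiling, and two-cohort comparison statistics for
shotgun metagenomes — packaged as a reusable, fully tested pipeline with a
synthetic-data generator, so every stage can be exercised end to end
without downloading sequencing data.

The motivating use case is a neonatal intensive care unit (NICU) cohort
comparison: infants cared for in an older shared-space unit versus a new
single-family-room unit, with stool, skin and environmental shotgun
metagenomes plus a clinical covariate table. The package re-implements the
complete computational chain such a study runs:

1. **Fingerprint index** — from reference genomes and their rooted
   phylogeny, every canonical k-mer (default k = 21) is assigned to the
   lowest common ancestor of the genomes containing it. A k-mer whose
   genome set is exactly a node's leaf set is a *strict* fingerprint
   (uniquely identifies that clade); other k-mers are kept as *relaxed*
   fingerprints at their LCA with half weight.
2. **Read classifier** — each read's canonical k-mers are looked up in the
   fingerprint sets; the deepest supported node becomes the candidate, and
   the whole read is then verified by banded edit distance (edlib, band =
   ⌈0.1·read length⌉) against windows of the candidate's leaf genomes
   around the matched k-mer positions. Accepted reads are aggregated to
   per-node counts, presence calls and relative abundances (%), with
   internal-node counts redistributed to present descendant leaves.
3. **Gene profiler** — unassembled reads are queried against an
   antimicrobial-resistance / virulence gene panel with the same k-mer +
   edit-distance comparator; each gene is quantified by breadth of
   coverage (% positions covered) and normalized read frequency
   (reads per million).
4. **Cohort statistics** — Fisher exact / chi-squared 2×2 tests and
   pooled-variance t-tests for the clinical table; Chao1 richness
   (S_obs + F1²/2F2, bias-corrected variant by default); the
   whole-community Dirichlet-Multinomial likelihood-ratio test; Bray-Curtis
   PCoA with PAM clustering; Pearson similarity matrices; and two-log
   fold-change differential gene calling with one-tailed t-tests.

The Dirichlet-Multinomial (DM) model at the center of the community
comparison is parameterised by the mean composition π (Σπᵢ = 1) and
overdispersion θ ∈ [0, 1), with αᵢ = πᵢ(1−θ)/θ:

    P(x | π, θ) = C(N; x) · Γ(A)/Γ(N+A) · Πᵢ Γ(xᵢ+αᵢ)/Γ(αᵢ),   A = Σᵢαᵢ

which reduces to the multinomial as θ → 0. Cohorts are compared with the
likelihood-ratio statistic −2(ℓ̂_pooled − ℓ̂_A − ℓ̂_B) on rarefied counts,
referenced to χ² with df = K·(G−1) where K = (n_taxa − 1) + 1 free
parameters per group and G = 2 groups.

The synthetic-data generator draws genomes down a random coalescent-style
tree, per-sample compositions from the DM model (shared parameters for
stool, a shifted composition for skin/environment in the new cohort),
spikes resistance/virulence genes into a host genome at cohort-differential
copy numbers (≥ 2 log2 units for the designated genes), and emits
single-end 100 bp reads whose ids carry their ground-truth source.

## Worked example

The numbered drivers under `analysis/` run the whole study at desk scale
(85 samples, 10,000 reads each, 12 reference genomes of 50 kb):

```
python analysis/01_simulate_study.py
python analysis/02_classify_samples.py
python analysis/03_profile_resistome.py
python analysis/04_cohort_statistics.py
```

The final driver prints (abridged):

```
clinical covariates (Fisher exact / t-test):
  antibiotic_exposure          p = 0.0276
  cephalosporin_3rd_gen        p = 0.0278
  exclusive_breast_milk        p = 0.0356
  some_breast_milk             p = 0.2951
  tpn                          p = 0.4123
whole-community DM LRT per sample type:
  environment      stat =    72.60  df = 12  p = 1.04e-10
  skin             stat =    91.86  df = 12  p = 2.15e-14
  stool_2wk        stat =    12.01  df = 12  p = 0.445
  stool_discharge  stat =    10.95  df = 12  p = 0.533
flagged genes (|log2FC| >= 2, new vs old):
  all sample types: AMR01, AMR02, AMR03 (up), VIR02 (down)
```

Reading the output: the regenerated clinical table reproduces the
published contingency p-values (antibiotic exposure 0.03, 3rd-generation
cephalosporin 0.03, exclusive breast milk 0.04, TPN 0.41, any breast milk
0.30 at two decimals); the skin and environment communities — simulated
with a cohort shift — are detected as significantly different while the
stool communities — simulated from shared parameters — are not; and the
three resistance genes spiked ≥ 2 log2 units higher in the new cohort are
flagged with the correct sign in every sample type, with the old-cohort-
only virulence gene flagged in the opposite direction. Small tables land
under `results/`, bulk intermediates under `scratch/`.

A `fingertax` console script exposes the same stages
(`simulate`, `index`, `classify`, `profile-genes`, `stats`, `validate`,
`run-all`) for file-at-a-time use.

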