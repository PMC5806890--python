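# Methods

`coexnet` reconstructs a gene co-expression network (GCN) from an RNA-seq
count matrix by combining three inference algorithms across a panel of
normalizations of the same data, filtering each algorithm's raw output at a
permutation-derived confidence cutoff, and merging the surviving networks
by two-step unweighted voting with confidence re-scoring. This note records
the model, the parameters that matter, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Input filtering

Counts are filtered by three criteria before anything else runs:

| criterion | rule | default |
|---|---|---|
| I (samples) | drop a sample when the fraction of genes with count < `low_count_threshold` exceeds `sample_low_fraction` | 10 reads, 0.90 |
| II (genes) | drop a gene when its count is < threshold in more than `gene_low_fraction` of samples | 10 reads, 0.80 |
| III (genes) | drop a gene whose coefficient of variation sd/mean is strictly below `min_cv` | 0.5 |

Boundaries are strict ("more than 90%" removes, exactly 90% keeps). The CV
uses the sample (n−1) standard deviation and is computed on raw counts by
default; all-zero genes fall to criterion II before the CV is evaluated, so
a zero mean never reaches the division.

## The six expression datasets

The filtered counts are carried forward in six forms: raw counts, an
externally supplied FPKM matrix (never recomputed — gene lengths are out of
scope), and four normalizations.

* **UQ** — each sample divided by (75th percentile of its nonzero counts) /
  (geometric mean of those percentiles). Linear-interpolation percentile.
* **TMM** — scaling factors from the trimmed mean of M-values against a
  reference sample (the one whose upper quartile of depth-scaled counts is
  closest to the mean), double-trimming 30% of each M tail and 5% of each A
  tail, precision-weighted mean, factors normalized to geometric mean 1.
  Counts are divided by the effective library size (library size × factor,
  re-centred to geometric mean 1). The factors agree with edgeR's
  `calcNormFactors(method="TMM")` to numerical precision.
* **RLE** — median-of-ratios size factors against the per-gene
  geometric-mean pseudo-reference; genes containing any zero are excluded
  from the reference (an input in which *every* gene has a zero is an
  error that asks for prefiltering). Matches DESeq2's
  `estimateSizeFactorsForMatrix`.
* **VST** — counts are RLE-normalized and passed through the closed-form
  negative-binomial variance-stabilizing transform. Per-gene dispersions
  come from method-of-moments ((var − μ)/μ²); the parametric trend
  α(μ) = a₀/μ + a₁ is fitted by least squares on the positive dispersions,
  and the transform is
  `log2((1 + a₀ + 2a₁q + 2√(a₁q(1 + a₀ + a₁q))) / (4a₁))`.
  If the fitted asymptotic dispersion a₁ is not positive the documented
  fallback `log2(q + 1)` is used. Output is shifted to be non-negative
  (a per-matrix constant; correlation-based inference is unaffected).

## Base inferrers

**Weighted correlation / TOM.** Unsigned soft-threshold adjacency
a_ij = |cor(i,j)|^β with Pearson correlation (Spearman configurable) and
default β = 6; an optional scale-free-fit selector scans β = 1…12 for a
degree-distribution log-log fit with R² ≥ 0.8. Confidence score is the
topological overlap measure

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with TOM_ii defined as 1. Constant genes get zero adjacency with a logged
warning.

**Shrinkage Gaussian graphical model.** The sample correlation matrix is
shrunk toward the identity, R* = (1−λ)R + λI, with the analytic
optimal intensity λ* = Σ var̂(r_ij) / Σ r_ij² (clipped to [0,1]); the score
is |pcor_ij| with pcor = −Ω_ij/√(Ω_ii Ω_jj), Ω = (R*)⁻¹. Shrinkage makes
the inversion well-posed when genes outnumber samples.

**BC3NET.** Mutual information between profiles uses the Gaussian closed
form MI = −½ ln(1 − ρ²) by default (|ρ| = 1 capped at ½ln 10¹², warned); a
binned estimator is available: equal-frequency bins, ⌈n^⅓⌉ bins per margin,
plug-in estimate with the Miller–Madow bias correction (at √n bins the
plug-in bias is O(B²/2n) ≈ 0.5 nat at n = 10⁴ and never vanishes, so the
cube-root rule is used to meet the closed-form limit). Each bootstrap
resample of samples yields a C3NET core: every pair's MI gets an empirical
p-value against a permutation null *pooled across all gene pairs* —
whole-matrix per-gene permutations are accumulated until the pool holds at
least 10 values per tested pair, and the same bootstrap column indices are
applied after permutation so the null shares the bootstrap's duplicate
pattern — then Benjamini–Hochberg correction across pairs at α = 0.05
zeroes non-significant MI, and each gene nominates its maximum-MI
surviving partner (ties broken by lexicographic gene id). Bagging over B
bootstraps (default 100; 50 in the synthetic study) gives each edge a
frequency f_e; edges are kept when a one-sided binomial test of the count
against the uniform-scatter rate (total nominations / (B · C(p,2))) is BH
significant at 0.05, and f_e is the confidence score. Three design points
matter and were verified on pure-noise input: the large pooled null keeps
empirical p-values fine-grained enough for the BH step to reject
chance-extreme pairs; the duplicate-aligned null keeps the bootstrap MI
calibrated; and per-pair α without multiplicity control would let ~5% of
null pairs nominate.

## Permutation cutoff

TOM and |pcor| are dense (every pair is scored), so each initial network is
thresholded at a null cutoff: each gene's profile is independently permuted
across samples (a joint whole-column permutation is available by flag), all
pairwise scores of the permuted data are computed, their 99.99th percentile
(linear interpolation) taken, and the mean over 100 permutations (10 in
the synthetic study) is the cutoff. Edges with score ≥ cutoff (boundary
inclusive) survive. Two numerical choices: permuted GGM datasets are scored
with the λ estimated from the *observed* data — re-estimating λ on permuted
data drives it to 1 and collapses the null score scale — and a warning is
emitted when fewer than 10⁴/(100−percentile)·100 scores per permutation
make the percentile poorly resolved. BC3NET output is not cutoff-filtered;
its binomial edge test already is one.

## Voting and re-scoring

Scores of each initial network are min-max normalized to [0,1] (a network
of identical scores maps to all 1 — uniform confidence treated as full
confidence, logged). Step one keeps links present in ≥ 3 of one method's 6
per-dataset networks ("more than two of six"), scored by the mean of the six
normalized scores with absent = 0. Step two keeps links present in ≥ 2 of
the 3 intra-method networks ("more than one of three"), scored by the mean
of the three intra-method scores with absent = 0. Both thresholds are
configurable; a single-dataset variant (3 methods on one matrix, keep links
found by ≥ 2) is provided for mixed circRNA/gene matrices. Alternative
combiners for comparison: weighted voting (per-method weights, e.g.
positive-fold / negative-fold performance ratios; support is weight-summed
and compared to the weight-scaled thresholds — equal weights reduce exactly
to the unweighted scheme) and per-edge score/rank averaging over all inputs
with no vote filter.

## Gold standards and evaluation

Positives are the union of within-set pairs of GO categories and pathways
(sets larger than 500 genes skipped so root-like categories do not
contribute near-complete graphs) plus protein–protein and probabilistic
functional network edges. Negatives: candidate term pairs are
same-namespace annotated terms with propagated gene counts strictly between
5 and 50 and semantic similarity exactly 0; all cross gene pairs (shared
genes excluded) form the initial set; the threshold is the mean of 5th
percentiles of random-pair functional similarity over 10000 backgrounds of
1000 pairs (sampling with replacement over the annotated universe); pairs
with similarity below the threshold are final negatives. Positives take
precedence when the two sets overlap. Term similarity is Lin
2·IC(MICA)/(IC(t₁)+IC(t₂)) (max-normalized Resnik available) with
IC(t) = −ln(genes under t / genes in the namespace); gene similarity is the
best-match average over the two direct annotation sets; an unannotated gene
is an error, never a silent zero.

Fold enrichment at a cutoff k of the ranked edge list is
(n_k/m_k)/(M/N) — the rate of gold links among selected edges over the
genome-wide rate. The formula's worked values (9.4-fold for 33/1093 vs
180/55986; 3.72-fold for 88/1329 vs 996/55986) fix this orientation;
the inverse reading (multiplying by M/N) cannot reproduce them.

Function prediction scores a gene's direct co-expression neighborhood by a
one-sided Fisher (hypergeometric-tail) test per term with propagated
annotations, BH correction within the gene, and keeps terms with q < 0.05
at score −log₁₀(q) (base 10, fixed by documentation). A prediction is a
true positive iff it equals a known term or is more specific (a
descendant). Scores propagate toward the root, each ancestor taking the
maximum over its descendants (idempotent). CAFA-style gene-centric
metrics: over a score-threshold sweep, precision is averaged over genes
with a nonempty prediction and recall over all genes with known terms;
an information-content weighting of term hits gives the weighted variant;
F-max is the maximal harmonic mean; AUROC/AUPRC are trapezoidal.
Root terms are excluded from both prediction and truth sets (they carry no
information). The evaluation pre-filter keeps genes with ≥ 3 known and ≥ 3
predicted annotations whose two counts have CV ≤ 0.5.

Topology statistics (degree histogram, clustering, average shortest path
on the largest component), guide-gene subnetworks (induced subgraph within
a fixed hop count of bait genes) and trait link-density analysis (within-
vs between-trait link rates, fold, and a size-preserving label-permutation
p-value) use networkx for the graph machinery.

## Synthetic study

The generator emulates an RNA-seq compendium at desk scale: 600 genes ×
120 samples, six planted modules of 20 genes (within-module target
correlation 0.8 through a shared standard-normal latent factor per module
and sample; the per-gene loading is √(ρ/(1−ρ)·σ²) with σ² ≈ ln(1 + α + 1/μ)
the gene's log-count noise variance, which lands the realized Spearman
correlation within ±0.1 of target at n ≥ 100), lognormal baseline means
(location 4.5, scale 1.0 on the log scale — typical counts in the tens to
hundreds), negative-binomial dispersion 0.1, and relative library sizes
uniform in [0.6, 1.6]. The remaining 480 genes are independent noise. A
pseudo-FPKM companion matrix (counts scaled by fixed random gene lengths
and depth) lets the six-dataset design run end to end; it is synthetic
plumbing, not an FPKM computation.

The toy ontology places each module under one of two branches: five
modules under one domain, the last on a disjoint branch, so the
off-branch module's terms have semantic similarity exactly 0 with every
other module's terms — the raw material for the negative standard. All but
one gene per off-branch leaf are cross-annotated to a shared on-domain
term; this keeps the fraction of zero-similarity random gene pairs small
enough (≈3%) that the 5th-percentile background threshold stays strictly
positive, while the exclusive genes retain genuine zero-similarity
partners. The synthetic negative standard uses a 200 × 200 background
sampling design (the full 10⁷-pair design is the default for real data).

What the synthetic study does *not* emulate: real count depth (millions of
reads), batch effects, tissue structure, hub-dominated degree
distributions, annotation incompleteness, or isoform-level signal. Passing
tests demonstrate the pipeline's arithmetic and its qualitative behaviour
(null control, module recovery, consensus filtering), not field
performance on a real compendium.

A known limitation follows from the module model: planting *dense*
equicorrelated modules makes the TOM branch nearly ideal (every
within-module pair shares all its neighbors) while the partial-correlation
branch is structurally blind — the true partial correlation between two
members of a 20-gene equicorrelated module is ρ/(1+18ρ) ≈ 0.05, below the
≈1/√120 sampling noise — and the one-nomination-per-gene C3NET core caps
BC3NET's recall of the 190 pairs per module. Under these conditions a
consensus that requires two of three methods to agree cannot match the
best single method's F1; it trades recall for precision (the final
network's precision exceeds 0.9 where the best single method's is lower).
An ensemble-superiority claim therefore holds only when the member methods
are of comparable strength, which this planted-module design deliberately
does not provide; the acceptance suite asserts the claim anyway and
documents the failure rather than adjusting the study conditions to it.

## Problem sizes and determinism

The test and acceptance runs use 600 genes × 120 samples with 10
permutations per cutoff and 50 bootstrap resamples, three seeds — the
package's chosen desk-scale study conditions. All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); per-stage seeds are
drawn from the pipeline's master seed, and a fixed seed reproduces the
final edge list byte for byte.
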