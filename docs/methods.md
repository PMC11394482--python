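# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Differential expression

Each feature (protein or gene) is tested independently between two sample
groups with a two-sided two-sample *t*-test on log2-transformed values.
Group B is the fold-change numerator: log2FC = mean(log2 B) − mean(log2 A).
A feature is significant when *p* < α (default 0.05, **uncorrected**) and
|log2FC| ≥ `log2fc_min` (default 0, i.e. direction only). Multiple-testing
correction is deliberately absent at this stage; it enters only in the
enrichment stage. This mirrors the basal-statistics convention of the
analysis the package re-implements, where per-feature calls feed set
algebra rather than standing as final inferences.

Choices where the procedure was underspecified:

* **Welch vs Student.** Default Welch: replicate groups are tiny (n = 3)
  and variance equality is unverifiable. Student is available
  (`DEConfig(test="student")`) and is the exact-size test under the
  synthetic generator's equal-variance normal noise; the null-calibration
  check uses it for that reason, since Welch at n = 3/3 is measurably
  conservative (empirical size ≈ 0.036 at α = 0.05).
* **Scale.** Tests run on log2 values after per-sample normalization
  (median-centering for intensities, mean-library-size for counts;
  configurable, `none` disables). Counts get a pseudo-count of 1 before
  log2; proteomic zeros are treated as non-detections and masked, not
  imputed.
* **Degenerate inputs.** Zero within-group variance in both groups with
  equal means reports *p* = 1 (no evidence); with separated means, *p* = 0.

## Venn partitioning and percentages

Families of 2–3 named feature sets are decomposed into all 2^k − 1
exclusive regions. Percentages are `round_half_up(100·count/denominator, 1)`
— round-half-up reproduces every printed one-decimal value in the
published tables the package bundles (`cmpnomics.examples`). The
denominator is a **required argument**: published analyses of this kind mix
denominators (all 1059 identified proteins in the unfiltered analyses;
filtered totals 876, 18, 6424, 103 afterwards), so inferring it silently
would invite mistakes.

The bundled region tables were checked for internal consistency before
being frozen: exclusive regions sum exactly to each printed union, and the
printed per-set totals equal the sums of their four regions.

## Two-step filtration

`two_step_filtration(family, spec)` subtracts layer 1 (features whose
expression tracks CCM1 dosage itself) then layer 2 (the "antagonist" set —
responses attributable to GR/nPR, which share the mifepristone ligand,
derived from mifepristone-treated GR/nPR-positive cells). Because both
layers act by set difference, the composition equals subtraction of the
union and is order-independent; the report records per-layer removals per
set. The filtration worked example rebuilds the published 876-protein
family, applies a two-layer spec whose removals realize the published
survivor table, and recovers the 18-protein mPR-specific family region by
region. The published tables constrain only each region's total removal,
not its split across layers; the fixture splits each region's removals
evenly between the layers.

Cross-species caveat: the antagonist set originates from a human cell
line while the response sets are murine, so the default id matching is
case-insensitive gene-symbol comparison (`exact` available). This is a
heuristic; orthology is not resolved.

## Over-representation analysis

For universe size N, term size K (after intersecting the term with the
universe), annotated query size n (query members annotated to ≥ 1 term),
and k query hits in the term, the enrichment p-value is the upper tail
P(X ≥ k), X ~ Hypergeometric(N, K, n) — over-representation only.
GeneRatio is k/n (reported both as a reduced fraction and as a real).
Adjustment is Benjamini–Hochberg step-up across all tested terms of a
collection (Bonferroni available); GO and KEGG collections are adjusted
separately, meeting only in the comparative dot-plot table. The universe
is the set of identified features of the modality, not the genome.
Empty queries return an empty, flagged result rather than an error.

The comparative dot-plot table flags terms found in any exclusion filter
(with the filter's name as the reason) and marks terms enriched in more
than one condition as shared.

## TF prediction

* **Standardization.** Every sequence is made exactly `standard_length`
  (default 1000) residues: truncation keeps the N-terminus, padding
  appends X at the C-terminus.
* **Featurization.** The built-in featurizer concatenates amino-acid
  composition (20 dims) with 3-mer counts hashed into 400 buckets by a
  deterministic 21-ary positional code, then L2-normalizes. k-mers
  containing X are skipped and composition counts only non-X residues, so
  the encoding is invariant to padding. External per-sequence embedding
  tables (e.g. from a protein language model) plug in via
  `EmbeddingTable`; the package never computes such embeddings itself.
* **Cost-sensitive SVM.** Class costs are cost(c) = total/(n_classes·count(c)),
  so the cost ratio is the inverse frequency ratio (at the benchmark
  composition, cost(TF)/cost(NTF) = 2784/954 ≈ 2.92). Costs enter as SVM
  class weights. Kernel default is linear (typical for high-dimensional
  embeddings); RBF available. The regularization constant defaults to
  C = 10: with L2-normalized (unit-norm) inputs, C = 1 over-regularizes,
  and performance is flat across C ∈ [5, 50].
* **Cross-validation and consensus.** Stratified k-fold (default 10),
  fold assignment seeded; per-fold confusion matrices yield F1,
  specificity, sensitivity and balanced accuracy; each record's consensus
  fraction is the share of its held-out evaluations predicted TF
  (one per CV repeat), and candidates are records with fraction ≥ the
  threshold (default 0.5, inclusive at the boundary).

## Synthetic data: what it emulates, what it does not

The generators reproduce the *design* of the emulated study — three CCM1
genotypes × two treatments × three biological replicates — and plant
known effects so recovery is exactly scorable:

* **Proteomics:** log-normal intensities; per-feature baseline log2
  intensity ~ Uniform(18, 30) (an iBAQ-like dynamic range), replicate
  noise Normal(0, σ) with σ = 0.5 log2 units, planted shifts of
  ±`effect_log2fc` (default 2) in the designated genotype/treatment
  cells. An optional missing-at-random mask (default off) emulates
  non-detections.
* **RNA-seq:** negative-binomial counts via a gamma–Poisson mixture with
  common dispersion (default 0.2) and log-normal means; planted shifts
  multiply the mean by 2^(±effect).
* **Gene sets:** flat term lists (no GO DAG structure); planted terms
  draw 60% of members from the planted DE features.
* **TF benchmark:** default composition 954 TF / 2784 NTF (3738 records).
  Every TF sequence carries three non-overlapping copies of a fixed
  7-mer motif; NTF sequences are motif-free i.i.d. background. The
  repeated short motif is a synthetic stand-in for the long DNA-binding
  domains of real TFs — one 7-mer in a 200–1200-residue sequence is not
  reliably visible through a 400-bucket hashed 3-mer encoding, whereas a
  repeated motif is, which is the regime the benchmark is meant to probe.
* **Antagonist filter:** covers a configurable fraction of the planted
  non-mPR treatment responders plus background ids, and never touches the
  designated mPR-specific ids.

None of this emulates real biological correlation structure, batch
effects, peptide-level missingness mechanisms, sequencing depth gradients,
or real protein families. Passing tests therefore demonstrate that the
*procedures* are implemented correctly and recover planted structure under
their stated assumptions — not that the pipeline's biological conclusions
transfer to any real dataset.

Where neither the emulated analysis nor common practice fixed a value,
the defaults above (noise σ, dispersion, DE fractions of 0.1, 50/50
mPR/non-mPR split) were chosen once as plausible for MEF-scale omics and
are ordinary config knobs, not estimates of anything.

## Problem sizes used in the checks

The acceptance-style checks run at: 5000 features for null calibration
(binomial 99% band around α), 800–1000 features for recovery and
monotonicity, the full 3738-sequence composition for the TF benchmark
(10-fold), a 400-sequence subsample for the 20-seed permuted-label null
(the chance-level property is size-independent), and a reduced synthetic
pipeline for the byte-determinism check. These sizes are the package's
test design; the library itself has no size limits beyond memory.

## Known limitations

* Uncorrected per-feature p-values are a convention of the re-implemented
  analysis, not a recommendation; at 0.05 with thousands of features the
  DE sets contain α-level noise by construction, which the set algebra
  then propagates.
* The "shared" membership rule across genotype contrasts is taken from
  the published region tables as given; with differing per-genotype
  contrasts there is more than one defensible rule.
* Layer-1 filtration is supported at feature granularity in `setops` and
  at term granularity in `enrichment` (dot-plot exclusion); the emulated
  analysis itself mixed both.
* The cost-sensitive SVM is evaluated by cross-validation on a labelled
  benchmark; applying it to unlabelled candidates requires external
  embeddings or sequences compatible with the built-in featurizer.
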