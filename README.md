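# cmpnomics

Multi-omics isolation of **mPR-specific, CCM1-mediated progesterone signals**.

Cerebral cavernous malformation gene 1 (CCM1/KRIT1) couples classic nuclear
(nPR) and non-classic membrane (mPR) progesterone receptors inside the
CSC-mPR-PRG-nPR ("CmPn") signaling network. Experiments that probe this
network compare mouse embryonic fibroblasts across three CCM1 genotypes
(wild type, knockout, knockin/96) under vehicle or combined
progesterone + mifepristone treatment — but the treatment acts through
*every* progesterone-binding receptor at once. This package implements the
analysis chain that isolates the mPR-specific part of the response:

1. **Differential expression** (`cmpnomics.diffexpr`) — per-feature
   two-sided two-sample *t*-tests on log2 abundances (Welch by default,
   Student available), significance at uncorrected *p* < α with an optional
   |log2FC| floor; proteomic iBAQ intensities and RNA-seq counts are both
   supported.
2. **Venn set algebra** (`cmpnomics.setops`) — exhaustive region
   decomposition of 2–3 DEP/DEG sets with counts and round-half-up
   one-decimal percentages against an *explicit* denominator.
3. **Two-step filtration** (`cmpnomics.setops.two_step_filtration`) —
   subtract (layer 1) features tracking CCM1 dosage itself, then (layer 2)
   the "antagonist" set of non-mPR responses derived from
   mifepristone-treated GR/nPR-expressing cells; what survives is
   mPR-specific.
4. **Over-representation analysis** (`cmpnomics.enrichment`) — upper-tail
   hypergeometric test per gene set, GeneRatio = k/n, Benjamini–Hochberg
   adjustment, comparative dot-plot tables with filter-based term exclusion.
5. **TF prediction** (`cmpnomics.tfpred`) — protein sequences standardized
   to 1000 residues (N-terminal keep, C-terminal X padding), encoded by a
   pluggable embedding (external per-sequence table, or the built-in
   composition + hashed 3-mer featurizer), classified by a cost-sensitive
   SVM whose class costs are inversely proportional to class frequencies,
   under stratified 10-fold cross-validation; sequences called TF in ≥ 50%
   of held-out evaluations become consensus candidates.

A synthetic-data module (`cmpnomics.datasets`) generates every input with
planted, recoverable structure, so the full pipeline runs and is tested
without any external download.

The statistical stages follow the statsmodels idiom: a model object built
from data whose `fit()` returns a results object
(`DifferentialExpression → DifferentialExpressionResults`,
`OverRepresentation → ORAResults`, `TFPredictionModel → CVReport`), each
with a `summary()`.

## Worked example

```python
from cmpnomics import (ExperimentConfig, generate_omics, call_de, SetFamily,
                       venn_partition)

cfg = ExperimentConfig(n_features_protein=1000, n_features_rna=2000, seed=1)
proteomic, rna, truth = generate_omics(cfg)

members = {}
for genotype in ("WT", "KO", "KI96"):
    res = call_de(
        proteomic,
        proteomic.samples_where(genotype=genotype, treatment="VEH"),
        proteomic.samples_where(genotype=genotype, treatment="PRG_MIF"),
    )
    print(res.summary())
    members[genotype] = res.de_sets()[2]

family = SetFamily(name="prg_response", members=members)
partition = venn_partition(family, denominator=1000)
for row in partition.to_frame_rows():
    print(row["region"], row["count"], row["percentage"])
```

prints (seed 1):

```
Differential expression (two-sample t-test on log2 values)
  test: welch, alpha: 0.05, |log2FC| >= 0.0, normalization: median_center, no multiple-testing correction
  features tested: 1000
  significant: 128  (up: 68, down: 60)
...
WT 111 11.1
KO 93 9.3
KI96 84 8.4
WT&KO 7 0.7
WT&KI96 9 0.9
KO&KI96 15 1.5
WT&KO&KI96 1 0.1
```

Each genotype's significant set mixes the ~100 planted treatment responders
with α-level false positives; the Venn rows give each exclusive region's
size and its share of the 1000-protein universe (the explicit denominator).

The same stages are scriptable from the shell:

```bash
cmpnomics run-all --outdir out/ --seed 1        # full synthetic pipeline + manifest
cmpnomics venn --family sets.tsv --denominator 1059 --out venn.tsv
cmpnomics tfpredict --fasta tf_benchmark.fasta --out cv.json
```

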