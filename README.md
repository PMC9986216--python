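# dnvrisk

Case/control prediction of neurodevelopmental-disorder risk from de novo
coding variation, built around a shallow neural network whose loss directly
trades true positives against penalized false positives — the operating
regime is classification at a very low false-positive rate (FPR < 0.01).

## What it does

- **Feature matrices** (`dnvrisk.io_features`): variant-class-specific
  sample × gene matrices from a de novo variant table. LGD matrices use 0/1
  gene indicators plus per-sample constraint/conservation features (pLI,
  LOEUF, RVIS, phastCons, aggregated most-deleterious across a sample's
  mutated genes); missense matrices hold the maximum per-variant
  pathogenicity score per gene and use no gene-score columns. A trivial
  one-hot mode supports ablations.
- **Shallow neural network** (`dnvrisk.snn`): one hidden ReLU layer,
  sigmoid output, full-batch Adam on the loss
  `1 − (TP − λ1·FP) + λ2·‖w_out‖²` with soft (summed-probability) TP/FP
  counts. Hyperparameters are picked by stratified 3-fold CV maximizing the
  fraction of validation cases scored strictly above every validation
  control.
- **Baselines and combination** (`dnvrisk.baselines`): random forest,
  linear SVM, and logistic regression; per-sample max over the LGD- and
  missense-specific models ("combined"); mean-probability ensembles with
  and without the network; LGD gene-list / pLI ≥ threshold / LOEUF <
  threshold heuristic classifiers.
- **Evaluation harness** (`dnvrisk.evaluation`): repeated stratified 75/25
  splits (identical split handed to every model per iteration), TPR at
  FPR < 0.01, ROC-AUC (Mann–Whitney, ties at ½), PR-AUC (step
  integration), percentile 95% CIs, and z-scores against a uniform-random
  reference model.
- **Gene ranking** (`dnvrisk.ranking`): artificial samples carrying a
  single variant in one gene are scored by the trained models; mean
  probability over iterations ranks genes, with case/control enrichment
  differences and Spearman correlations against constraint scores.
- **Synthetic cohorts** (`dnvrisk.synthetic`): Poisson per-sample variant
  counts (defaults 0.21 vs 0.12 LGD events for cases vs controls), planted
  risk genes absorbing the case excess, skewed constraint scores, and
  upward-shifted missense pathogenicity for case risk-gene variants.

## CLI

```sh
# generate a cohort (variants.tsv, pli/loeuf/rvis/phastcons.tsv, truth.tsv)
dnvrisk simulate --config cohort.yaml --out cohort/

# build a feature matrix
dnvrisk build-matrix --variants cohort/variants.tsv --scores cohort/ \
    --variant-class lgd --out lgd_matrix.tsv

# repeated-split evaluation of SNN + baselines + ensembles
dnvrisk evaluate --variants cohort/variants.tsv --scores cohort/ \
    --n-iter 100 --seed 1 --out-json metrics.json --out-tsv metrics.tsv

# rank genes via artificial single-variant samples
dnvrisk rank --variants cohort/variants.tsv --scores cohort/ \
    --variant-class lgd --n-iter 100 --seed 1 --out ranking.tsv
```

`--config` accepts a YAML file with an `snn:` block (lambda1,
hidden_units, lambda2, learning_rate, epochs), an optional `snn_grid:`
block for cross-validated search, and `baseline_grids:` overrides.

Input dialects: the variant table is a TSV with columns `SampleID`,
`Phenotype` (case|control), `Gene`, `Class` (lgd|missense|other), and
optional `PrimateAI` (float or NA); gene-score files are two-column
`Gene<TAB>Score` TSVs; heuristic gene lists are one symbol per line with
`#` comments.

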