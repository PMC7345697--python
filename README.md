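# qsrrkit

Automated retention-time prediction for LC-MS metabolomics and lipidomics.

Compound identification by mass spectrometry is ambiguous: many metabolites
and lipids share an *m/z*. Chromatographic retention time (RT) is the usual
orthogonal evidence, but it shifts between columns, eluents and
instruments, so every laboratory method needs its own predictive model.
`qsrrkit` automates building such Quantitative Structure–Retention
Relationship (QSRR) models: given a CSV of compound names, SMILES and
measured retention times (minutes), it produces a fitted, persisted model
and honest cross-validated estimates of how well it will predict new
compounds — no bioinformatician in the loop.

## The method

1. **Descriptors.** ~210 2-D molecular descriptors are calculated from each
   SMILES with RDKit (constitutional counts, topological indices, SLogP,
   TPSA, ...). Users may supply their own descriptor columns; these take
   precedence on a name collision.
2. **Descriptor hygiene.** Three filters, applied in order with inclusive
   thresholds: drop descriptors missing in ≥ 75 % of compounds, descriptors
   whose modal value covers ≥ 90 % of compounds, and — by a greedy
   keep-the-earlier scan — descriptors with |Pearson r| ≥ 0.9 against an
   already-kept descriptor.
3. **Model search.** After a seeded shuffle of the data, a pipeline of
   median imputation → per-feature standardization → recursive feature
   elimination (500-tree random-forest importance; inner 5-fold CV picks the
   subset size by mean absolute error) → learner selection is evaluated by
   an outer 5-fold cross-validation. Candidate learners are linear
   regression, a 500-tree random forest, and rbf-kernel SVR with C and γ
   grid-searched over 7 log-spaced values each in [10⁻³, 10³]; the winner
   has the best mean inner-CV r², ties broken by lower mean inner-CV MAE,
   then by simplicity (linear < svr < random forest).
4. **Final model and prediction.** The pipeline is refit on all rows and
   saved as a self-describing bundle (scaler statistics, imputation
   medians, selected features, learner, training RT range). Predictions
   outside the training RT window are flagged as extrapolation.
5. **Evaluation.** Best-fit line of predicted on measured RT, r², median
   (signed) error, median % error, fractions within 1 and 2 minutes;
   optional exclusion of test compounds whose observed RT lies outside the
   training window, and a 35 %-relative-error validity filter.

A `protocol` command reproduces the replicate-model experiment design:
randomized 75/25 (or fixed-size) train/test splits, several replicate
models per split, per-model evaluation and a summary of which descriptors
recur across models.

## Worked example

```sh
qsrrkit simulate --out series.csv --chain-max 31 --seed 1   # 30-compound homologous series
qsrrkit train --input series.csv --save model.qsrr --seed 1 --rf-trees 50
qsrrkit predict --model model.qsrr --input series.csv --out preds.csv
qsrrkit evaluate --pred preds.csv --obs series.csv --max-pct-error 35
```

prints (train, then evaluate):

```
outer CV (5 folds): mean r2 = 0.9935, median r2 = 0.9945, mean MAE = 0.1332 min (sd 0.0505); learners: svr, svr, svr, svr, svr
final model: svr {'C': 100.0, 'gamma': 0.01}, 3 features, training rt range [1.73, 11.87] min
model saved to model.qsrr
...
fit: pred = 0.9957*obs + 0.0266, r2 = 0.9972; median error -0.014 min (-0.17%); 100% within 1 min, 100% within 2 min (n = 30, excluded 0)
30 of 30 predictions valid at 35% error cutoff
```

The outer-CV line is the honest performance estimate: each fold's model was
fit without its held-out compounds, so a mean absolute error of ~0.13 min
is what new compounds from the same chemistry should expect. The final
in-sample fit (slope ≈ 1, intercept ≈ 0, r² ≈ 1) confirms the model is
unbiased across the elution range.

The same workflow is available as a library (`qsrrkit.compute_descriptors`,
`apply_filters`, `train`, `predict`, `run_protocol`, ...); see
`examples/` for narrative scripts covering each capability and
`docs/methods.md` for the modeling details and design choices.

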