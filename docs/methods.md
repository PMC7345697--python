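# Methods

## Model

`qsrrkit` treats retention-time prediction as supervised regression from
2-D molecular descriptors. The underlying assumption is the usual QSRR
one: on a fixed column/eluent/gradient, retention is a reproducible
function of molecular structure, and 50–200 identified standards sample
that function densely enough to interpolate. The package deliberately
refuses to trust extrapolation: predictions outside the training
retention window are flagged, and evaluation can exclude test compounds
whose observed time falls outside that window, because the model has no
support there.

Descriptors are the ~210 2-D descriptors built into RDKit — counts of
functional groups and ring systems, elemental composition, hybridization,
topological and electrotopological indices, SLogP (Wildman–Crippen
octanol/water partition coefficient, exposed under that conventional
name), TPSA, and the like. These are deliberately simple per-molecule
quantities, not fingerprint bit-vectors: with 60–200 training compounds,
interpretable low-dimensional features paired with aggressive filtering
and feature selection generalize better than sparse high-dimensional
encodings. No conformers are generated. Non-numeric or non-finite backend
outputs become missing values.

## Descriptor hygiene

Three filters run in a fixed order — high-missing, near-constant,
correlated — each with an inclusive drop boundary:

| filter | default | rule |
| --- | --- | --- |
| high-missing | 0.75 | missing-cell fraction ≥ threshold |
| near-constant | 0.90 | modal non-missing value covers ≥ threshold of compounds |
| correlated | 0.90 | greedy scan in column order; drop when \|Pearson r\| ≥ threshold vs. an already-kept column |

Missingness is handled first so correlations are computed on the most
complete columns; correlations use pairwise-complete observations with at
least 3 shared points (a correlation with fewer is treated as undefined,
never as a drop reason). The greedy scan keeps the *earlier* column of a
correlated pair, which makes the outcome deterministic and independent of
row order; it depends on column order, which is canonicalized to input
order. Residual missing cells are imputed with training-column medians —
fit on training rows only, and a matrix containing a column the imputer
never saw is a contract error rather than a silent zero.

## Training pipeline

Rows are shuffled once with the run seed; all cross-validations then use
contiguous folds of that shuffled order, so a single integer seed fully
determines every split, every forest, and hence the final model.

Within every fold (and for the final fit) the training rows alone produce:
imputation medians, per-feature mean/sd standardization (features constant
within the fold are set aside as uninformative), a descriptor subset from
recursive feature elimination, and the selected learner. RFE ranks
features by random-forest importance (500 trees by default), eliminating
10 % of the feature count per round; an inner 5-fold CV selects the subset
size minimizing mean absolute error, the metric chromatographers care
about. A forced feature count (e.g. 6/9/12-feature models for
interpretability studies) runs the same elimination to exactly that count.

Learner selection compares linear regression, a 500-tree random forest,
and rbf-SVR over a 7 × 7 log-spaced grid of C and γ spanning
[0.001, 1000]. Each candidate is scored by the same inner CV; the winner
maximizes mean r², with ties broken by lower mean MAE and then by
simplicity (linear < svr < random forest) so degenerate ties resolve
deterministically toward the cheaper model. The outer 5-fold CV reports
per-fold r² and MAE (mean, median, sd) *of the whole pipeline*, then the
pipeline is refit on all rows for the final model. The persisted bundle
embeds every preprocessing statistic plus a format version, so a reloaded
model predicts bit-identically with no access to training data, and files
from a future incompatible layout fail loudly.

Minimum training size is 10 rows — enough for the internal 5-fold CVs to
function. That is a mechanical floor, not a recommendation: useful QSRR
models start around 50–100 compounds.

## Evaluation conventions

The best-fit line regresses predicted (y) on measured (x) retention time,
so a perfect model reads y = x; this orientation matters for slope and
intercept and is stated wherever they are reported. Signed errors are
predicted − observed minutes; percent errors divide by the observed time
(which must be positive). Band fractions count |error| ≤ 1 and ≤ 2 min
inclusively. The validity filter drops predictions whose percent error
*strictly* exceeds 35 % — the boundary value stays. Paired and unpaired
two-sided t-tests are implemented from the textbook Student formulas (and
cross-checked against an independent statistics library in the tests);
identical paired samples return t = 0, p = 1, while constant nonzero
differences leave the statistic undefined and raise.

## Study protocol

`run_protocol` reproduces the replicate-model experiment design: for each
of `n_splits` independent seeded shuffles, the first 75 % of rows (or an
absolute `train_n`; ceiling on fractional sizes) train `replicates`
models that share the split's test set and differ only through the seed
(`base_seed + 1000·split + replicate`). Descriptor filters are refit per
training set. Each model is scored after extrapolation exclusion, and a
feature-usage table counts in how many models each descriptor was
selected — the cross-model core of recurring features (hydrophobicity
measures such as SLogP chief among them on lipid-like data) is the
protocol's interpretability output. Failed replicates are recorded with
their reason, never silently dropped.

## Synthetic data

Two generators make every stage testable without instrument data.

`gen_matrix` emulates a post-filter descriptor matrix: i.i.d. standard
normal noise features; a few informative features driving retention either
linearly or through sin(2x) terms (a smooth nonlinearity an rbf kernel can
fit but a line cannot); optional affine-copy blocks (jittered) for the
correlation filter; near-constant columns at 95 % duplication and
high-missing columns at 80 % missingness, both constructed to cross the
default thresholds. Retention noise defaults to 0.1 min, mid-range of the
0.005–0.2 min replicate spread typical of stable LC-MS features. The
default retention offset is 18 min — the long end of real HILIC gradients
— placed more than five signal standard deviations above zero so the
default spec cannot generate the non-positive retention times the
generator rejects.

`gen_series` builds homologous series of real molecules — n-alkanols or
straight-chain fatty acids — with retention linear in chain length
(default 1 + 0.35·n<sub>C</sub> min, spanning ~1.7–15 min over chains
2–41). This mirrors reverse-phase lipid behaviour, where members of a
family share a backbone and retention tracks hydrophobicity, giving the
descriptor pipeline a known monotone driver (SLogP) to find.

What the generators do *not* emulate: correlated descriptor structure of
real molecules beyond the planted blocks, heavy-tailed retention noise of
poorly-retained phosphate-bearing compounds on HILIC (0.4–1 min spreads),
and chemistry-specific failure modes (isomers indistinguishable by 2-D
descriptors). Passing tests therefore demonstrate that the machinery is
correct and leak-free under its stated assumptions — not that any
particular column's chemistry is predictable.

## Verification sizes and numerical choices

The end-to-end checks run at study settings (500-tree forests, 5 + 5-fold
nested CV, default filters) with problem sizes chosen to keep a full run
on one core tractable: planted-feature recovery uses 200 compounds with
3 informative (+/-2 coefficients) among 53 features over 10 seeds
(75/25 split, linear fit on the selected subset); the filter stack is
cross-checked against a brute-force reference on 100 random planted
matrices up to 20 × 15; the homologous-series run uses 40 compounds over
5 seeds; the training-size protocol uses 240 compounds, 3 informative +
20 noise features, sizes 60/120/180 with 2 splits × 1 replicate and the
linear learner. Scores are compared with exact float equality only where
determinism is the property under test; statistical properties use the
tolerances stated with each check.

Tie-breaks, boundaries and degenerate inputs are all pinned: inclusive
filter thresholds, exclusive 35 % error filter, inclusive-keep
extrapolation boundary, earlier-column wins correlation ties,
simplicity-order model ties, constant targets and all-constant training
matrices raise typed errors.

## Known limitations

2-D descriptors cannot separate stereoisomers or E/Z isomers; compounds
whose retention depends on such features need curated training sets. The
correlation filter's greedy order-dependence means renaming/reordering
input descriptor columns can change *which* of a correlated pair
survives (never whether the pair is pruned). Random-forest training
dominates runtime; at ~400 surviving descriptors and 200 compounds a full
nested search takes minutes, which is the intended scale.
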