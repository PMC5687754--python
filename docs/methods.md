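# Methods

This note documents the statistical model, the algorithmic and numerical
choices, and what the synthetic-data generators do and do not emulate.

## Model family

All supervised methods in the package are instances of one alternating
covariance-maximisation scheme over a set of *blocks* — the predictor
matrices X₁…X_B plus the outcome side Y. Given centred/scaled blocks and
a symmetric B × B design matrix *D* of connection weights (diagonal 0,
entries in [0, 1]), one component is extracted by iterating, until the
loadings stop moving:

1. for each block *b*: form the target
   z_b = u + Σ_{j≠b} D_{bj} t_j (the outcome score *u* is always
   included with weight 1),
   set w_b = X_bᵀ z_b, soft-threshold w_b to its keepX_b largest
   entries, renormalise to unit length, and update t_b = X_b a_b;
2. update the outcome loading c ∝ Yᵀ Σ_b t_b (unit norm) and score
   u = Y c.

This is a Horst-type alternating scheme: each update maximises the sum
of design-weighted covariances between connected scores, subject to the
unit-norm and cardinality constraints. With B = 1 the loop reduces to
the classic NIPALS inner loop of two-block PLS, whose fixed point is the
dominant singular-vector pair of XᵀY — the basis of the SVD oracle used
in the tests.

Choices worth stating explicitly:

- **Outcome coding.** The categorical outcome enters as an N × K dummy
  indicator, centred but *not* scaled. Centring leaves XᵀY unchanged
  (columns of X are centred), keeps the SVD characterisation exact, and
  makes predicted dummy values directly interpretable against 0/1.
- **Deflation.** Regression mode everywhere: each X block is deflated by
  its own score (X ← X − t pᵀ with p = Xᵀt/tᵀt), and Y is deflated by
  regression on the mean of the block scores (identical to the
  single-block rule when B = 1). Scores of one block are therefore
  mutually orthogonal.
- **Sparsity.** keepX survivors are the largest |w|, each shrunk by the
  (keepX+1)-th largest magnitude (soft thresholding); the result is
  renormalised to unit length. Ties at the selection boundary are broken
  by feature index, and the threshold is nudged just below the smallest
  kept magnitude so the nonzero count is exact even under ties.
- **Initialisation and signs.** Loadings start at the first left singular
  vector of X_bᵀY. After convergence each loading is flipped so its
  largest-magnitude entry is positive (ties → lowest index); the outcome
  side is then flipped to keep u positively associated with the scores,
  so predictor- and outcome-space variates of a sample agree in
  orientation (this is what makes short arrows in the arrow plot mean
  "good agreement"). The whole fit is deterministic: identical input
  gives bitwise-identical output.
- **Convergence.** Tolerance 1e-6 on the maximum absolute loading change,
  at most 100 iterations; both are recorded per component, and
  non-convergence is a warning (typically seen on tiny CV folds), never
  an error.
- **Standardisation.** Column sd uses the N−1 denominator; constant
  columns stay at zero after centring with sd recorded as 1, so
  projection of new samples never divides by zero.
- **Default design.** When no design matrix is given for a multi-block
  fit, block–block weights are 0.1 and every block–outcome connection
  is 1 — a weakly-connected compromise between cross-block agreement and
  discrimination; fully user-overridable.
- **Multi-study fits.** Each feature is centred (and scaled) within each
  study before the global solve, which removes additive study offsets
  exactly and multiplicative ones after scaling. Loadings are global;
  scores can be read globally or per study. Studies need ≥ 2 samples
  (≥ 3 recommended when scaling).

## Prediction

New samples are standardised with the training parameters (per-study
parameters for multi-study models; an external study with ≥ 3 samples is
standardised by its own moments, smaller ones fall back to the global
training parameters), then pushed through the stored deflation sequence:
t_h = X a_h, X ← X − t_h p_hᵀ. Self-projection reproduces the training
scores exactly.

Predicted dummy values at depth *h* come from the least-squares
regression of the raw indicator on the first *h* training scores (with
intercept — the class proportions, since scores are centred). The
distances:

- `max` — argmax of the K predicted dummy values;
- `centroid` — nearest class centroid of training scores (Euclidean);
- `mahalanobis` — nearest centroid under the **pooled within-class
  covariance** of the training scores. The estimator is a package choice;
  a singular covariance falls back to the centroid rule with a warning.

Multi-block votes: majority (ties → `None`) and weighted, where a
block's weight is the mean over components of the multiple correlation
between its score and the outcome indicator (the plain |r| when K = 2) —
a symmetric, scale-free aggregation. All predictions are reported at
every depth h = 1…H; the headline is depth H.

## Tuning and evaluation

- Stratified M-fold CV × repeats: per class, shuffled indices are dealt
  round-robin from a random starting fold, so per-fold class counts are
  within one sample of proportional. Leave-one-group-out CV uses the
  studies as folds.
- keepX is tuned one component at a time (earlier components frozen at
  their chosen values), minimising BER (default) or the overall error
  under a chosen distance (default `centroid`; the tuning and reporting
  distances are independent knobs). Ties → smallest keepX (multi-block
  factorial grids: smallest total, then lexicographic). Tie predictions
  (`None`) count as errors — an instability penalty.
- BER is the unweighted mean of per-class error rates, so minority
  classes are not swamped.
- The number of components: one-sided paired t-tests across CV repeats
  ask whether depth H+1 beats depth H; the first non-significant step
  (α = 0.05) stops. A flat curve yields H = 1.
- `perf` refits the model inside every training fold (selection is
  repeated per fold), evaluates held-out samples at every depth under all
  three distances, and records per-fold selections; stability is the
  selection frequency across those refits. ROC/AUC is computed one-vs-all
  on the predicted dummy values, per fold, and averaged; tied thresholds
  are grouped before the trapezoid. Since the classifiers are
  distance-based, AUC is reported as a complement, not the headline.

## Plot backends

Correlation circles and similarity networks use feature–component
correlations on the standardised training data; the similarity between
two selected features is Σ_h r(x_i, t_h) r(x_j, t_h) over the retained
components (each feature against its own block's component), with the
conventional |r| > 0.7 cut-off for network edges. The clustered image map
uses Euclidean distance with complete linkage on both axes. Confidence
ellipses are per-class bivariate-normal 95% contours. Arrow plots join
each sample's predictor-space variate (averaged over blocks) to its
outcome-space variate.

## Synthetic data

The generators produce the structure the methods assume, with defaults
chosen once as typical study conditions: Gaussian noise of unit sd
(Student-t with 3 df as a heavy-tail option), planted marker effects of
1.5 sd — detectable but individually overlapping — and, for multi-study
data, additive offsets of 2 sd and multiplicative factors exp(N(0, 0.2²))
per study/feature, a strong batch regime.

- `gen_single` plants each informative feature as a *marker*, shifted up
  by the effect size in exactly one class. With K ≥ 3 the last class
  carries no markers and is characterised by being low on every
  signature — a marker-negative reference group, as with a control or
  triple-negative subtype. This keeps the planted signature aligned with
  the leading discriminant contrasts; a fully symmetric assignment (one
  marker set per class) would place one class's markers in a direction
  the first component structurally cannot carry, making single-component
  recovery experiments ill-posed rather than hard.
- `gen_multiblock` routes the class signal through shared latent factors
  (one contrast per factor, K−1 by default): informative feature =
  γ·factor + √(1−γ²)·noise, so paired informative features across blocks
  correlate at γ² given the class, and γ = 0 removes both the class
  signal and the cross-block correlation.
- `gen_multistudy` applies per-study offsets and scale factors on top of
  a study-invariant marker signal; classes are dealt round-robin so every
  study contains every class.
- `inject_missing` masks cells at a nominal rate, guarded against fully
  missing rows/columns.

What the generators do **not** emulate: count-data distributions and
library-size artefacts, feature–feature correlation beyond the planted
modules/factors, outliers, non-linear class boundaries, or class signals
that differ across studies. Passing tests on these data therefore
demonstrate correctness and calibration of the machinery, not performance
on any particular real platform.

## Problem sizes

The test suite and the acceptance script run everything on generated data
at moderate sizes chosen to make the statistical contrasts unambiguous on
one CPU: recovery experiments at 60 × 500 with a 20-marker signature over
10 seeds (5-fold CV × 10 repeats), batch-robustness at 45 × 200 × 4
studies, null calibration at N = 300–500 averaged over 6 permutations,
and the microarray-scale shape checks at 63 × 2308. Larger problems
change runtimes, not conclusions.

## PCA with missing values

PCA uses the NIPALS power loop; with missing cells the inner products
skip unobserved entries and deflation subtracts the rank-1
reconstruction on observed cells only. Near-degenerate eigenvalue pairs
make power iterations slow, so the loop allows a large iteration budget
(20000) at tolerance 1e-12 — still milliseconds at these sizes.
`nipals_impute` refines the initial reconstruction EM-style (fill, refit
on the completed matrix, re-fill) until the imputed cells stabilise;
on exactly low-rank data this recovers held-out cells to numerical
precision.

## Known limitations

- The multi-block objective is maximised block-wise (Horst scheme);
  other schemes (centroid/factorial) are not implemented.
- Canonical-mode (symmetric) two-block deflation is not exposed; all
  supervised fits use regression deflation.
- Missing values are accepted only by PCA/imputation, not by the
  supervised fits — impute first.
- AUC on distance-based classifiers ignores the fitted decision rule;
  treat it as descriptive.
- The t-test rule for the number of components needs CV repeats; with a
  single repeat it falls back to strict improvement, which is greedier.
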