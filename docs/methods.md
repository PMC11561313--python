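# Methods

## The favourability transform

A presence/background SDM with a binomial response and logit link predicts
the probability of presence

P(x) = e^η / (1 + e^η),  η = α + Σᵢ βᵢ xᵢ.

P is confounded with the training prevalence n₁/(n₁+n₀): doubling the
background sample halves every predicted probability, which makes maps of
species with different record counts incomparable. Environmental
favourability removes this by rescaling the odds against the training
odds:

F = (P/(1−P)) / (n₁/n₀ + P/(1−P)),  with F(0) = 0 and F(1) = 1 as limits.

For a logistic model this is *identical* to the same model with intercept
α − ln(n₁/n₀) — an algebraic identity the test suite asserts to 1e−12 —
so no second model fit is needed, and the closed odds form also defines
favourability for non-parametric probability output (boosted trees), where
no intercept exists. F = 0.5 exactly where P equals the prevalence, which
makes 0.5 the natural crisping threshold for binary comparisons. The
package never converts relative-suitability (Maxent-style cumulative)
output to favourability: those values are not probabilities of presence,
and `favourability_surface` rejects them.

Assumptions worth keeping in mind: the transform corrects the *global*
intercept-level effect of prevalence. Finite-sample estimation noise in
the coefficients still differs between subsampled datasets, so empirical
favourability surfaces at different prevalences agree closely (Pearson
r ≥ 0.98 in the test conditions) but not perfectly.

## Fuzzy comparison of surfaces

Favourability is read as a fuzzy membership degree in "areas favourable to
the species". With only min/max operators (no algebraic t-norms):

- intersection/union: cellwise min / max;
- fuzzy overlap index FOvI = Σ min(F_A,F_B) / Σ max(F_A,F_B) over valid
  cells (0 = disjoint, 1 = identical); the same ratio is the fuzzy Jaccard
  similarity;
- binary Jaccard: surfaces crisped at 0.5, then |A∩B|/|A∪B| on cell sets;
- shared-favourability profile: cells binned by their overlap
  o = min(F_A,F_B) into ten equal-width bins of [0,1] (bin edges computed
  as b/10 exactly; a value on an edge goes to the upper bin, the last bin
  is right-closed); per bin, mean F_A and F_B with symmetric Student-t
  confidence intervals at 0.95 (bins with fewer than two cells are flagged
  and get no interval). Equal-width bins were chosen over quantile bins
  for determinism and interpretability of the x-axis;
- fuzzy entropy (Kosko): Σ min(μ,1−μ) / Σ max(μ,1−μ) — 0 for a crisp
  surface, 1 when every membership is 0.5. The logarithmic
  De Luca–Termini entropy would serve the same role; the min/max form was
  chosen for consistency with the other operators.

## Models

All four families consume a site × predictor table with response 1
(presence record) / 0 (random background point). Background points are
treated as plain 0/1 pseudo-absences without case weights.

- **GLM** — maximum-likelihood logistic regression (statsmodels Newton
  IRLS). Complete separation triggers a small-ridge fallback that is
  flagged on the fitted model.
- **GAM** — per-predictor cubic B-spline basis (default 4 functions,
  quantile knots after standardisation) under one penalized logistic fit,
  with the ridge strength selected by internal 5-fold cross-validation
  over C ∈ 10^{−3..3}. A penalized-basis formulation was preferred over
  backfitting smoothers because it keeps a single logistic fitting engine
  and preserves the intercept algebra that the favourability identity
  relies on.
- **BRT** — gradient boosting with Bernoulli deviance, learning rate 0.01,
  interaction depth 3, 75 % subsampling; the number of trees is chosen at
  the held-out deviance minimum on a stratified 20 % split, then the model
  is refit on all rows. Depth-3 trees wiggle visibly on one-dimensional
  monotone signals; for known-additive data depth 1 is the appropriate
  setting.
- **Maxent-like** — an L1-regularized logistic fit on standardized linear
  + quadratic features, exploiting the large-sample equivalence between
  Maxent and a Poisson point-process model. The raw exp-linear intensity
  is converted to the cumulative representation (a cell's value is 100 ×
  the summed normalized weight of cells with lower-or-equal raw intensity,
  ties sharing one value), computed within whatever cell set is being
  predicted, and rescaled to [0,1]. The output is *relative* habitat
  suitability: it is excluded from favourability conversion and from the
  Hosmer–Lemeshow test, and it enters fuzzy comparisons only when forced.
  Bit-compatibility with the Java Maxent is a non-goal.

Skill is summarized by stratified 5-fold cross-validation repeated 10
times (fold seeds derived from the run seed), reporting AUC, TSS, CCR,
sensitivity and specificity per fold. The classification threshold
defaults to the training-fold prevalence — consistent with F = 0.5 ⇔
P = prevalence — with fixed and max-TSS rules available.

## Evaluation metrics

AUC is the rank-sum (Mann–Whitney) statistic with midrank tie handling,
identical to the trapezoidal ROC area and to exhaustive pair counting.
TSS = sensitivity + specificity − 1 is prevalence-independent; CCR is the
overall accuracy. The Hosmer–Lemeshow test uses equal-frequency (decile)
bins of the predicted probability (ties on a quantile edge fall to the
lower bin), χ² = Σ_bins [(O₁−E₁)²/E₁ + (O₀−E₀)²/E₀] with E₁ = Σ pred,
df = bins − 2, upper-tail p-value. The reported RMSE is on the per-bin
*count* scale, √(mean (O₁−E₁)²): count-scale errors can exceed 1, which
matches how the statistic is conventionally reported by the R tooling this
mirrors; a proportion-scale reading is not used. Bins with a zero expected
count are computed with a 0.5 guard and flagged.

## Preprocessing

- **Spatial thinning** — iterative elimination: while any pair of retained
  points lies closer than the minimum great-circle distance (haversine,
  Earth radius 6371.0088 km), delete a point with the most conflicting
  neighbours (random tie-break); the randomized pass is repeated (default
  100 reps) and a run keeping the most points is returned. The minimum-
  distance guarantee holds on every run; the retained count is heuristic,
  matching the exhaustive optimum on ≥ 80 % of small random instances in
  the test conditions. Defaults: 10 km, 100 reps.
- **Predictor pruning** — pairwise Pearson correlations over valid cells;
  while any kept pair has |r| > 0.8, drop the member with the largest mean
  absolute correlation to the other kept predictors (alphabetical
  tie-break). The rule is deterministic and idempotent on its own output.
  Zero-variance predictors are reported as undefined and set aside.

## Synthetic data

The generator emulates the statistical structure of a bioclim-style SDM
study without any external data:

- **Landscapes** — each predictor layer is white noise convolved with an
  isotropic Gaussian kernel (scale = `smoothness` cells, default 5–6),
  standardized; layers are empirically orthogonalised and re-mixed through
  the Cholesky factor of a requested correlation matrix, so achieved
  pairwise correlations hit the target to well within ±0.05. Kernel-
  smoothed noise was chosen over geostatistical simulation for simplicity
  and direct control of smoothness.
- **Species** — logistic niches on one to three layers, optionally with
  negative quadratic terms (unimodal response). Presences are drawn
  without replacement with probability proportional to P and placed at
  cell centers so raster extraction is exact; background points are
  uniform over valid cells (default 10,000, with replacement allowed).
- **Default study** — three correlated layers; two species sharing two
  niche axes; a widespread species (prevalence ≈ 0.10 against the
  background sample) and a restricted one (≈ 0.02), the contrast that
  motivates the prevalence-free transform.

What the generator does *not* emulate: climate seasonality semantics,
sampling bias in occurrence records (background is uniform), observation
error, and spatial autocorrelation of residuals beyond layer smoothness.
Passing tests therefore demonstrate correctness of the algebra and
algorithms under ideal presence/background sampling, not robustness to
real-world data pathologies.

## Problem sizes and determinism

The demo pipeline and `scripts/acceptance.py` run the default study at a
reduced scale (scale 0.2: a 45 × 45 grid with 2,000 background points,
BRT capped at 300 trees) so a full run with 5 × 10 cross-validation for
all four algorithms completes in about 1–2 minutes on one core; the
generator's documented defaults (100 × 100, 10,000 background) remain the
reference conditions and are what `default_study` produces when called
without arguments. Every stochastic step is a pure function of the run
seed; the pipeline manifest records the seed and a configuration hash.

## Known limitations

- The thinning heuristic is not guaranteed optimal (validity is).
- The GAM uses one global ridge penalty across predictors rather than
  per-term smoothing parameters.
- Favourability assumes the fitted model's probabilities are calibrated;
  favourability from a miscalibrated model inherits the miscalibration.
- The cumulative Maxent-like output depends on the cell set over which it
  is computed; comparing cumulative surfaces from different extents is
  not meaningful.
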