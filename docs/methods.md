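# Methods

This note describes the statistical model, the estimation and inference
procedures, the synthetic-cohort generator, and the main numerical choices
and limitations of the `pushpull` package.

## Data model

The input is a long-format cohort table with columns `animal_id`, `sex`,
`age_years`, `biomarker`, `value`, `lab_code`: many animals, each observed
at irregular ages over decades, with a panel of clinical biomarkers per
visit, occasional same-day repeat draws, and per-biomarker missingness.

## Preprocessing

1. **Exclusions.** Configurable threshold rules remove physiologically
   implausible records (defaults: Albumin below 2, RDW above 40), and a
   drop list removes biomarkers that are deterministic functions of others
   (default: GFR, leaving 43 of the 44 panel measures).
2. **Log transform.** Per biomarker, the skewness of the raw values is
   compared with the skewness of `log(value + delta)`, where the
   pseudocount `delta` is the smallest positive increment observed between
   distinct recorded values. The transform with smaller absolute skewness
   is kept (ties keep raw; a forced override is available per biomarker).
3. **Age-drift removal.** Per (animal, biomarker), a least-squares line in
   age is fitted using only ages >= 5 years and only values inside that
   series' 1st-99th percentile range; series with fewer than 3 eligible
   points fall back to the biomarker's pooled slope. The fitted line is
   subtracted.
4. **Normalization.** Each (animal, biomarker) residual series is
   standardized to mean 0, variance 1 (unbiased variance). Zero-variance
   series are dropped with a warning.
5. **Increment diagnostics.** For each biomarker, squared increments
   between consecutive visits are binned into 12 equal-count bins over
   sqrt(dt); per-bin histograms (18 boxes, scaled to max 1) and a linear
   regression of squared increment on dt summarize how variance grows with
   the time gap. For a biomarker with drive variance `Q_vv` and observation
   noise `R_vv`, the regression has slope `Q_vv` and intercept `2 R_vv`,
   which is how the two noise sources are told apart.

## The pairwise SDE model

Each ordered biomarker pair (v, w) is modeled as a 2-dimensional linear
stochastic differential equation with noisy observations:

    dX = [a + A X] dt + B dW,      Y_i = X(t_i) + C eps_i,

with drive covariance `Q = B B^T` and observation-noise covariance
`R = C C^T`. Free parameters: `a` (2), `A` (4), `Q` (3), `R` (3) — 12 in
total. The initial state carries a fixed standard-normal prior. Off-diagonal
entries of `A` are the directed interactions: `A[target, source]` is the
response rate of the target to the source's displacement.

Between consecutive observations the SDE is discretized with a single
Euler step per gap: transition mean `x + (a + A x) dt`, transition
covariance `dt * Q`. Same-day repeats (`dt = 0`) share the latent state and
differ only by independent observation noise; this is what identifies `R`
separately from `Q`.

## Estimation

Parameters are estimated by EM on the exact linear-Gaussian state-space
likelihood, pooled over animals:

- **E-step.** A Kalman filter (Joseph-form updates, missing components
  handled by sub-block selection) and RTS smoother with lag-one
  cross-covariances produce the posterior moments of the latent states.
  The expected sufficient statistics are the weighted regression blocks of
  the complete-data likelihood for `(a, A, Q)` over all `dt > 0` gaps, and
  the expected noise outer-products for `R` over all observation times.
  When a component of an observation is missing, the 2-vector of
  observation noise is treated as latent and its conditional moments under
  the current `R` are used, so the `R` update below is an exact M-step.
- **M-step.** `(a, A)` solve the generalized-least-squares normal
  equations (weight `1/dt`); `Q` is the expected residual outer-product
  per unit time; `R` is the mean expected noise outer-product. Both are
  clipped to the positive-semidefinite cone (eigenvalue floor 1e-10).
- Exactness of both steps makes the log-likelihood trace non-decreasing;
  the test suite enforces this to 1e-9 relative slack, and convergence is
  declared on a 1e-6 relative change.
- The filter/smoother is cross-checked against a brute-force oracle that
  builds the full joint Gaussian of the latent chain and conditions on the
  observed components (agreement to 1e-8 relative on random instances with
  `dt = 0` and missing data).

## Permutation inference

The null hypothesis for an interaction `A[v, w]` is that it is zero. A
label-shuffled null is built by randomly permuting each animal's in-window
visit time labels (never across animals), moving whole visit vectors so
contemporaneous cross-biomarker correlations are preserved while temporal
ordering is destroyed. The same K permutations (default 256) are reused
for every pair, so null estimates are trial-aligned across hypotheses.
Each parameter's observed estimate is converted to
`z0 = (obs - mean(null)) / sd(null)` and a two-sided Gaussian p-value
`p0 = erfc(|z0| / sqrt 2)`, computed in log space so extreme z-scores do
not underflow. Two multiplicity adjustments are reported:

- Bonferroni `p_b = min(1, J p0)` with `J = N(N-1)` for directed terms and
  `N(N-1)/2` for drive-covariance terms on an N-biomarker panel;
- an empirical step-down max-|z| (Holm-type) adjustment computed from the
  trial-aligned null z-score matrix, which respects the dependence between
  hypotheses because trial k uses the same permutation everywhere.

Results are exported as signed log-p matrices (sign of the estimate times
`ln p`), with a fingerprint comment line recording seed, K and age window.

**Calibration caveat.** The time-label shuffle destroys *all* temporal
structure, not just the directed interactions. When the data themselves
are temporally continuous (drive variance `Q > 0`), shuffled refits are
fit to effectively time-scrambled series and their spread overstates the
sampling variability of the estimator on the real data; the resulting
p-values are conservative, increasingly so the stronger the serial
dependence. In the interaction-free case (`A = 0` with `Q > 0`, a random
walk) the inflation is severe — the acceptance suite measures the z-score
spread and the fraction of nominal rejections on such cohorts and finds
the test far below its nominal level, while an exchangeable control
(serially independent observations) is approximately calibrated. The
conservative direction means reported detections remain valid; nominal
levels are upper bounds on the false-positive rate.

## Interaction structure

The signed score matrix `Z[target, source] = sign(estimate) * |z|` is
searched for *push-pull blocks*: disjoint sets (V sources, V' targets)
where every V -> V' effect is excitatory and every reciprocal effect
inhibitory. The score is the sum of `Z[w, v] - Z[v, w]` over the block,
normalized by `sqrt(|V| |V'|)`. A greedy maximizer (net-flow
initialization, single-element side swaps, then peeling) extracts blocks
iteratively; each block's significance is a Monte-Carlo p-value against a
null that reassigns reciprocal value pairs `(Z_ij, Z_ji)` to uniformly
random slots with coin-flip orientation, preserving the value
distribution while destroying who carries it. Drive-covariance structure
is displayed by ordering biomarkers along the leading eigenvector of the
symmetric z-score matrix (sign fixed to the majority-positive convention,
lexicographic tie-break).

## Group contrasts

Observations are split by sex filter and half-open age windows `[lo, hi)`
into two disjoint groups. Each group is fitted independently; the
difference of estimates `delta = est_g1 - est_g2` is tested against
trial-aligned null differences (trial k of group 1 minus trial k of group
2). Each group's permutation stream is keyed by the group's name, so
swapping the two groups flips every delta's sign and leaves every p-value
unchanged, exactly; contrasting a group with itself yields `delta = 0`
and `p0 = 1` by construction.

## Synthetic cohorts

The generator draws, per animal: a lifespan uniform in a range, visit
times with exponential gaps truncated to [1 day, 2 years], occasional
same-day repeat visits, a latent N-dimensional SDE path simulated by
Euler-Maruyama at internal steps of at most 1 day, observations with
Gaussian noise `R`, per-animal linear age drift (slope plus jitter),
per-component missingness, and optional exponentiation of designated
biomarkers to a positively skewed raw scale. The default study-scale
specification has 144 animals, 43 biomarkers, one planted 3-source /
6-target push-pull block at +-0.5/yr, a drive covariance with two
anticorrelated groups, lifespans 20-50 years and a 0.25-year mean visit
gap; a `scale` argument shrinks animal and panel counts proportionally.
The observable table never contains the ground truth; a scoring helper
reports sign accuracy, absolute error, false-positive rate and block
Jaccard overlap against the generating spec.

Because the generator integrates the SDE at fine internal steps while the
fitted model uses one Euler step per observation gap, every recovery test
runs under realistic discretization mismatch; recovery tolerances were
set with this mismatch present.

## Numerical choices

- Filter/smoother run in a compiled kernel with explicit 2x2 algebra;
  covariance updates use the Joseph form; singular innovation covariances
  and non-finite propagation raise errors naming the animal and index.
- `p0` is computed via `log_ndtr` so `|z| ~ 40` still yields a finite log
  p-value; Bonferroni is applied in log space for the exports.
- Monte-Carlo p-values use the `(1 + count) / (n + 1)` smoothing, which
  keeps them in `(0, 1]`.
- PSD projections clip eigenvalues at 1e-10; regression designs with
  condition numbers above 1e12 raise an estimation error rather than
  returning unstable coefficients.

## Limitations

- The one-step-per-gap discretization biases dynamics estimates for gaps
  long relative to the system's relaxation time; this is intentional
  model realism for irregular clinical sampling, not a numerical bug.
- Permutation p-values are conservative on serially dependent data (see
  the calibration caveat above); they remain valid as upper bounds on
  type-I error. The same null-spread inflation limits power: in the
  acceptance suite's group-contrast benchmark the planted difference is
  estimated essentially exactly in every replicate, yet the shuffle-null
  spread of the difference is an order of magnitude larger than the
  estimator's sampling spread, so few replicates reach significance.
- Pairwise fits marginalize over the other N-2 biomarkers; detected
  interactions are bivariate-screen effects, not partialled network
  edges.
- The greedy block search is a heuristic; it is verified against
  exhaustive enumeration only at small panel sizes.
- No survival/dropout modeling, no change-point dynamics, at most two
  groups per contrast.
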