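# Methods

## Model

Network inference is cast as `P` independent time-lagged regressions.
For target gene `i`, every replicate contributes the sample pairs
(regulator values at `t`, target value at `t+1`) for `t = 0 … T_r − 2`;
pairs never span replicate boundaries and the lag is one index step
regardless of wall-clock spacing (non-uniform sampling intervals are
deliberately ignored — the model is index-based).  By default every gene
except the target is a candidate regulator; a restricted regulator list
(e.g. annotated transcription factors) can be supplied.

Each per-target model is an ensemble of CART regression trees fitted by
one of two boosting schemes:

* **AdaBoost.R2** — per round: draw a size-N bootstrap with probability
  proportional to the maintained sample weights; fit a tree to the
  bootstrap; compute linear losses `err_i = |y_i − f(x_i)| / max_j |y_j −
  f(x_j)|` on the *original* N samples; average them under the
  renormalized weights to get `L̄`; set `β = L̄/(1−L̄)`, update `w_i ←
  w_i β^(1−err_i)`, and record the estimator weight
  `learning_rate · log(1/β)`.
* **Gradient boosting** — start from the target mean; each round fit a
  tree to the residuals of the current additive model on the full data
  and add it scaled by the learning rate.

Edge evidence is variance-reduction variable importance.  A tree node
splitting on regulator `G` contributes `w(S)Var(S) − w(S_L)Var(S_L) −
w(S_R)Var(S_R)` (weighted counts and weighted population variances when
sample weights are active); a regulator's per-tree score sums these over
the nodes that split on it, and the ensemble score is the
estimator-weighted **sum** of per-tree scores for AdaBoost and the plain
average for gradient boosting.  The AdaBoost aggregation is often called
a weighted average, but no division by the weight total is performed —
the literal weighted sum is used; with per-target normalization on
(the default) the distinction cancels anyway.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_rounds` | 100 | boosting rounds per target (ensemble size) |
| `max_depth` | 3 | depth cap of each base tree |
| `learning_rate` | 1.0 (AdaBoost) / 0.1 (gradient boosting) | estimator-weight scale / shrinkage |
| `standardize` | on | scale each gene's pooled series to mean 0, population SD 1 |
| `normalize_importance` | on | rescale each target's importance vector to unit sum |
| `threshold` | 0.25 | strict (>) score cutoff for network reconstruction |

Standardization uses the population SD pooled across replicates; a
zero-variance gene is centred only (warned, not fatal).  Whether to
standardize before fitting is genuinely open for this family of methods;
it is on by default because tree ensembles are scale-invariant for
*splitting* but the importance magnitudes — and hence the fixed 0.25
threshold — are not.  Per-target unit-sum normalization makes scores
comparable across targets (with ~20 regulators a score of 0.25 then
means "a quarter of this target's total explained variance"); raw
importance values are available by flag, and within one target's column
the two conventions induce the same regulator ranking.

The 0.25 threshold applies to normalized scores by default.  Both
normalization and thresholding are exposed as independent flags because
the appropriate combination depends on how many regulators a dataset
has.

## AdaBoost edge policies

Three situations end boosting early.  A round whose tree fits every
sample exactly (zero maximal loss) is kept with the capped estimator
weight `learning_rate · log(1/1e−10)` — β would otherwise be 0 and the
weight infinite — and boosting stops.  A round with `L̄ > 0.5` is
discarded and boosting stops; at `L̄ = 0.5` exactly the round is kept
with weight exactly 0 (β = 1) and boosting stops.  If the very first
round is discarded no valid ensemble exists and the fit raises rather
than return an empty ensemble.

## Numerical choices

Split search maximizes weighted variance reduction with thresholds at
midpoints between consecutive distinct sorted feature values.  Node
scores are computed on node-mean-centred targets: the reduction is
shift-invariant, and centring avoids the catastrophic cancellation that
raw moment sums (`Σwy² − (Σwy)²/Σw`) suffer when the mean dominates the
spread.  Candidates within `1e−10` relative of the best reduction are
treated as exact ties.

Ties are broken by the **lowest threshold value, then the lowest feature
index**.  Tie-breaking by feature index alone would make results depend
on gene ordering: ties across features are not exotic — any 2-sample
node is separated equally well by *every* feature — and the importance
of a tied split would then be attributed to whichever gene happens to
come first.  A threshold is a property of the data, unchanged by column
reordering, so the chosen rule keeps the whole pipeline equivariant
under gene permutations (verified by test).

Growth stops at the depth cap, at pure nodes, below 2 samples, or when
no split has positive reduction.  Leaf predictions are (weighted) means.
Tiny negative importance contributions from float rounding are clipped
at zero.

Per-target sub-seeds are spawned from the master seed keyed on the
target index (`numpy.random.SeedSequence(seed, spawn_key=(j,))`), so
targets can be fitted concurrently (joblib) with results identical to
sequential execution.

## Synthetic benchmark generator

The generator emulates the *structure* of the DREAM4 in-silico
time-course benchmark — 5 replicates × 21 time points, about one third
of the genes perturbed (a different subset per replicate) for the first
10 time points, perturbation then removed — but not its thermodynamic
ODE simulator.  Dynamics are a stable linear lag-1 Gaussian vector
autoregression

    x(t+1) = M x(t) + u(t+1) + ε,   M = diag(ρ) + Aᵀ,

with self-decays ρ ~ U(0.3, 0.7), signed edge weights ±U(0.5, 1.5)
shrunk until the spectral radius of `M` is below 0.95, perturbation
offsets ±U(0.5, 1.0) applied as forcing while active, and i.i.d. noise
ε ~ N(0, 0.05²) at every time point (about 5–10 % of the perturbation
signal — "moderate" for this kind of benchmark).  Linear dynamics were
chosen deliberately: they exercise lag-1 regression fully and admit a
closed-form least-squares recovery oracle (on noise-free runs, ordinary
least squares on the post-perturbation rows recovers `M` to machine
precision — asserted in the tests).

What this generator does *not* emulate: saturating/thermodynamic
regulation kinetics, mRNA/protein separation, measurement-specific noise
models, and steady-state heterogeneity.  Passing recovery tests
therefore demonstrates that the estimator extracts lag-1 dependencies
from realistically sized, perturbed, noisy multi-replicate data — not
that it matches any particular published score on real benchmark
datasets.

## Problem sizes used in tests

Unit and property tests run on instances up to N ≈ 50 samples and a few
features, where brute-force oracles (exhaustive CART search, pair
counting, step-by-step boosting transcripts) are exact and fast.  The
benchmark-scale recovery tests and the acceptance script use the 10-gene
generator defaults (5 × 21 time points, 100 boosting rounds), the size
at which per-network inference takes a couple of seconds; recovery is
averaged over several independently drawn networks because single-network
AUROC has a spread of roughly ±0.09.

## Known limitations

* Only lag-1 dependencies are modelled; longer or variable regulatory
  delays are out of scope.
* Edge sign (activation vs repression) is not called; importance is
  non-negative by construction.
* Importance-based scoring shares CART's known bias toward features
  offering many distinct split points; with standardized continuous
  expression data all regulators offer comparable split richness, so the
  bias is mild here.
* The AdaBoost estimator weight `log(1/β)` is unbounded as a round's
  average loss approaches zero; the β floor caps it at `lr · log(1e10)`,
  which dominates any ordinary round's weight — intended, since such a
  round fits the data perfectly.
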