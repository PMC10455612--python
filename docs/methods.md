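# Methods

## Model

`mggum` implements the multidimensional generalized graded unfolding model
(MGGUM) with between-item simple structure and optional person covariates.

For person *j* and item *i* loading dimension *d(i)*, the probability of
response category *z* ∈ {0..C} is

    P(Z_ij = z | θ_j) ∝ exp{α_i [z(θ_jd − δ_i) − Σ_{k≤z} τ_ik]}
                       + exp{α_i [(M−z)(θ_jd − δ_i) − Σ_{k≤z} τ_ik]}

with τ_i0 ≡ 0 and M = 2C + 1.  This is an ideal-point (unfolding) response
process: the endorsement probability peaks at θ = δ_i and falls off
symmetrically with distance.  The multidimensional kernel is the weighted
Euclidean distance √(Σ_d α_id²(θ_jd − δ_id)²) with threshold sums
ψ_ik = Σ_d α_id τ_ik; under simple structure (a single loading per item)
this reduces exactly to the unidimensional kernel on the loading dimension,
a reduction enforced by test.

Latent traits follow a latent regression

    θ_j ~ MVN(β′X_j, ω),

where ω is restricted to a correlation matrix (unit residual scale per
dimension) for identification, and the latent mean is zero with variance one
per dimension when no covariates are supplied.  A consequence of keeping the
printed model form rather than re-standardizing is that the marginal trait
variance exceeds 1 when β ≠ 0 (by Σ_p β_pd², ≈ 0.125 under the study's
covariate effect of 0.25); correlations and credible-interval decisions are
unaffected, and absolute-error metrics change only in the second decimal.

Missing responses are dropped from the likelihood (valid under missingness
completely at random); missing covariate values are rejected as unsupported.

## Priors

* α_i ~ logN(0, 0.5) — second argument an SD throughout.
* δ_i ~ N(−1, 1) with δ ≤ 0 for negative items, N(1, 1) with δ ≥ 0 for
  positive items, N(0, 1) unbounded for neutral items.  Items are labelled
  negative/positive when a user-supplied location classification puts them
  below −1.5 / above +1.5; boundaries count as neutral.  In simulations the
  label comes from the generating δ.
* τ_i1 ~ N(−2, 2) with two response options; (τ_i1, τ_i2, τ_i3) ~
  N(−3, 2), N(−2, 2), N(−1, 2) with four.  Thresholds are *not* constrained
  to be ordered (GGUM thresholds need not be monotone); ordering in
  simulated data arises solely from the disjoint generating intervals.
* β_pd ~ N(0, 1) independently; ω ~ LKJ(1) (uniform over correlation
  matrices).

## Posterior computation

No probabilistic-programming backend is used; the sampler is part of the
package:

* **HMC core.**  All continuous parameters — item parameters (log α,
  log |δ| for bounded locations, raw τ), latent traits, trait correlations
  and regression coefficients — are updated jointly by Hamiltonian Monte
  Carlo with analytic gradients.  ω is parametrized by canonical partial
  correlations through its Cholesky factor L (tanh-transformed to the real
  line); under LKJ(1) the partial correlations are independent with density
  (1−z²)^((D−2−c)/2), c the conditioning-set size — verified against
  rejection sampling of uniform positive-definite correlation matrices.
  The traits are *non-centered*: θ = Xβ + ηL′ with η ~ N(0, I) i.i.d.
  Both choices matter empirically: a Gibbs alternation ω | θ mixes an
  order of magnitude slower than joint HMC (the conditional is much
  tighter than the marginal posterior), and the centered parametrization
  leaves a θ–ω funnel that dominates the nonconvergence rate in weakly
  informed cells (few binary items per trait).
* **Step size and metric.**  Dual averaging targets 0.9 acceptance; the
  metric is block-diagonal with dense per-item blocks — (log α_i, δ_i, τ_i)
  are strongly correlated a posteriori (|r| up to ≈ 0.95) — and diagonal
  entries elsewhere, estimated in two warmup windows.  Leapfrog trajectory
  lengths are jittered uniformly on [L/2, L] with L = 32 by default.
* **Warmup annealing.**  The likelihood weight ramps linearly from ~0 to 1
  over the first quarter of warmup.  Without it, chains at large J can
  freeze into a self-consistent but inferior (θ, item) configuration (all
  locations compressed toward zero with inflated discriminations, a known
  GGUM ridge); annealing lets the prior-dominated early target deform
  continuously into the posterior.
* **Discrete mode moves.**  The unfolding likelihood has near-symmetric
  discrete sub-modes that gradient dynamics cross only rarely.  Three
  involutive Metropolis proposals address them directly: (i) per-item sign
  flips of neutral-item locations (a weak item's δ posterior can be bimodal
  at ±|δ|); (ii) per-person sign flips of one trait coordinate (a
  respondent who disagrees with everything fits both tails); (iii) during
  warmup only, whole-dimension reflections (θ_d, neutral δ on d, coupled
  correlations).  Items and persons are conditionally independent given the
  rest, so (i) and (ii) are evaluated for all items/persons in one
  vectorized pass per iteration.
* **Reflection canonicalization.**  A dimension whose items are all neutral
  has *exactly* reflection-invariant likelihood and priors, so its sign is
  pure convention.  Post-warmup states and retained draws are mapped to one
  fundamental domain of that symmetry (as in mixture-model relabeling);
  anchored dimensions are never altered by the estimator.  The recovery
  harness additionally aligns each dimension's sign with the generating
  truth before scoring — the standard alignment in factor-model recovery
  studies.  For unanchored dimensions this is a pure convention; for weakly
  anchored ones it keeps a rare mirror-image run from being scored as its
  own reflection (the alignment uses the truth and therefore lives in the
  scoring harness only, never in the estimator).

Defaults follow the study protocol: 2 chains × 2000 iterations, the first
1000 discarded as warmup (the iteration count includes warmup).  Convergence
is declared when the classic Gelman–Rubin potential scale reduction factor,
R̂ = √(((n−1)/n·W + B/n)/W), is below 1.05 for every retained scalar
parameter; zero within-chain variance is treated as nonconverged.
Divergent trajectories are counted and reported, never silently retained.

Point estimates are posterior means (EAP), uncertainties are posterior SDs,
and intervals are equal-tailed 95% quantiles; a covariate effect is called
significant when its interval excludes zero.

## Model comparison

WAIC and PSIS-LOO are computed from the pointwise log-likelihood matrix over
non-missing cells, on the deviance scale (−2 × elpd) so that smaller is
better.  p_waic uses the sample (S−1) variance.  PSIS follows the standard
recipe: generalized-Pareto fit (Zhang–Stephens) to the largest
min(0.2 S, 3√S) importance ratios, order-statistic smoothing truncated at
the raw maximum, per-observation k̂ reported and flagged above 0.7, with a
truncated-importance-sampling fallback when the tail is degenerate.  The
implementation is cross-checked in tests against an exact closed-form
leave-one-out calculation on a conjugate normal model and against an
independent library implementation.  Selection takes the smaller value per
criterion; exact ties resolve to the model listed first (callers list the
more parsimonious model first).

## Simulation studies

The generator reproduces the recovery-study design exactly: α ~ U(0.5, 2),
δ ~ U(−2, 2), τ ~ U(−3, −1) for two options or U(−3.5, −2.5), U(−2.5, −1.5),
U(−1.5, −0.5) for four; (θ, X) jointly multivariate normal with zero means,
unit variances, common trait correlation, independent covariates, and a
common trait–covariate correlation; responses drawn cell-wise from the
category probabilities; missingness completely at random with an exact cell
count (round(p·J·I) cells without replacement — chosen over i.i.d. Bernoulli
so small instances hit the stated proportion exactly).  Items load traits in
contiguous blocks; any fixed assignment is statistically equivalent under
simple structure.  What the generator does not emulate about real data:
person misfit, item-level multidimensionality (cross-loadings), informative
missingness, and non-normal traits — recovery results here say nothing about
robustness to those.

Study-1 style runs simulate, fit (covariates included exactly when the
generating trait–covariate correlation is nonzero, or on request to measure
the Type-I error of the interval test at zero effect), apply the convergence
gate, discard-and-redraw nonconverged replications with seeds derived
deterministically from (base seed, condition index, replication, redraw
counter), and score Cor/bias/absolute error per parameter family, averaged
over dimensions and replications.  θ is additionally scored within
extreme-low (< −1.282), middle, and extreme-high (> 1.282) bands of the
generating values, the ±10% tails of a standard normal.  Trait-correlation
recovery is scored from posterior-mean ω off-diagonals and covariate effects
from posterior-mean β against the generating 0.25/0 values.  Study-2 style
runs fit a unidimensional and a 2-dimensional model to 2-trait data and
record which one WAIC/LOO select per replication.

## Problem sizes

Full-scale runs use 100 replications per condition.  The bundled test-suite
and acceptance computations use scaled-down designs chosen to keep a
laptop-class run practical: one replication per sample size for recovery
conditions (pooled across N ∈ {200, 500, 1000} and dimensions), 2–10
replications for selection-power conditions, and Monte-Carlo
tolerances of ±2 empirical standard errors computed from those replicates.
A single N = 1000, 2-trait, 10-items-per-trait, 4-option fit takes roughly
4–5 minutes on one CPU core.

## Known limitations

* Within-item multidimensionality (cross-loadings) is out of scope.
* Covariate missingness is unsupported.
* The nonconvergence rate of the sampler on the hardest design cells
  (5 binary items per trait, 20% missing data) is markedly higher than the
  design-wide average — on the order of one replication in five in those
  cells, versus a few percent across a representative mix of cells.  The
  harness's discard-and-redraw protocol absorbs this at the cost of extra
  replications.
* Marginal maximum likelihood estimation is deliberately not provided.
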