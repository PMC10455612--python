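# mggum

Bayesian estimation of the **multidimensional generalized graded unfolding
model (MGGUM)** with person covariates, for researchers measuring
noncognitive constructs (personality facets, vocational interests,
organizational attitudes) with ideal-point items.

Unlike dominance IRT models, an unfolding model places each item at a
location δ on the trait continuum and predicts *agreement* when a
respondent's trait level θ is close to δ, from either side:

    P(Z_ij = z | θ_j) ∝ exp{α_i [z(θ_jd − δ_i) − Σ_{k≤z} τ_ik]}
                       + exp{α_i [(M−z)(θ_jd − δ_i) − Σ_{k≤z} τ_ik]}

with discrimination α_i, subjective response category thresholds τ_ik
(τ_i0 ≡ 0), z ∈ {0..C} and M = 2C + 1.  The multidimensional extension
assumes between-item simple structure — each item measures exactly one of D
correlated traits — and models the traits as

    θ_j ~ MVN(β′X_j, ω),

so that trait correlations (ω) and covariate effects (β) are estimated
jointly with the item parameters, free of the attenuation that plagues
two-step scoring.  Estimation is by Markov chain Monte Carlo (Hamiltonian
dynamics with analytic gradients, plus conjugate and involutive Metropolis
updates; see `docs/methods.md`), with direction-informed location priors,
a Gelman–Rubin convergence gate (R̂ < 1.05), and WAIC / PSIS-LOO for model
comparison.

The package also ships the simulation machinery used to validate the
estimator: a generator for the standard recovery-study design, recovery
metrics (Cor / bias / absolute error, with extreme-vs-middle θ splits),
power / Type-I computation for covariate effects, and runners for
parameter-recovery and dimensionality-selection studies.

## Worked example

```python
import numpy as np
from mggum import (SimulationCondition, simulate_dataset,
                   build_model, fit, McmcConfig)
from mggum.harness import aligned_estimates

cond = SimulationCondition(
    n_persons=500, n_traits=2, items_per_trait=5, n_options=4,
    trait_cor=0.5, trait_covariate_cor=0.25,
)
sim = simulate_dataset(cond, np.random.default_rng(42))

model = build_model(sim.responses, sim.items, sim.scale, X=sim.persons.X)
posterior = fit(model, McmcConfig(seed=5))

print("converged:", posterior.converged, " max R-hat: %.3f" % posterior.max_rhat)
theta, alpha, delta, tau, omega, beta = aligned_estimates(sim, posterior)
print("Cor(true delta, est delta): %.3f"
      % np.corrcoef(sim.items.delta, delta)[0, 1])
print("trait correlation estimate: %.2f" % omega[0, 1])
print("covariate effects:\n", beta.round(2))
```

Output (about two minutes on one CPU core):

```
converged: True  max R-hat: 1.005
Cor(true delta, est delta): 0.993
trait correlation estimate: 0.48
covariate effects:
 [[0.3  0.27]
 [0.18 0.16]]
```

The ten generated locations are recovered almost perfectly (r = 0.993),
the between-trait correlation lands near the generating residual
correlation, and the four regression coefficients sit near the generating
value of 0.25 — the effects one would miss or attenuate by correlating
observed sum scores instead.

## Command line

```bash
mggum simulate --config cond.yaml --seed 1 --out data/
mggum fit --responses data/responses.csv --itemmap data/itemmap.csv \
          --covariates data/covariates.csv --options 4 \
          --chains 2 --iters 2000 --burnin 1000 --seed 2 --out fit2d/
mggum compare --fits fit1d/ --fits fit2d/ --out compare.csv
mggum study1 --grid grid.yaml --reps 100 --seed 3 --out recovery.csv
mggum study2 --grid grid.yaml --reps 100 --seed 4 --out power.csv
```

`fit` exits nonzero when the R̂ gate fails (pass `--allow-nonconverged` to
keep the draws anyway).  `study1`/`study2` accept either an explicit
condition list or crossed factor levels in the YAML grid.

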