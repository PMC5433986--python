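# lifetraj

Simulation and multimodel inference for binary life-history trajectories:
telling **state dependence** apart from **hidden permanent demographic
heterogeneity** (HPDH) in longitudinal breeding records.

## The problem

In many iteroparous species an individual's breeding record is a short binary
sequence — success/failure at each occasion until death. Two very different
mechanisms produce the observed mix of "streaky" and erratic trajectories:

* *state dependence*: this year's outcome causally shifts next year's odds
  (spirals of failure, costs of reproduction), a Markovian process that
  generates variation among identical individuals;
* *heterogeneity*: fixed, latent differences in individual quality that make
  some individuals persistently better than others.

Tests of the "neutral theory for life histories" fit a state-dependence-only
model and check whether it predicts the population distribution of lifetime
reproductive success (LRS). `lifetraj` implements the Monte Carlo machinery
to show why that protocol is fragile — a misspecified model can predict LRS,
entropy and within-individual variance as well as the truth, while its
parameter estimates are badly biased — and why multimodel selection with
BIC weights recovers the generating mechanism.

## The model

Individual `i` carries bivariate-normal random effects on the logit scale,

    (alpha_i1, alpha_i2) ~ N2(0, [[s_phi^2, r s_phi s_rep], [r s_phi s_rep, s_rep^2]])

Survival between occasions is `Bernoulli(expit(logit(phi) + alpha_i1))` with
mean survival `phi = 0.75`; every individual reaches a second occasion, and
trajectories are capped at 42 occasions. Breeding success at occasion `t` is

    success_it ~ Bernoulli(expit(mu + alpha_i2 + gamma * success_i,t-1))

with `mu = 0` (average success probability 0.5) and `gamma` the log odds
ratio of repeating a success versus recovering from a failure. Four candidate
models are fitted to each simulated breeding record: `Mnil` (intercept only),
`MNTLH` (+ lagged state), `MHPDH` (+ univariate random intercept) and `Mfull`
(both). The mixed models are estimated by maximum likelihood with 5-node
adaptive Gauss–Hermite quadrature. Per model and replicate the package
records estimates, log-likelihood, BIC/AIC weights, the Earth Mover Distance
between observed and predicted LRS histograms, the scaled transition entropy
`H / log 2` of the implied success/failure Markov chain, and the plug-in
within-individual variance of a failure-then-success step.

## Worked example

Simulate one panel where both mechanisms operate (odds ratio 2, both
heterogeneity SDs 1), fit all four candidates, and compare them:

```python
import math
import numpy as np
from lifetraj import (
    ScenarioParams, SimulationSettings, simulate_panel, build_design,
    BreedingTrajectoryModel, information_weights, MODEL_ORDER,
    transition_matrix, scaled_entropy, within_individual_variance,
)

params = ScenarioParams(gamma=math.log(2), sigma_phi=1.0, sigma_repro=1.0)
settings = SimulationSettings(n_individuals=1000, max_occasions=42)
panel = simulate_panel(params, settings, np.random.default_rng(42))
design = build_design(panel)

fits = [BreedingTrajectoryModel(design, name).fit() for name in MODEL_ORDER]
weights = information_weights(fits, "BIC")

print(f"panel: {panel.n_individuals} individuals, {panel.total_occasions} breeding occasions")
for fit, w in zip(fits, weights):
    print(f"{fit.spec.name:>6}: loglik {fit.loglik:9.2f}  BIC {fit.bic:9.2f}  "
          f"weight {w:6.4f}  mu {fit.mu_hat: .3f}  gamma {fit.gamma_hat: .3f}  "
          f"sigma {fit.sigma_repro_hat:.3f}")
```

which prints

```
panel: 1000 individuals, 6345 breeding occasions
  Mnil: loglik  -4344.75  BIC   8698.26  weight 0.0000  mu  0.260  gamma  0.000  sigma 0.000
 MNTLH: loglik  -4069.00  BIC   8155.51  weight 0.0000  mu -0.295  gamma  1.224  sigma 0.000
 MHPDH: loglik  -3944.14  BIC   7905.78  weight 0.0000  mu  0.277  gamma  0.000  sigma 1.285
 Mfull: loglik  -3903.24  BIC   7832.75  weight 1.0000  mu  0.011  gamma  0.627  sigma 1.025
```

The true generator (`Mfull`) takes essentially all the BIC weight and its
estimates sit near the truth (`gamma = 0.693`, `sigma_repro = 1`). The two
misspecified single-mechanism models illustrate the pathology: `MNTLH`
absorbs the heterogeneity into a spurious, near-doubled lag coefficient
(`gamma = 1.224`), and `MHPDH` inflates its frailty SD (`sigma = 1.285`).
Note the total occasion count exceeds the homogeneous expectation of ~5,000:
survival heterogeneity lengthens the average trajectory because long-lived
individuals dominate.

The same pipeline is scriptable from a shell:

```bash
lifetraj grid --count                      # 560 factorial scenarios
lifetraj run-study --scenarios corner --replicates 100 --seed 1 --out-dir out/
```

`run-study` writes `rows.csv` (one row per scenario x replicate x model) and
`tiles.csv` (scenario-level means, Monte Carlo SEs and capped relative
biases).

## Layout

* `lifetraj.scenarios` — scenario parameters and the 7x4x4x5 factorial grid
* `lifetraj.simulate` — panel simulator (effects, lifespans, breeding sequences)
* `lifetraj.model` — the four candidate models, AGHQ marginal likelihood,
  dense-grid oracle, information weights (statsmodels-style Model/Results)
* `lifetraj.metrics` — transition matrix, stationary distribution, scaled
  entropy, within-individual variance, LRS prediction, EMD, relative bias
* `lifetraj.study` — replicate/study drivers, aggregation, named subgrids
* `lifetraj.cli` — `lifetraj` console script

See `docs/methods.md` for modelling assumptions, numerical choices and known
limitations.
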