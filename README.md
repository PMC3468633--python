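# iporangaia

Inference stack for field studies of the costs of paternal care, built
around the Neotropical harvestman *Iporangaia pustulosa*, whose males guard
egg-batches on streamside vegetation while females and non-caring males
roam. The package asks the three questions such a study asks — does caring
cost survival, condition, or food? — with the statistical machinery each
question needs:

* **Mortality risk** — a multi-state Huggins closed robust-design
  capture-mark-recapture model. Marked animals move through hidden states
  (female, non-caring male, caring male, dead) across monthly primary
  occasions; within a month the population is closed and each sampling day
  is a Bernoulli(*p*) detection. The likelihood (conditional on first
  capture, so abundance is derived by Horvitz–Thompson rather than
  estimated) yields apparent survival Φ, recapture *p*, and state-transition
  ψ probabilities under 4 × 6 × 15 × 15 = 5,400 candidate structures,
  ranked by QAICc with a step-down procedure and an overdispersion factor ĉ
  from a goodness-of-fit ratio or a parametric bootstrap.
* **Energetic costs** — body condition as normal models with linear mean
  μ = β₀ + β₁·size (+ β₂·care) and power variance sd = α·(z+1)^θ, fitted by
  maximum likelihood and selected by AICc in two steps (size first, then
  care effects); body volume from the ellipsoid V = (π/6)·TBL·BW·BH, and
  the caring period of a male read off his oldest eggs' developmental stage
  via a cumulative schedule (6.6 d at stage 1 up to 32.0 d at stage 6).
* **Feeding activity** — monthly feeding proportions per category as
  binomial GLMMs with a month random intercept integrated by adaptive
  Gauss–Hermite quadrature, plus transect movement distances compared by an
  analysis of deviance.

A first-class synthetic-data generator produces encounter histories,
transect positions, morphometrics and feeding tables with exactly the
statistical structure these models assume — with ground truth attached — so
the whole pipeline runs and is tested without any field data.

## Worked example

```python
import numpy as np
from iporangaia import (SimulationConfig, simulate_population, default_layout,
                        ParameterStructure, fit_ml, chat_from_ratio)

layout = default_layout()          # 12 months, 46 sampling days
t = layout.n_primary

# a study where caring males survive better (0.90 vs 0.75 monthly)
cfg = SimulationConfig(
    seed=7,
    phi=np.vstack([np.full(t - 1, 0.75)] * 2 + [np.full(t - 1, 0.9)]),
    p=np.full((3, t), 0.4),
    psi=np.vstack([np.full(t - 1, 0.25), np.full(t - 1, 0.30)]),
    recruitment_males=(500,) + (0,) * 11,
    recruitment_females=(300,) + (0,) * 11,
)
pop = simulate_population(cfg)
print(len(pop["histories"]))       # 775 animals ever detected

fit = fit_ml(pop["histories"],
             ParameterStructure(phi="state", p="constant", psi="state"),
             layout, se=True)
est = fit.estimates()
print(round(est.phi[0, 0], 3), round(est.phi[2, 0], 3))   # 0.734 0.899
print(round(est.p[0, 0], 3))                              # 0.399
print(np.round(est.psi[:, 0], 3))                         # [0.242 0.302]
```

The fitted monthly survival of non-caring individuals (0.734) and caring
males (0.899), the daily detection probability (0.399) and the two
transition probabilities (N→C 0.242, C→N 0.302) all land on the generating
values within sampling error. A goodness-of-fit statistic converts to an
overdispersion factor the same way a worked example from field data does:

```python
chat, adequacy = chat_from_ratio(535.266, 485)
print(round(chat, 4), adequacy)    # 1.1036 adequate
```

The same analyses are available from the shell:

```sh
iporangaia simulate --seed 7 --out data/
iporangaia rank-cmr --inp data/encounters.inp --layout data/layout.yaml \
    --chat 1.1036 --out ranking/
iporangaia gof --chi2 535.266 --df 485
```

`rank-cmr` writes one CSV per step-down stage with columns
`structure,QAICc,K,delta_QAICc,weight`; `fit-condition`, `fit-feeding` and
`movement` produce the corresponding condition, feeding and movement
tables. See `docs/methods.md` for the models, conventions and numerical
choices in detail.

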