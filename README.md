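# arealrisk

Bayesian spatiotemporal risk mapping for areal count panels — built for
epidemiological surveillance teams who receive a line-list of notifiable
events (e.g. suicide attempts reported by municipality and date), census
populations, and an area-level covariate, and need to answer: *which areas
carry excess risk, how did risk evolve over time, and which count model fits
each age group best?*

## The model

For municipality *i* and quarter *t*, counts *y<sub>it</sub>* follow a
Poisson, zero-inflated Poisson (ZIP) or negative-binomial (NB) likelihood
with expected count λ<sub>it</sub> = ρ<sub>it</sub>·ε<sub>it</sub> and a
shared log-linear incidence rate

> ν<sub>it</sub> = log ρ<sub>it</sub> = α + γ<sub>i</sub> + δ<sub>t</sub> + β<sub>i</sub>·I<sub>it</sub>

where ε<sub>it</sub> is the age-group population offset, α the log baseline
rate, γ<sub>i</sub> ~ N(0, 1/τ<sub>γ</sub>) IID area effects,
δ<sub>t</sub> a random walk of order two (RW2) identified by sum-to-zero and
zero-linear-trend constraints, and β<sub>i</sub> ~ N(0, 1/τ<sub>β</sub>)
per-area slopes on the covariate I<sub>it</sub>. The NB family has variance
λ + λ²/φ; the ZIP family mixes a structural point mass at zero with weight
π. Posteriors are sampled by an adaptive Metropolis-within-Gibbs engine,
families are compared by DIC/WAIC (lowest DIC selected per age group), and
areas with posterior probability P(γ<sub>i</sub> > 0) above 0.8 are flagged
high-risk. See `docs/methods.md` for the full specification.

## Worked example

```python
import numpy as np
from arealrisk import (
    ModelSpec, ScenarioConfig, simulate_truth, simulate_panel,
    fit, exceedance_probabilities, fixed_effect_incidence,
)

cfg = ScenarioConfig(n_areas=60, n_quarters=12, dip=(10, 11, 0.3))
truth = simulate_truth(cfg, alpha=-9.0, seed=3, planted_gamma={0: 1.0, 1: 1.0})
panel = simulate_panel(truth, cfg)          # 60 municipalities x 12 quarters
draws = fit(panel, ModelSpec("poisson"), n_chains=2, n_iter=3000, seed=1)

print(fixed_effect_incidence(draws))
risk = exceedance_probabilities(draws, threshold=0.8)
print(risk.table.head(3))
print("high-risk municipalities:", risk.n_high_risk)
```

Output (abbreviated):

```
{'mean': 14.12, 'median': 14.15, 'q025': 12.3, 'q975': 16.19}
  area_id  exceedance_probability  high_risk state
0   01001                    1.00       True    01
1   01002                    1.00       True    01
2   01003                    0.05      False    01
high-risk municipalities: 21
```

The fixed-effect summary is exp(α)·10⁵ — the baseline incidence per 100,000
inhabitants per quarter (truth here: e⁻⁹·10⁵ ≈ 12.3, recovered as 14.1
because two area effects were deliberately planted at +1, pulling the
baseline up). The two planted areas get exceedance probability 1.0 and are
flagged.

The same pipeline runs from the shell (`arealrisk simulate | ingest | fit |
select | report`); `arealrisk ingest` consumes a line-list CSV
(notification date, 5-digit DIVIPOLA municipality code, age, sex), a census
population table and a quarterly covariate table, and writes one panel per
age group (5-9, 10-14, 15-19, 20-24, 25-59, >59) with reject and drop
reports so record counts are conserved end to end.

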