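# Methods

## The model

`arealrisk` analyses panels of event counts aggregated to administrative
areas (municipalities) and quarters, for one age group at a time. For area
*i* = 1..n and quarter *t* = 1..T the observed count *y<sub>it</sub>* is
modelled through an incidence rate *ρ<sub>it</sub>* and a known population
offset *ε<sub>it</sub>*:

    ν_it = log ρ_it = α + γ_i + δ_t + β_i · I_it
    λ_it = ρ_it · ε_it

with three interchangeable count likelihoods:

* **Poisson**: y<sub>it</sub> ~ Poisson(λ<sub>it</sub>);
* **zero-inflated Poisson (ZIP)**: a structural point mass at zero with
  weight π, otherwise Poisson — P(y=0) = π + (1−π)e<sup>−λ</sup>;
* **negative binomial (NB)**: mean λ, scale φ, variance λ + λ²/φ
  (success probability φ/(φ+λ), size φ); φ → ∞ recovers the Poisson.

The effects are: a global intercept α (the log baseline incidence rate);
exchangeable IID Gaussian area effects γ<sub>i</sub> ~ N(0, 1/τ<sub>γ</sub>)
(**no** neighbourhood structure — independence between areas is a modelling
assumption, not an omission); a random walk of order two for the temporal
effect, penalising squared second differences of δ with precision
τ<sub>δ</sub>; and exchangeable per-area covariate slopes β<sub>i</sub> ~
N(0, 1/τ<sub>β</sub>) multiplying an exposure covariate I<sub>it</sub>
(fixed-internet points per inhabitant in the motivating application).

### Identification

The RW2 prior is improper in level and slope: adding a + b·t to δ leaves
its density unchanged. Without constraints α and δ are confounded. We
identify δ by *two* linear constraints — zero sum and zero best-fit linear
trend — and let α absorb the level (the model deliberately has no global
slope term). The sampler enforces this exactly by parameterising δ = B z,
where B is an orthonormal basis of the (T−2)-dimensional orthogonal
complement of {1, t}. Every stored draw therefore satisfies the
constraints to machine precision; no post-hoc projection is needed.

γ is left unconstrained (its prior mean is zero), which means α and the
empirical mean of γ share a prior-resolved ridge: with n areas the
posterior of α carries an irreducible uncertainty of about
(n·τ<sub>γ</sub>)<sup>−1/2</sup> even under infinite data. Recovery
experiments must expect α errors of that order.

### Priors

The hyperpriors are weakly informative, mirroring common latent-Gaussian
software defaults: τ<sub>γ</sub>, τ<sub>δ</sub>, τ<sub>β</sub> ~
Gamma(shape 1, rate 5·10⁻⁵) (equivalently a log-gamma prior on the log
precision); α ~ N(0, 1000); logit π ~ N(−1, 1); log φ ~ N(0, 1). The RW2
quadratic form has rank T−2, which the τ<sub>δ</sub> update uses. All
likelihood masses keep their combinatorial constants so that DIC/WAIC are
comparable **across** families.

## Posterior computation

Inference is adaptive Metropolis-within-Gibbs (`arealrisk.inference`):

* τ<sub>γ</sub>, τ<sub>β</sub>, τ<sub>δ</sub>: exact Gamma Gibbs draws from
  their conjugate full conditionals.
* α, logit π, log φ: scalar adaptive random-walk Metropolis, target
  acceptance 0.44.
* γ and β: *vectorised single-site* Metropolis. Given everything else the
  likelihood factorises over areas, so all n proposals are evaluated in one
  matrix operation and accepted independently; per-coordinate scales adapt
  to 0.44. This mixes far better than one blocked n-dimensional proposal
  at identical cost.
* δ: blocked adaptive random walk in the z-coordinates of the constraint
  subspace, target acceptance 0.234.
* Two extra moves address known slow directions: a per-area **ridge move**
  shifting β<sub>i</sub> and compensating γ<sub>i</sub> through the
  area-mean covariate (the covariate often varies little within an area,
  leaving slope and area effect nearly confounded), and an **interweaving
  scale move** on (τ<sub>β</sub>, β) — propose τ<sub>β</sub> on the log
  scale and rescale β so the Gaussian prior terms cancel — which removes
  the funnel that appears when the slopes are prior-dominated. Both are
  standard remedies; without them R-hat for β/τ<sub>β</sub> can exceed 2
  on weakly-informative covariates, with them the worst R-hat in our
  experiments is ≈ 1.08.

Proposal scales adapt by Robbins–Monro (gain 2·k<sup>−0.6</sup>) during
burn-in only and are frozen afterwards, preserving ergodicity. Defaults:
burn-in = n_iter/2, thinning 5, two chains. Initialisation: α at the crude
log rate log(Σy/Σε) (pseudo-count 0.5 if no events), effects at zero,
precisions at 10, π at 0.1, φ at 1. One root seed spawns independent
per-chain streams (`numpy` `SeedSequence`), so runs are bit-reproducible
given (seed, n_chains, n_iter). Non-finite proposals are rejected rather
than clipped. Diagnostics (split-R̂, ESS) are computed through `arviz`;
constant chains yield flagged, not crashing, results.

## Model comparison

DIC uses the deviance D(θ) = −2 log p(y|θ) with the plug-in point at the
cell-wise posterior mean of the expected-count surface λ (π averaged on the
logit scale, φ on the log scale): DIC = 2·mean D − D(plug-in). WAIC is
pointwise: lppd<sub>cell</sub> = log mean over draws of the cell's
likelihood mass (log-sum-exp stabilised), p<sub>cell</sub> = variance over
draws of the cell's log mass (population variance, matching `arviz`, our
cross-checking oracle), WAIC = −2 Σ (lppd − p). Selection takes the lowest
DIC; exact ties go to the simpler family (poisson < negbin < zip) with a
logged note. Criteria computed on different panels refuse to compare.

## Reporting conventions

* **Exceedance**: the event is γ<sub>i</sub> > 0 (area relative risk above
  1), the standard disease-mapping convention; the paper-level threshold
  0.8 on its posterior probability flags "high risk". State rollups take
  the first two characters of the 5-digit municipality code.
* **Fixed-effect incidence**: posterior summaries of exp(α)·10⁵, the
  baseline incidence per 100,000 inhabitants per quarter.
* **Spatial surface**: because "incidence attributable to the spatial
  effect" is ambiguous, both honest candidates are emitted — mean
  exp(γ<sub>i</sub>) (relative risk) and mean exp(α+γ<sub>i</sub>)·10⁵.
* **Covariate significance**: a slope is called nonzero iff its equal-tailed
  (0.025, 0.975) posterior interval excludes zero.
* All posterior intervals are equal-tailed quantiles.

## The synthetic-data generator

`arealrisk.synthetic` draws panels exactly from the model: γ and β IID
Gaussian, δ built by the RW2 recursion from Gaussian second differences and
then projected onto the identified subspace (second differences are
unaffected by removing a line, so the generator's stated innovation variance
is testable directly), counts from any of the three families. A ZIP draw
zeroes each cell with probability π *after* the Poisson draw, so π = 0
reproduces the Poisson branch draw-for-draw under the same seed. An
optional "dip" subtracts a smooth raised-sine bump from δ over a configured
quarter window, emulating a mid-window drop in case notification (as seen
in 2020 surveillance data); the result is re-projected so the truth stays
identified. Planted area effects (e.g. γ<sub>i</sub> = +1) support
risk-flagging calibration experiments.

Default scenario values are chosen to emulate quarterly municipal
surveillance panels: per-area age-group populations uniform in
5,000–50,000, baseline log rate α = −9 (≈ 12.3 events per 100,000 per
quarter), τ<sub>γ</sub> = 4, τ<sub>δ</sub> = 25, τ<sub>β</sub> = 4, a
covariate near 0.05 points per inhabitant growing by 0.01 per quarter.
These sizes produce zero-heavy small counts (λ ≈ 0.6–6 per cell).

What the generator does **not** emulate: spatial autocorrelation between
neighbouring municipalities, reporting delays and duplicate notifications,
intercensal population drift, and covariate measurement error. Passing
recovery tests therefore demonstrate correctness of the inference machinery
under the model's own assumptions, not robustness to their violation.

## Experiment sizes

Test-suite experiments are sized for a single CPU: recovery uses 20
replicates of n = 60 areas × T = 12 quarters with 2 chains × 3,000
iterations; flag-calibration runs a matching 20 replicates with three
planted γ = +1 areas (planting is kept out of the plain recovery set
because the planted mass shifts the unidentifiable γ-mean and would bias
the α-coverage measurement); model-selection power uses 20 replicates of
n = 40 × T = 8 per generating family; the dip-recovery check uses larger
exposures (populations 50,000–200,000, smooth trend τ<sub>δ</sub> = 400)
because a notification dip is only detectable when quarterly totals are
informative — the regime real national surveillance data occupy. The
acceptance script runs one 150-area pipeline end to end.

## Known limitations

* No CAR/BYM spatially structured prior and no space–time interaction — by
  design, matching the independence assumption of the analysis this package
  operationalises.
* The ZIP zero-probability is structural and shared across cells; no
  covariates on the zero process.
* MCMC at desk scale: a full 1,121-municipality panel fits in minutes, but
  the package makes no claim of numerical equality with nested-Laplace
  (INLA-style) approximations of the same posterior.
* Population offsets are constant over quarters (census snapshot); no
  intercensal interpolation.
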