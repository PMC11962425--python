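# agesirs — pathogen evolution in an age-structured SIRS host population

`agesirs` is a toolkit for studying where the phenotype of an endemic
pathogen is headed when its host population is split into age stages with
different demographic rates. It is aimed at theoretical epidemiologists and
evolutionary biologists who want a small, fully testable implementation of
the eco-evolutionary pipeline: an age-structured SIRS model, next-generation
reproduction numbers, an evolutionarily stable strategy (ESS) solver under
an infectivity–recovery trade-off, and a variant-replacement simulator.

## The model

The host population is divided into *n* age stages. Stage *i* holds
susceptible *Sᵢ*, infected *Iᵢ* and recovered *Rᵢ* densities; individuals
age at rates *aᵢ*, die of background causes at rates *δᵢ*, recover at rates
*γᵢ*, die of disease at rates *dᵢ*, and lose immunity at the age-invariant
rate *ω*. All births enter stage 1 susceptible and balance all deaths, so
the total population is constant (normalised to 1). Transmission from an
infected of stage *j* to a susceptible of stage *i* happens at rate
*βᵢⱼ = cᵢⱼ·β(γⱼ)*, where *cᵢⱼ* is a contact structure (by default an outer
product *xᵢyⱼ*, making the transmission matrix rank 1) and *β(γ)* is a
concave, increasing trade-off: acuter infections shed more per unit time but
last shorter.

Three quantities organise the analysis:

- **R₀** — the spectral radius of the next-generation matrix −TΣ⁻¹ at the
  disease-free equilibrium, with *Tᵢⱼ = βᵢⱼŜᵢ* and Σ the lower-bidiagonal
  transition matrix with diagonal −μᵢ, μᵢ = aᵢ+δᵢ+γᵢ+dᵢ. For rank-1
  transmission R₀ equals the trace of −TΣ⁻¹, which the package evaluates in
  closed form alongside the dense eigenvalue route.
- **Q₀** — the invasion number of a rare mutant: the same construction with
  the mutant's traits and the resident's endemic susceptible profile *S\**.
  A mutant invades iff Q₀ > 1; a resident is an ESS when Q₀ ≤ 1 for every
  mutant.
- **γᵢ\*** — the ESS recovery rates. Under slow aging (γ+d ≫ a) the
  stationarity of Q₀ decouples by stage into
  *β′(γᵢ)(aᵢ+γᵢ+dᵢ+δᵢ) = β(γᵢ)* — geometrically, a line through
  −(aᵢ+dᵢ+δᵢ) tangent to the trade-off curve. Contact rates cancel from
  this condition; for the power law *β = cγᵖ* (0 < p < 1) the solution is
  *γᵢ\* = p·mᵢ/(1−p)* with *mᵢ = aᵢ+dᵢ+δᵢ*. Stages with higher mortality
  therefore evolve shorter, more infectious infections.

The evolution module chains random mutant proposals (multiplicative
log-normal steps on γ) and settles each one either by integrating the full
two-strain ODE competition or by the adaptive-dynamics rule (fix iff
Q₀ > 1), tracking γ and R₀ across fixation events. Two sensitivity modes
deliberately break the model's simplifying assumptions: a random (full-rank)
contact matrix, and disease mortality far above background.

## Worked example

The built-in `single_stage` scenario is a scalar SIRS benchmark
(β(0.1) = 0.4, γ = 0.1, δ = 0.01, ω = 0.02, power-law trade-off p = 0.5):

```
$ agesirs r0 --template single_stage
R0 = 3.636363636  (method: trace)
```

which is β/(γ+δ) = 0.4/0.11: each infection causes ~3.6 secondary cases in
a fully susceptible population, so the endemic susceptible fraction settles
at S* = 1/R₀ = 0.275. The three-stage human-like scenario (young/adult/old,
per-day rates, mortality rising with age) gives the per-stage ESS:

```
$ agesirs ess --template three_stage_human --verify
 stage  gamma_star  beta_star      residual
     1    0.005147   0.143485  2.556289e-14
     2    0.010111   0.201106 -2.775558e-17
     3    0.020183   0.284131  5.551115e-17
R0 at ESS = 14.81517096
invasion verification: max Q0 = 0.99999899 (tolerance 1.82e-03) -> PASS
```

Recovery at the ESS is four times faster in the old stage than in the young
stage — the disease evolves to be acute where mortality is high and chronic
where it is low — and no probed mutant achieves Q₀ > 1. Running evolution
from a resident far above the ESS walks it back:

```
$ agesirs evolve --template single_stage --attempts 100 --seed 0
fixations: 36 / 100 attempts
final gamma: 0.00998244
final R0: 6.32455
relative distance to ESS prediction: 0.00176
```

The resident's γ falls from 0.1 to ≈ 0.01 = γ* = p·(δ)/(1−p), and R₀ rises
monotonically across fixations to its maximum on the trade-off curve.

## Layout

- `src/agesirs/params.py` — demography, strain traits, trade-off, contacts
- `src/agesirs/model.py` — ODE right-hand sides, integration, equilibria
- `src/agesirs/ngm.py` — disease-free equilibrium, T, Σ, Σ⁻¹, R₀, Q₀, ∇Q₀
- `src/agesirs/ess.py` — ESS residual/solver, tangency, invasion probes
- `src/agesirs/evolution.py` — mutation kernel, competition, evolution runs
- `src/agesirs/scenarios.py` — templates, YAML load/save/validate
- `src/agesirs/cli.py` — `agesirs r0|invade|ess|simulate|evolve|sensitivity|check`

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
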