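# Methods

## Model structure and assumptions

The population is partitioned into `n` age stages of susceptible, infected
and recovered individuals. Aging moves stage `i` into `i+1` at rate `a_i`;
the terminal stage has `a_n = 0` and is left only through death (this is
enforced at construction — any other convention breaks the constant-
population accounting below). Background mortality `delta_i`, disease
mortality `d_i` and recovery `gamma_i` are per-stage; immunity wanes at a
single rate `omega`. Every death (background or disease, any compartment)
is balanced by a birth into stage-1 susceptibles, so the total population is
exactly conserved and normalised to 1; all compartment values are densities.
There is no vertical transmission of infection or immunity.

The two-strain extension adds mutant pools `I~, R~` under total
cross-immunity: both strains deplete the same susceptible pool, both
recovered pools return to it at rate `omega`, and both share `a`, `delta`,
`d`, `omega`. Strains differ only in recovery (and, through the trade-off,
infectivity). Partial cross-immunity, demographic stochasticity and data
fitting are out of scope.

Transmission is `beta_ij = c_ij * beta(gamma_j)`: infectivity depends on
the *infected* stage `j` (shedding is a property of the infected host), and
the contact structure `c_ij` is either an outer product `x_i y_j` (rank 1,
unlocking the trace formula for reproduction numbers) or an arbitrary
nonnegative matrix. The trade-off `beta(gamma)` must be positive and
increasing; concavity is what guarantees an interior ESS, and the built-in
power law `beta = c * gamma**p` is concave exactly for `0 < p < 1`
(`p >= 1` is rejected at ESS-solve time as the unbounded "Darwinian demon"
optimum). A numerical concavity check on a log grid warns — rather than
fails — for custom trade-offs, since the rest of the machinery remains
meaningful.

Rates are per day by default; nothing in the code depends on the unit, only
on ratios. The slow-aging regime that decouples the ESS condition means
`gamma_i + d_i >= 50 * a_i` (recovery in weeks, aging in years).

## Reproduction and invasion numbers

The linearised infected subsystem at a susceptible profile `S` is
`dI/dt = (T + Sigma) I` with `T_ij = beta_ij S_i` and lower-bidiagonal
`Sigma` (diagonal `-mu_i`, `mu_i = a_i + delta_i + gamma_i + d_i`,
subdiagonal `a_i`). `Sigma` is inverted in closed form:
`(-Sigma^{-1})_{ji} = (a_i .. a_{j-1}) / (mu_i .. mu_j)` for `j >= i`, the
expected infected time spent in stage `j` after entering in stage `i`.
R0 is the spectral radius of `K = -T Sigma^{-1}` at the disease-free
equilibrium, whose age profile follows the recursion
`S_hat_i = alpha_i S_hat_1`, `alpha_i = prod_{k=2..i} a_{k-1}/(a_k+delta_k)`.
Q0 is the identical construction with the mutant's `gamma` in both the
trade-off and `mu`, and the resident's *endemic* susceptible profile.

Two routes to the spectral radius are kept deliberately separate: the
closed nested-sum trace formula (valid only for rank-1 transmission, where
the trace equals the dominant eigenvalue because `K` has a single nonzero
eigenvalue) and a dense eigenvalue computation on `K` (`n` is small; no
iterative methods). Requesting the trace route for a general contact matrix
is refused with an explanatory error rather than silently returning a wrong
number. The two routes cross-check each other in the test suite on
randomised instances.

`q0_gradient` differentiates Q0 in the mutant recovery rates by central
differences with relative step `1e-5 * gamma_l`. Q0 is smooth in
`gamma~`, so the difference error is dominated by round-off
(~`eps / h` ≈ 1e-9 at `gamma ~ 1e-2`), comfortably inside the 1e-6
stationarity tolerance used in the tests; an analytic derivative would be
an optimisation, not a correctness requirement.

## Equilibria

`endemic_equilibrium` first checks R0; subcritical inputs return the
disease-free state with a flag rather than an error. Otherwise it
integrates from a seeded disease-free state (or a supplied warm start, e.g.
the previous equilibrium after a small trait change) in geometrically
growing chunks (500 → 2e5 time units, horizon cap 1e6) with LSODA at
rtol 1e-9 / atol 1e-12, monitoring the RHS max-norm. Once the residual is
small (< 1e-5) the point is refined by a safeguarded Newton iteration in
which the last equation is replaced by the conservation constraint
`sum(y) = total` — the raw Jacobian is singular because the RHS conserves
the total identically. The polish typically lands at residuals ~1e-14,
well below the 1e-10 convergence target; pure integration can stall near
the integrator's own error floor, which is why the refinement step exists.
A polished point with a vanishing infected pool is rejected (the
disease-free state is unstable when R0 > 1) and integration continues.

The closed-form aggregate equilibrium
`S* = 1/R0`, `I* = delta_bar (1 - 1/R0) / (gamma_bar + delta_bar - omega
gamma_bar/(omega + delta_bar))`, `R* = gamma_bar I* / (omega + delta_bar)`
uses rates averaged over the disease-free age profile (the natural weights
"by age structure"; the choice only matters for `n > 1`, where the formula
is an approximation anyway). It is exact for `n = 1` with `d = 0` and is
cross-checked against long-run integration at 1e-6 in the tests.

## ESS solver

Stages decouple under slow aging, so each `gamma_i*` is a root of
`beta'(gamma)(a_i + gamma + d_i + delta_i) - beta(gamma)`, found by Brent's
method after a 200-point log-grid scan of `[1e-6, 1e3]` that must find
exactly one sign change — multiple sign changes abort with an error, since
the concavity-based uniqueness argument then fails. Within-stage contact
scalars multiply both terms of the residual and cancel; the tests verify
that rescaling all contacts by 1e3 moves `beta*` but not `gamma*`. The
full cross-stage coupling is only *assessed* (via the Q0 gradient and
invasion probes), never solved for: the per-stage condition is the model's
prediction, and the measured gradient at `gamma*` quantifies the slow-aging
error (observed ≈ 1% of the `gamma*/2` gradient magnitude for the
three-stage scenario, against the 5% bound asserted in the tests).

`verify_ess_by_invasion` probes each stage with multiplicative factors
{0.25, 0.5, 0.8, 0.9, 1.1, 1.25, 2, 4} plus 50 joint log-normal
perturbations (fixed seed). The pass tolerance on `Q0 <= 1 + tol` is 1e-6
for `n = 1` (where stationarity is exact) and scales as
`10 * max(a_i/(gamma_i* + d_i))**2` otherwise: the neglected cross-stage
terms enter at second order in the aging-to-removal ratio.

## Evolution simulation

The variant-replacement algorithm is the package's own design (the chain
of proposal/competition/replacement is standard adaptive dynamics):

- **Kernel** — `gamma~ = gamma * exp(sigma z)`, `z ~ N(0, 1)` i.i.d. per
  stage, `sigma = 0.1` by default; multiplicative steps keep `gamma`
  positive and scale-free. A per-stage mode perturbs one random stage.
- **Competition (`ode_competition`)** — the resident sits at its endemic
  equilibrium; 1e-6 of the total population is moved from its infected
  pools (proportionally across stages) to the mutant, small enough that the
  linearised mutant dynamics govern early growth. Fixation: mutant share of
  infections > 0.99. Extinction: pooled mutant infections < 1e-9 of the
  population. Timeout: 5e4 time units, resident retained. Outcomes are
  insensitive to these thresholds within an order of magnitude because
  competitive exclusion under total cross-immunity is monotone.
- **Adaptive-dynamics mode** — fix iff Q0 > 1. This is the default in the
  tests; its agreement with the ODE route away from neutrality
  (`|Q0 - 1| > 1e-3`) is itself a test.
- One seeded generator per run; identical seed and configuration reproduce
  the trajectory bit for bit.

After each fixation the new resident's equilibrium is recomputed, warm-
started from the previous one. At `n = 1` with the `p = 0.5` power law the
invasion fitness `beta(gamma) S*/(gamma + d + delta)` is exactly symmetric
in `log gamma` about `gamma*`, so every fixation strictly decreases
`|log(gamma/gamma*)|` and strictly increases R0 — the simulation tests
assert both. With a general (random) contact matrix, Q0 at the endemic age
profile can exceed 1 while R0 at the disease-free profile drops slightly;
R0 then only *tends* to rise, and the corresponding test asserts the
tendency (net increase, >= 90% of fixations nondecreasing, shrinking mean
distance to the per-stage ESS) rather than strict monotonicity. Weakly
coupled stages (a near-zero contact column) experience almost no selection
and converge very slowly — evolution slows down near the ESS generally,
which a dedicated test (declining fixation rate) also checks.

## Sensitivity modes

- **Random contacts** — every outer-product contact element is multiplied
  by an independent Uniform(0, 1) draw (seeded), producing a generically
  full-rank transmission structure; trace-based shortcuts are refused
  downstream.
- **High CFR** — disease mortality is set to `10 * delta_i * multiplier`,
  leaving the low-CFR regime; the aggregate closed form becomes unreliable
  and equilibria must come from integration. The ESS shifts to larger
  `gamma*` because `d` enters `m = a + d + delta`.

## Scenario templates and what they do (not) emulate

Templates are the package's study conditions, with per-day rates:

- `single_stage` — scalar SIRS: `beta(0.1) = 0.4`, `gamma = 0.1`,
  `delta = 0.01`, `omega = 0.02`, `d = 0`, power law `p = 0.5`
  (`c = 0.4/sqrt(0.1)`); R0 = 40/11. Chosen so every closed form
  (S* = 1/R0, the aggregate I*, R*, `gamma* = 0.01`) is exact.
- `three_stage_human` — young (0–20 y), adult (20–65 y), old stages;
  aging 1/7300 and 1/16425 per day; background mortality 1e-5, 5e-5,
  1/5475; immunity loss 1/365; recovery 0.2, 0.15, 0.1; disease mortality
  5e-3, 1e-2, 2e-2 rising steeply with age. The disease-mortality scale is
  deliberately large enough that `gamma + d >= 50 a` holds along the whole
  evolutionary range *including at the ESS* (with negligible `d` the ESS
  recovery rates fall to the order of the aging rates and the slow-aging
  decoupling would not describe the template's own endpoint). Contact
  vectors (1.5, 1.0, 0.7) x (1.2, 1.0, 0.8), trade-off `2 sqrt(gamma)`;
  R0 ≈ 5.7.
- `slow_aging_n` — an `n`-stage ladder with 15-year stages and geometric
  background mortality, `d = 0`, used for dimension sweeps.
- `high_cfr`, `random_contacts` — the sensitivity variants of the
  three-stage template.

These scenarios are theory probes, not calibrated populations: they do not
emulate realistic human contact surveys, seasonality, maternal immunity, or
age-varying immunity loss, and passing tests on them demonstrates the
internal consistency of the framework (formulas vs. dynamics vs.
simulation), not predictive accuracy for any real pathogen.

## Numerical choices

- Integration: LSODA (stiffness-switching), rtol 1e-9 / atol 1e-12 for
  equilibria and trajectory work; competition runs use rtol 1e-8 for speed,
  which is ample for threshold crossings at 0.99/1e-9.
- Equilibrium detection: RHS max-norm < 1e-10 (reached via the Newton
  polish described above) or horizon 1e6.
- Eigenvalues: dense `numpy.linalg.eigvals`, largest real part (K is
  nonnegative, so the spectral radius is attained by a real eigenvalue).
- Root finding: Brent with xtol 1e-14 on a bracketing interval from a
  log-grid scan; degenerate `n = 1` collapses all stage products to single
  factors and is covered by the same code paths.
- Problem sizes: the test suite and the acceptance script run at
  `n <= 8`, 100 randomised trace-identity instances, 300-attempt evolution
  chains; each component completes in seconds on one core, and the sizes
  are large enough that every asserted tolerance is met with orders of
  magnitude to spare.

## Known limitations

- Total cross-immunity between strains is structural; relaxing it would
  change the invasion analysis qualitatively.
- The aggregate closed-form equilibrium is exact only at `n = 1`, `d = 0`.
- The per-stage ESS is an approximation whose error grows with
  `a/(gamma + d)`; outside the slow-aging regime the reported `gamma*` is
  the decoupled prediction, not the true joint optimum (the gradient and
  probe diagnostics quantify the gap).
- ODE competition cannot represent drift: a neutral mutant times out at
  its seeding share instead of fixing or dying.
- Only two concurrent strains are modelled; standing diversity and
  branching are out of scope.
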