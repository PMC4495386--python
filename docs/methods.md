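# Methods

## Model and assumptions

The package models emigration of a cavity-dwelling ant colony choosing
between two candidate nests as a compartment system over the active scouts
(uncommitted pool `X`, assessors `Z_i`, potential transporters `Y_i`) and the
passive ants plus brood (`P` at the original nest, `B_i` carried into nest
`i`). The flux structure is:

* discovery: `X → Z_i` at per-capita rate `mu` for each nest independently
  (total outflow `2*mu*X`);
* acceptance: `Z_i → Y_i` at rate `k_i`;
* abandonment: `Z_i → X` and `Y_i → X` at rate `rho_i` — allegiance switches
  only *indirectly* through the pool, and potential transporters keep
  abandoning at the same rate after quorum;
* carrying: `P → B_i` at aggregate rate `phi_i * Y_i * H(Y_i − T)` while the
  passive pool lasts.

Assumptions worth making explicit: no tandem running (scouts find nests
independently, which matches the short nest distances the design emulates);
no spatial structure or travel times; no quorum-assessment delay (the ~2-min
encounter-rate estimation real ants perform is collapsed into an
instantaneous threshold test); carried ants never contribute to the
potential-transporter count `Y_i`, though they do count toward the visible
nest population `Z_i + Y_i + B_i`; quality switching only modulates
`(k_2, rho_2)` between two phase values.

Both the active total `X + Z1 + Z2 + Y1 + Y2` and the passive total
`P + B1 + B2` are conserved exactly by construction; the test suite checks
this both symbolically (flux bookkeeping) and along every integrated
trajectory (tolerance 1e-6 over 180 min).

## Parameters

| parameter | meaning | default | units | rationale |
|---|---|---|---|---|
| `mu` | per-nest discovery rate | 0.03 | /min | study value |
| `k1, rho1` | constant mediocre nest | 0.020, 0.008 | /min | study values |
| `k2, rho2` good | fluctuating nest, good phase | 0.024, 0.004 | /min | study values |
| `k2, rho2` poor | fluctuating nest, poor phase | 0.016, 0.012 | /min | study values |
| `phi` | per-transporter carrying rate | 0.099 | /min | study value |
| `T` | quorum threshold on `Y_i` | 7 | ants | study value |
| period / good fraction | quality cycle | 10 min; 0.25/0.50/0.75 | — | treatment definitions, good phase first |
| horizon | observation window | 180 | min | experimental censoring time |
| `X(0)` | initial uncommitted scouts | 16 | ants | calibrated, see below |
| `P(0)` | initial passive pool | 80 | ants | inert before quorum |
| `active_fraction` | scouting minority of workers | 0.25 | — | "small minority" of the 24–92 workers; a config field |

**Initial-scout calibration.** `X(0)` is not dictated by the rate set; it
scales the whole (pre-quorum, linear) solution. It was calibrated once
against two qualitative anchors — no treatment may attain the quorum within
180 min under the default rates, while nest populations should still climb
somewhat above the threshold count — and frozen at 16. Larger values (e.g.
20) push the 75%-good treatment over the quorum within the horizon and were
rejected. With `X(0) = 16` the final fluctuating-nest populations are
6.32 / 6.99 / 7.81 ants for 25/50/75% good, and the maximum
potential-transporter count stays below 7 in all three treatments.

Derived desk quantities follow from the race between acceptance and
abandonment: a discoverer eventually assesses the nest positively with
probability `p = k/(k+rho)` (57%, 71%, 86% for poor/mediocre/good), and the
characteristic times are `1/k` (62.5, 50, ~42 min) and `1/rho`
(~83, 125, 250 min).

## Deterministic integration

Quality switches make the right-hand side piecewise-smooth, and the quorum
Heaviside and pool indicator make it discontinuous in the state. The
integrator therefore (i) segments time at every switch point of either
schedule and restarts the solver from the previous end state, and (ii) within
a segment, runs `scipy.integrate.solve_ivp` (DOP853, rtol 1e-10, atol 1e-12)
with terminal events on `Y_i − T` (direction chosen by the current regime)
and on `P` reaching zero, flipping the corresponding regime flag and
restarting at the located root. Event roots are found by scipy's Brent
bracketing to well below 1e-6 min. Between restarts the system is linear, so
the high-order adaptive scheme is effectively exact; the suite verifies the
end state against an independent fixed-step RK4 oracle at step 0.001 min to
1e-6 per component. Output is sampled on a 1-min grid; restart points are
exact, never grid-snapped. Boundary conventions: phases are half-open
(right-continuous switching, good phase on `[0, g*period)`), and
`H(0) = 0` — carrying starts only when `Y_i` strictly exceeds `T`.

## Averaged nest and the homogenization check

Because the pre-quorum dynamics are linear in the quality rates, the
fast-fluctuation (homogenization) limit replaces `k_2(t)` and `rho_2(t)` by
their cycle means: the good-phase value weighted by the good fraction plus
the poor-phase value weighted by its complement. For the 25%-good treatment
this gives `k̄ = 0.018` and `ρ̄ = 0.010` per minute. The overlap between the
fluctuating nest's population time course and its averaged counterpart is
quantified by the sup-norm on the shared 1-min grid, with frozen tolerances
of 0.5 ants for the standard treatments and 1.5 ants for the robustness
variants (magnified amplitude: good (0.038, 0.001) / poor (0.002, 0.015);
period slowed to 30 min). Measured values at the 10-min period are
0.048–0.071 ants for the standard treatments, 0.08–0.21 ants for five of the
six robustness variants, and the gap shrinks monotonically through periods
10 → 5 → 2.5 → 1.25 min.

**Known limitation.** The magnified-amplitude 75%-good variant attains the
quorum inside the horizon (fluctuating nest at t ≈ 136, averaged nest at
t ≈ 146). The ~10-min offset in carrying onset produces a transient
population gap of 2.6 ants, exceeding the documented 1.5-ant tolerance:
time-averaging holds cleanly only up to the quorum discontinuity, and across
it the agreement is qualitative (both pairings cross the quorum and emigrate
the same way), not uniform in time. The acceptance suite keeps this check at
the documented tolerance and it fails there, deliberately.

## Stochastic emulator

The emulator is the continuous-time Markov chain whose transition rates are
the model's fluxes evaluated at integer counts; one passive item is carried
per transport event, which matches the mean-field flux `phi*Y` in
expectation. Rates are constant between quality switches, so Gillespie
simulation with clocks redrawn at each switch is exact (memorylessness).
Colonies draw `n_workers ~ U{24..92}`, scouts as
`round(active_fraction * n_workers)`, and a brood count `~ Poisson(n_workers)`
joins the passive pool. A replicate records per-nest occupancy
(`Z_i + Y_i + B_i`) every 10 min, ends at the first carrying event — defining
the chosen nest, the time to quorum, and the "observed" quorum threshold as
the chosen nest's occupancy at that moment — or is censored at 180 min, with
later counts missing. For mean-field comparisons the chain can instead run
past the first carrying event (`stop_at_choice=False`), since the ODE does
not stop there either.

Mean-field agreement is a *large-colony* statement: the chain's mean equals
the ODE exactly only while quorum crossings are negligible, because the
Heaviside makes the dynamics nonlinear. The acceptance check therefore runs a
tenfold colony (160 scouts, 800 passives, `T = 70`) for 1,000 replicates and
compares the mean nest-2 population at t = 120 with the ODE within 3
Monte-Carlo standard errors. At the experimental scale (≈16 scouts, `T = 7`)
a minority of runs crosses the quorum stochastically and biases the mean
upward relative to the sub-quorum ODE — a real feature of the model, not an
emulator defect.

What the generator emulates and what it does not: it reproduces the design
(colony-size range, two-of-three balanced treatments in randomized order,
10-min counts, censoring), the qualitative treatment ordering of choice
proportions (increasing in the good fraction, stable from ≈300 records per
treatment), and quorum thresholds that grow with colony size (because larger
colonies field more scouts, the chosen nest holds more ants when carrying
starts). It does not reproduce the real experiment's choice frequency
(roughly a third of synthetic replicates reach a quorum versus ~three
quarters in the real data — the fixed `T = 7` on potential transporters is
demanding for colonies whose scout contingent is barely above it), nor
between-colony behavioural heterogeneity beyond size (real counts are
overdispersed relative to this chain; no extra overdispersion mechanism is
claimed), nor the 2-min quorum-assessment delay, tandem runs, or arena
geometry. Passing tests therefore certify internal consistency with the
model and design, not distributional fidelity to unreleased field data.

## Statistical summaries

* **Choice table**: counts of FN/CN/none per treatment; censored replicates
  are tabulated but excluded from the proportion. Intervals are 95% Wilson
  score — strata can be as small as a handful of choices, where Wald
  intervals degenerate.
* **Pooled binomial**: the exact upper-tail probability of at least
  `max(n_FN, n_CN)` successes in `n_FN + n_CN` fair-coin trials by direct
  summation of binomial mass. The one-sided tail is the primary form (for
  24 vs 20 it gives 0.326; doubling for a two-sided test gives 0.652) and a
  two-sided option is provided.
* **Accumulation slopes**: Poisson log-linear regression of the 10-min
  counts on time, pooled across the replicates of a treatment that made a
  choice, fitted by IRLS (statsmodels GLM). This is deliberately a
  single-level fit: colony-level random effects belong to mixed-model
  analyses of the real (unreleased) data and are out of scope here, where the
  slope's role is parameter recovery on synthetic data and qualitative
  comparison. A slope is reported only when at least three time points carry
  nonzero counts.

## Problem sizes and seeds

Stochastic checks use sizes chosen to make their conclusions stable: 1,000
replicates for the mean-field comparison, 450 colonies (300 records per
treatment) for the choice-ordering check, 2,000 replicates for the
first-discovery waiting-time law (KS test at alpha = 0.01), and five
replications of the 44-series slope-recovery experiment so that the recovered
mean is compared against the single-experiment 2-SE band with the check's own
Monte-Carlo error controlled. All random draws flow from explicitly seeded
`numpy` generators; dataset generation is byte-reproducible given a seed.
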