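# nestquorum

Collective nest-site choice under fluctuating quality: a compartment model of
quorum-based emigration in cavity-dwelling ants (*Temnothorax*-style
house-hunting), its stochastic colony-level counterpart, and the analysis
pipeline for the resulting emigration datasets.

## The scientific problem

A colony must choose between two candidate nest sites when one of them
fluctuates in quality — good for a fraction *g* of every cycle, poor for the
rest — while the other is constantly mediocre. Individual scouts never
compare sites directly; they simply stay longer in better nests. The claim
under study is that quorum sensing turns this simple per-ant behaviour into a
*running average* of a fluctuating resource's quality: the colony behaves as
if the fluctuating nest were a constant nest with the time-averaged
parameters (the homogenization limit of the fast-switching system).

## The model

Active scouts move between compartments: the uncommitted pool *X*, assessors
*Z_i* of nest *i*, and potential transporters *Y_i* (scouts that accepted
nest *i*). Passive ants and brood wait in *P* until carried into nest *i*
(*B_i*). With per-nest discovery rate μ, acceptance rate *k_i*, abandonment
rate ρ_i, carrying rate φ_i and quorum threshold *T*:

    dX/dt  = −2μX + ρ₁(Z₁+Y₁) + ρ₂(Z₂+Y₂)
    dZᵢ/dt = μX − (kᵢ+ρᵢ)Zᵢ
    dYᵢ/dt = kᵢZᵢ − ρᵢYᵢ
    dBᵢ/dt = φᵢ Yᵢ H(Yᵢ−T) [P>0]      dP/dt = −Σᵢ φᵢ Yᵢ H(Yᵢ−T) [P>0]

H is the Heaviside step (carrying starts when the potential transporters at a
nest strictly exceed *T*). Switching between nests is indirect — an ant
abandons back to the pool before it can discover the other nest — and there
is no tandem-run recruitment. For the fluctuating nest, (*k₂*, ρ₂) alternate
between good-phase (0.024, 0.004) and poor-phase (0.016, 0.012) values each
10-min cycle, good first; the constant nest keeps (0.020, 0.008). Defaults:
μ = 0.03/min, φ = 0.099/min, *T* = 7.

Three layers build on this core:

* **Deterministic runs** (`nestquorum.dynamics`) — windowed integration that
  restarts at every quality switch and locates quorum crossings by event
  detection, plus the *averaged nest*: a constant nest whose rates are the
  time-weighted means of the fluctuating phases (e.g. for 25% good,
  k̄ = 0.25·0.024 + 0.75·0.016 = 0.018, ρ̄ = 0.25·0.004 + 0.75·0.012 = 0.010).
* **Stochastic emulator** (`nestquorum.colonies`) — the exact integer-count
  Markov-chain counterpart, used to generate experiment-like datasets:
  30 colonies of 24–92 workers, two of three treatments each, counts every
  10 min, replicates ending at the first carrying event or censored at 180 min.
* **Summaries** (`nestquorum.summaries`) — per-treatment choice proportions
  with Wilson intervals, the pooled exact binomial comparison, Poisson
  log-linear accumulation slopes, and the desk quantities
  p = k/(k+ρ) and 1/k, 1/ρ.

## Worked example

The numbered scripts under `analysis/` run the full study; each writes its
tables under `results/`. The deterministic time courses:

```sh
$ python analysis/01_deterministic_timecourses.py
t25: after 180 min constant nest holds 7.56 ants, fluctuating nest 6.32; quorum not attained
t50: after 180 min constant nest holds 7.06 ants, fluctuating nest 6.99; quorum not attained
t75: after 180 min constant nest holds 6.47 ants, fluctuating nest 7.81; quorum not attained
fluctuating-nest population ordering across treatments: 6.321 < 6.989 < 7.814 -> strictly increasing
```

A mostly-poor fluctuating nest loses to the constant mediocre nest, a
mostly-good one beats it, and the 50% treatment is a near tie — the colony
ranks nests by their *time-averaged* quality. The homogenization check makes
that quantitative:

```sh
$ python analysis/02_homogenization.py
t25             fluctuating-vs-averaged sup-norm  0.048 ants (within 0.5-ant tolerance)
t50             fluctuating-vs-averaged sup-norm  0.071 ants (within 0.5-ant tolerance)
t75             fluctuating-vs-averaged sup-norm  0.060 ants (within 0.5-ant tolerance)
...
t25: sup-norm over periods 10/5/2.5/1.25 min = 0.0481/0.0244/0.0123/0.0062 (monotone decreasing)
```

i.e. the population of the fluctuating nest never departs from that of its
time-averaged constant counterpart by more than ~0.07 ants at the
experimental 10-min period, and the gap halves with each halving of the
period. (One robustness variant — magnified amplitude at 75% good — attains
the quorum and the overlap there loosens to 2.6 ants; see
`docs/methods.md`.) Scripts 03 and 04 generate a synthetic 60-replicate
experiment and summarize it, e.g.

```sh
$ python analysis/04_summary_statistics.py
...
pooled: FN 8 vs CN 13, one-sided exact binomial p = 0.192
positive-assessment probabilities (%): {'poor': 57, 'mediocre': 71, 'good': 86}
```

The same pipeline is scriptable via the `nestquorum` CLI
(`simulate`, `synth`, `analyze`, `compare`), every run writing a manifest
(config, seed, version) next to its outputs.

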