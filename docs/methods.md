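# Methods

## Model

`noisybc` simulates opinion formation in a population of `n` agents whose
opinions are scalars `x_i ∈ [0, 1]` (in the climate scenario: concern about
climate change, from dismissive at 0 to alarmed at 1). The baseline is the
pairwise bounded-confidence (BC) assimilation rule: in each time step two
distinct agents are paired uniformly at random and each moves a fraction
`mu` toward the other's message `m` provided `|m − x_i| ≤ ε` (non-strict):

    x_i ← x_i + mu · (m − x_i)   if |m − x_i| ≤ ε,   else unchanged.

`ε` is the confidence bound; a small `ε` operationalizes strong
confirmation bias. Both pair members update simultaneously from each
other's *pre-step* opinions, so the noiseless model is the classic
symmetric Deffuant dynamic: pair sums are conserved, the population mean
is constant, and dispersion is non-increasing.

### The four noise operators

Exactly one noise operator acts per run (their interplay is out of scope),
at a level `ν ≥ 0`, with zero-mean Gaussian deviations of standard
deviation `ν` (or, as a variant, uniform on `[−ν, ν]`):

* **Ambiguity** — the *message* is noisy: `m = x_j + ξ`, resampled until
  `m ∈ [0, 1]`. The receiver applies the BC rule to the noisy message.
  Because of the truncation, a sender at the boundary `x_j = 1` emits
  half-normal messages with mean `1 − ν·√(2/π)`; this asymmetry is what
  makes extremists disproportionately persuasive and drives the drift of
  the population mean toward the edges.
* **Selectivity** — the *acceptance test* is noisy: accept iff
  `|x_j − x_i| ≤ ε + ξ` with a fresh, un-truncated `ξ` per receiver per
  interaction. The acceptance probability for a gap `g` is
  `1 − Φ((g − ε)/ν)`; a negative effective bound always rejects.
* **Adaptation** — the *outcome* is noisy: after a (deterministically)
  accepted interaction the updated opinion is shifted by `ξ`, resampled
  until it stays in `[0, 1]`.
* **Exogenous** — *independent of interaction*: once per time step every
  agent independently jumps with probability `ω = ν` by a truncated
  deviation of scale `ν` (so `ν` doubles as a probability and must not
  exceed 1). The sweep is implemented by geometric gap-sampling over agent
  indices, which is exactly an independent Bernoulli(ν) per agent at
  O(n·ν) cost.

Truncation is always realized by **resampling the deviation**, never by
clipping; a defensive attempt cap (10⁶) guards the rejection loops but is
unreachable for anchors inside the opinion space.

### Communication regimes

Besides the dyadic default, two broadcast-style regimes are available on
the complete topology, with `regime_k` counterparts per step:

* *many-to-one*: one focal receiver hears `regime_k` distinct senders,
  each message drawn/accepted per the active noise operator, and updates
  once toward the mean of the accepted messages (senders do not update).
* *one-to-many*: one sender emits a **single** message (one ambiguity draw
  shared by all receivers — the broadcast is one signal) and each of
  `regime_k` distinct receivers independently applies
  selection/adaptation.

These conventions are the package's own: the fan-in/fan-out aggregation
rules admit several reasonable readings, and ensemble-level claims about
the regimes are therefore kept out of the quantitative targets.

### Topology

Default is a complete graph (pairs drawn uniformly among all agents). A
Watts–Strogatz small-world variant (`sw_degree` default 10, `sw_rewire`
default 0.1 — values chosen as the standard starting point for
small-world robustness checks) samples dyads uniformly over edges; it is
defined for the dyadic regime only.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `n` | 100 | population size (reference protocol) |
| `mu` | 0.5 | convergence speed, (0, 0.5] |
| `epsilon` | 0.2 | confidence bound (no canonical default exists; 0.2 is a moderate bias) |
| `steps` | 100 000 | time steps; at n=100 each agent averages 2000 dyadic interactions |
| `noise.level` | 0 | ν, the noise scale (s.d. of the Gaussian deviations) |
| `snapshot_every` | 1000 | recording cadence (step 0 and the final step are always recorded) |

## Initializers

* `uniform`: i.i.d. Uniform[0, 1]; initial dispersion 1/√12 ≈ 0.289.
* `six_americas`: each agent draws one of six attitude segments
  (dismissive … alarmed, low→high) with probabilities
  0.07/0.11/0.12/0.19/0.33/0.18 and then an opinion uniform within the
  segment's sixth of [0, 1]. The closed-form moments of this density are
  mean 0.6067 and s.d. 0.2530; segments are drawn i.i.d. (multinomial
  counts), not as fixed per-category quotas. Segment intervals are
  half-open `((k−1)/6, k/6]` with `x = 0` owned by the lowest segment.

The sixth-interval-uniform mapping was adopted because it reproduces both
documented initial moments (0.60 ± 0.03, 0.25 ± 0.01 at n = 100) from the
printed segment shares alone; it is validated, not assumed.

## Metrics

* **Dispersion** σ: *population* standard deviation (ddof = 0). At n=100
  the sample/population distinction is below reported precision; fixing
  the population convention makes results deterministic and exactly
  recomputable.
* **Excess kurtosis**: Fisher convention with population moments
  (normal → 0, uniform → −1.2); undefined at zero dispersion, signalled
  by `ZeroDispersionError` and recorded as NaN in summary tables.
* **Cluster count**: sort opinions, split where a consecutive gap exceeds
  0.05, count groups with ≥ 2 members. Noiseless runs from uniform
  initials typically end with ≈ 1/(2ε) clusters. Note the minimum-size
  filter makes the count non-monotone in the gap threshold in edge cases;
  the raw split count (min_size=1) is monotone.
* **PEA** (pro-environmental agreement): final mean ≥ 4/6 *and* final
  dispersion ≤ 0.1, both non-strict, evaluated at the final step.

## Ensembles and seeding

One master seed determines everything. Per-replicate seeds are derived
counter-style via `SeedSequence(master, spawn_key=(index,))`, so ensemble
results are independent of execution order; each run further splits its
seed into an initialization stream, a pairing stream and a noise stream.
Separating pairing from noise makes the ν→0 limit of every noise type
bit-identical to the noiseless run — a strong regression guard.

The reference ensembles use 1000 replicates per cell; the package defaults
to 100–400 (configurable) with binomial error bars, which resolves the
phase structure while keeping sweeps to minutes on a laptop core.

### Critical-noise estimator

`estimate_critical_noise` locates where ensemble agreement breaks: it
scans an ascending ν grid, finds the grid's dispersion minimum, and
linearly interpolates the upward crossing of mean final dispersion through
0.1 from there. Starting at the minimum matters: at very low adaptation
noise, cluster merging is slower than the simulated horizon, so the
low-ν side of the grid shows high dispersion that is a finite-time
artefact, not the agreement-breaking transition. No crossing inside the
grid raises `NoTransitionError`; the estimator never extrapolates. At
ε = 0.2 under adaptation noise it recovers ν*/ε ≈ 0.23–0.25, matching the
analytic 0.25·ε law.

## What the simulations show (and don't)

All quantitative behaviour is established on synthetic populations under
the model's own assumptions: homogeneous `ε` and `ν`, one noise type at a
time, no media, trust, or ideology structure, and survey-calibrated but
i.i.d. initial opinions. Passing tests therefore validate the simulator
and its documented phase behaviour — moderate ambiguity noise plus
moderate bias producing high-concern consensus, selectivity noise
producing agreement at the cost of lower mean concern, adaptation and
exogenous noise breaking agreement beyond a bias-proportional threshold —
not predictions about real populations.

## Numerical notes

* Acceptance comparisons are non-strict (`≤`) everywhere.
* Noiseless mean conservation holds to ~1e-12 over 10⁵ steps (floating
  point accumulation only); pair sums are conserved per step to 1 ulp.
* With n = 100 and ε ≈ 0.35 a minority (~15%) of noiseless runs lock into
  an absorbing two-cluster state; weak-bias "agreement" is an
  ensemble-mean statement (mean σ ≪ 0.1), not a per-run guarantee.
* Simulation kernels are numba-compiled; the first call in a fresh
  environment pays a few seconds of JIT compilation.

## Known limitations

* Regime conventions (mean-of-accepted aggregation; single-draw
  broadcast) are plausible but not canonical; treat cross-regime
  comparisons qualitatively.
* The small-world variant fixes pairing to uniform-over-edges; degree
  heterogeneity effects on per-agent interaction rates are not corrected.
* Ensemble PEA frequencies at a few hundred replicates carry binomial
  error of a few percentage points; comparisons near thresholds should
  use the reported replicate counts to size error bars.
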