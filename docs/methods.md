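# Methods

## The model

`paccsim` simulates a cancer cell population structured into three states:
proliferative therapy-susceptible cells (**2N+**, count `N`), cells in the
non-proliferative polyaneuploid refuge state (**PACC**, count `P`), and
proliferative cells that have passed through the PACC state (**2N+(R)**,
count `R`). Counts are in units of 10⁷ cells, so the carrying capacity
K = 100 corresponds to 10⁹ literal cells; simulating at single-cell
granularity with ~10⁹ cells is neither feasible nor informative, and the
population-level dynamics live on the 0–100 scale.

The mean-field system is given in the README. Its assumptions:

* Both proliferative states grow logistically with the same r and K and are
  inhibited equally by all three states.
* Drug kill is Michaelis–Menten in the evolved trait:
  per-capita rate m/(λ + βvᵢ) per active drug i. PACC cells do not divide
  and are fully therapy-refractory; they die only at the background rate b.
* Entry into the PACC state has an obligate component (rate γ, maintaining
  the small PACC reservoir observed without treatment) and a facultative,
  therapy-induced component proportional to the per-capita kill rate
  (c·kill). Every entry succeeds only with probability ζ; a failed
  polyaneuploid transition is mitotic catastrophe and the cell is lost.
  A single Bernoulli draw at event execution implements this; the mean
  field is identical to carrying ζ in the influx term.
* Depolyploidization (rate a per PACC cell) replaces one PACC cell with
  **two** proliferative daughters — 2N+(R) cells in the full model, 2N+
  cells in the `pacc_no_R` control, where the post-PACC state is removed
  but the PACC life cycle is kept.
* There is no cost of resistance and no within-state heterogeneity: the
  trait vector v = [v₁, v₂] is a single population-level resident strategy,
  not a per-cell attribute.

One printing inconsistency in the source system was resolved: the
facultative term of the susceptible equation couples the trait through
"λ_N + b vᵢ" while every other kill and facultative term uses β; b is the
background PACC death rate and appears nowhere else against v, so β is used
throughout.

## Stochastic realization

The engine is an exact Gillespie simulation over nine channels: birth in
2N+ and 2N+(R); death in all three states; and the four switches
2N+→PACC, PACC→2N+(R) (or →2N+ in `pacc_no_R`), 2N+(R)→PACC, 2N+(R)→2N+.
Waiting times are exponential with mean 1/(total rate). Two structural
choices deserve note:

* **Birth-only logistic.** The net logistic term is realized as a birth
  channel clamped at zero, with no separate crowding-death channel. Below
  carrying capacity this reproduces the mean field exactly. Above K the
  stochastic population has no density-dependent loss, and because
  depolyploidization doubles (net production ζ·2a/(a+b) per transit against
  an obligate loss of (1−ζ)γ), a drug-free population drifts upward slowly
  (~0.7 %/day at defaults) instead of settling on the deterministic
  equilibrium a few percent above K. This is a deliberate property of the
  nine-channel structure: replacing the clamp with a crowding-death channel
  measurably changes the extinction statistics of every scenario (it
  removes the modest super-capacity reserve present at therapy onset) and
  no longer reproduces the benchmark extinction probabilities. The
  mean-field correspondence is therefore verified in the sub-capacity
  regime, where it is exact.
* **Schedule boundaries.** Propensities are piecewise constant between
  events but jump at therapy-interval edges. The engine discards any
  tentative event whose waiting time overshoots the next boundary and
  restarts the clock there — the standard exact treatment of
  time-inhomogeneous, piecewise-constant rates. A quiescent configuration
  (zero total rate) jumps directly to the next boundary.

Extinction is N+P+R = 0 at any time up to the 900-day horizon and is
absorbing; the extinction probability of an experiment is the fraction of
trials extinct by the horizon.

## Evolution: trait substitution

Evolution follows adaptive-dynamics trait substitution. At each division
(mutational breadth σ₁) and each depolyploidization (breadth σ₂ > σ₁,
reflecting the elevated genomic content of the PACC state), a mutation
arises with probability φ; its additive effect on one resistance trait is
drawn from Normal(0, σ). A mutant that strictly increases invasion fitness
replaces the resident trait instantly; all others are purged without
demographic effect. Two aspects of this rule are fixed by identification
against the benchmark extinction probabilities rather than by any single
sentence of the source description, and both are discrete structural
choices, not tuned numbers:

* **Mutation target.** A division mutation targets the trait of the drug
  currently applying selective pressure (uniform among active drugs if
  several were active). A depolyploidization mutation is drug-agnostic: it
  targets a uniformly chosen trait, active or not. Since fitness is flat in
  an inactive drug's trait, roughly half of the depolyploidization mutants
  are neutral and purged — the PACC pathway supplies larger steps (σ₂) but
  undirected ones. Targeting the active drug at both event types roughly
  doubles the effective σ₂ supply and depresses the high-breadth and
  post-PACC scenario extinction probabilities far outside their reference
  bands; uniform targeting at both events halves the division supply and
  inflates the single-state extinction instead. Only the split rule
  reproduces all benchmarks simultaneously.
* **Acceptance criterion.** Invasion fitness is the per-capita net growth
  rate of the susceptible 2N+ state — logistic term minus obligate loss,
  kill, and facultative loss — whose rate constants (λ_N, c_N) do not
  depend on v. Acceptance therefore reduces exactly to "the targeted
  drug is active and the increment is positive"; ties (every inactive-trait
  proposal) are rejected. Evaluating fitness in the post-PACC state instead
  would let inactive-trait mutations hitch-hike on the trait-coupled
  λ_R(v), c_R(v) bonuses, which again breaks the benchmark agreement. The
  equivalence between the implemented sign rule and an explicit
  resident-vs-mutant comparison of susceptible-state fitness is pinned by a
  randomized test.

Consequences asserted as invariants: traits are non-decreasing along every
trajectory, and frozen during drug holidays.

## Parameters

Baseline values (see `ModelParameters`): r = 0.6 /day, K = 100, γ = 0.02
/day, m = 0.7 /day (0.5 for the low-dose control), λ_N = 1, λ_R = 2, β = 1,
c_N = 0.4 /day, c_R = 0.8 /day, a = 0.2 /day, b = 0.01 /day, μ = 0.2 /day
(0 except under temporary innate resistance), ζ = 0.7, φ = 0.05 /division,
σ₁ = 0.01, σ₂ = 0.05 (0.005/0.01/0.05 in the breadth comparison). At these
values the drug-exposed population at v = 0 is demographically *critical*
(the PACC loop exactly balances therapy losses at low density), which is
what makes the extinction probabilities sharply discriminating between the
hypotheses — and sensitive to the structural choices documented above.

## Experiments and reproducibility

`run_replicates` executes n_sets × n_trials independent trials (defaults
10 × 100) and reports the mean and sample (n−1) SD of per-set extinction
percentages, plus a Clopper–Pearson 99% CI on the pooled probability in
place of any between-arm hypothesis test. Per-trial random streams derive
from `SeedSequence(base_seed, spawn_key=(set, trial))`, so results are
independent of batch layout and identical for any partition of the trials.
Sweeps reuse the same base seed at every grid value (paired comparisons);
the same- and different-drug arms run at the same base seed share their
streams until the second treatment window, so arms whose extinctions all
occur in the first window coincide exactly rather than merely
statistically. Sweep grids: c_R over 0.4–1.6 and λ_R over 1.0–2.5 in 7
points, μ over 0–0.4 in 5 points.

The numba kernel and the pure-Python engine implement one draw-order
contract and are bit-identical per seed (asserted in the suite); the kernel
only elides the event log. Full replication of one scenario × schedule
(1000 trials, ~10⁴–10⁵ events each) takes roughly a second of compiled
time; the whole benchmark battery runs in about a minute including JIT
compilation. Test-suite sweep checks run at 5 sets × 60 trials, sized to
keep the suite fast while leaving the monotonicity and saturation claims
well outside Monte-Carlo noise.

## Deterministic reference

`ode.integrate` solves the printed mean-field system piecewise across
schedule boundaries (LSODA, rtol = atol = 1e−8, solutions clipped at zero
within tolerance), with traits frozen; a quasi-static trait ramp
(`traits_fn`) is available for exploration but is an extension beyond the
published model, which defines evolution only stochastically.
`ode.equilibrium` finds the drug-free coexistence fixed point of the
enabled compartments by root-finding from several interior starts,
excluding the trivial extinction root and flagging non-uniqueness. The
drug-free equilibrium keeps a small positive PACC fraction (~6% at
defaults), matching the pre-therapy reservoir the stochastic runs show.

## What the simulations do and do not show

All experiments are self-generating; there is no external data. The model
deliberately omits spatial structure, per-cell trait heterogeneity, genetic
drift at stationarity, costs of resistance, and any mechanistic detail of
how polyaneuploidy produces variation. Extinction probabilities are
statements about this stylized system at the baseline parameter set —
chosen to be biologically plausible and to separate the hypotheses clearly
— not calibrated predictions for any cell line or clinical schedule. The
qualitative conclusions (refuge + elevated variation rescue populations;
innate-resistance memory produces stronger cross-resistance than
re-entry memory; resensitization buffers it) are the robust content.

## Known limitations

* Above carrying capacity the stochastic model and the printed ODE
  deliberately diverge (see "Birth-only logistic"); drug-free ensembles
  held past equilibration drift a few percent above K per 10 days.
* Two drugs at most; at-most-one-active schedules are what the benchmark
  experiments use, though the types allow simultaneous dosing.
* The exact SSA is the only engine; no tau-leaping, so runtime scales with
  event count (~10⁵ per 900-day trial near capacity).
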