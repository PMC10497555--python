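# paccsim

Stochastic eco-evolutionary simulator of cancer cell populations structured
around the polyaneuploid cancer cell (PACC) state, built to ask how
**cross-resistance** to mechanistically independent therapies can arise.

Cancer cells in the proliferative, therapy-susceptible **2N+** state can
undergo a polyaneuploid transition (PAT) into the non-proliferative,
therapy-refractory **PACC** state, and later depolyploidize into two
proliferative daughters (**2N+(R)** cells, "post-PACC"). The package
simulates this life cycle as an exact Gillespie birth–death–switching
process with an evolving, population-level drug-resistance trait vector
v = [v₁, v₂], and compares five hypotheses about what the passage through
the PACC state leaves behind:

| scenario | post-PACC effect |
|---|---|
| `single_state` | no PACC biology at all (control) |
| `pacc_no_R` | PACC refuge only; daughters return to 2N+ (control) |
| `pacc_memory` | faster re-entry into the PACC state: c_R(v) = c_R / (1 + e^(−2Σvᵢ)), λ_R = λ_N, μ = 0 |
| `innate_resistance` | higher innate resistance: λ_R(v) = λ_R / (1 + e^(−2Σvᵢ)), c_R = c_N, μ = 0 |
| `temporary_innate_resistance` | as innate resistance, plus resensitization 2N+(R) → 2N+ at rate μ |

## Model

The mean-field skeleton (populations N, P, R in units of 10⁷ cells) is

```
dN/dt = r N (K−N−P−R)/K − γN − Σᵢ [ N mᵢ/(λ_N+βvᵢ) + c_N N mᵢ/(λ_N+βvᵢ) ] + μR
dP/dt = ζγ(N+R) + ζ Σᵢ [ c_N N mᵢ/(λ_N+βvᵢ) + c_R(v) R mᵢ/(λ_R(v)+βvᵢ) ] − aP − bP
dR/dt = r R (K−N−P−R)/K − γR − Σᵢ [ R mᵢ/(λ_R(v)+βvᵢ) + c_R(v) R mᵢ/(λ_R(v)+βvᵢ) ] + 2aP − μR
```

with logistic growth (r, K), Michaelis–Menten drug kill (dose m, innate
resistance λ, evolved resistance βvᵢ), obligate (γ) and therapy-induced
facultative (c·kill) transitions into the PACC state, PAT success
probability ζ, depolyploidization a (one PACC cell → two daughters),
background PACC death b and resensitization μ. The stochastic engine reads
nine event propensities off these equations (two births, three deaths, four
switches) and executes them with exponential waiting times, exactly across
therapy-schedule boundaries. Resistance evolves by trait substitution:
mutations arise at division (breadth σ₁) or depolyploidization (breadth σ₂)
with probability φ, and a mutant replaces the resident trait iff it
strictly increases the per-capita growth rate of the susceptible state —
so traits only ratchet upward, and only while a drug is active.

The canonical experiment gives no therapy until day 100, drug 1 until 400,
a holiday until 500, drug 1 (same) or drug 2 (different) until 800, then
nothing until day 900, starting from 50 susceptible cells; extinction
probability is estimated over 10 sets × 100 trials.

## Worked example

```
$ paccsim run --preset pacc-memory-same --outdir out/memory --seed 7
pacc_memory (same drug): extinction 53.7 ± 5.3 % (10 sets × 100 trials)

$ paccsim run --preset innate-resistance-same --outdir out/innate --seed 7
innate_resistance (same drug): extinction 31.1 ± 6.7 % (10 sets × 100 trials)
```

Each line is the mean ± across-set SD of the per-set extinction percentage
under repeated application of the *same* drug: populations whose post-PACC
cells re-enter the refuge faster (PACC memory) still lose more than half of
the trials, while populations whose post-PACC cells carry drug-agnostic
innate resistance survive far more often — innate resistance is the more
effective route to cross-resistance. Each output directory holds
`summary.csv`, per-trial outcomes (`trials.csv`) and a `manifest.json`
sufficient to replay the run bit-for-bit. The same experiments are
available from Python:

```python
from paccsim import make_scenario, make_schedule, run_replicates

res = run_replicates(make_scenario("innate_resistance"),
                     make_schedule(same_drug=False), base_seed=7)
print(res.mean_extinction_pct, res.sd_extinction_pct)
```

Other entry points: `paccsim sweep --param c_R --grid 0.4:1.6:7 ...` for
one-parameter extinction sweeps (paired seeds across the grid) and
`paccsim ode` for the deterministic mean-field trajectory.

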