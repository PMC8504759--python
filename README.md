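# idsim

Agent-based simulation of **affective polarization through social-identity
reinforcement**. The package asks a simple question from computational
social science: what happens to the strength of group identities when people
gain the freedom to choose whom they interact with — for example through
communication technology — instead of being confined to whoever happens to
be nearby?

It is aimed at researchers in opinion dynamics / computational sociology who
want a fast, fully reproducible implementation of the model and its three
experiment protocols, with a CLI for parameter sweeps and CSV/JSON outputs.

## The model

`N` agents occupy the sites of a one-dimensional ring lattice. Agent *i*
carries a fixed identity label *kᵢ* ∈ {1, …, M} and a scaled identity
strength *wᵢ* ∈ [*w*₋, *w*₊] = [0.05, 0.95] (the scaling is
*w* = 1 − e^(−w̃) from an unbounded raw strength *w̃*). One **time step**:

1. A focal agent *i* is picked uniformly. It interacts with its `n_loc`
   nearest lattice neighbors (constrained, heterogeneous ties) and `n_glob`
   globally sampled agents **sharing its identity** (chosen, homophilous
   ties).
2. It receives the aggregate utility
   *uᵢ* = Σ_{j∈Sᵢ} *wᵢwⱼ*(2δ_{kᵢkⱼ} − 1) — positive feedback from in-group
   partners, negative from out-group partners, weighted by both strengths.
3. Reinforcement update: *wᵢ* ← *wᵢ* + *d·uᵢ*(1 − *wᵢ*), clamped to the
   bounds (*d* = 0.5; the (1 − *wᵢ*) factor is the Jacobian of the strength
   scaling).
4. With probability *p*₍expl₎ = 0.2 an explorative perturbation
   (1 − *wᵢ*)·U[−*c*₍expl₎, *c*₍expl₎] is added (*c*₍expl₎ = 0.05).
5. Random migration mixes the lattice: each agent swaps positions with
   probability *ε* = 0.02 per step (expected *Nε*/2 pair swaps per update).

With all ties local (`n_glob = 0`) migration keeps identity strengths low — a
**fluid** regime. As `n_glob` grows (holding `n_loc + n_glob = 8`), identity
reinforcement becomes self-sustaining and one, then several, identities
fixate near the maximum — a **solid**, polarized regime. Reversing the
process exhibits **hysteresis**: a dominant identity survives even when all
global ties are removed.

## Worked example

```python
import numpy as np
from idsim import ModelParams, RunSpec, transition_run, regime_sweep

spec = RunSpec(params=ModelParams(), total_updates=50_000, base_seed=1)
traj = transition_run(spec)
print(np.round(np.sort(traj.mean_strengths[-1])[::-1], 3))
# [0.95  0.055 0.054 0.053]

spec = RunSpec(params=ModelParams(), total_updates=100_000, replicates=5, base_seed=1)
res = regime_sweep(spec, n_glob_values=[0, 4, 8])
for g, row in zip(res.n_glob_values, res.rank_sorted_strengths):
    print(g, np.round(row, 3))
# 0 [0.058 0.057 0.056 0.056]
# 4 [0.95  0.771 0.054 0.053]
# 8 [0.95  0.95  0.95  0.95 ]
```

The first run (5 local / 3 global ties, 50,000 updates) shows the transition:
one of the four identities fixates at the upper bound while the others are
suppressed to the lower bound. The sweep shows the regime structure as
rank-sorted, replicate-averaged final strengths: all weak with purely local
interaction, a growing number of dominant identities as global ties replace
local ones, and full saturation when all ties are chosen.

The same experiments from the shell:

```bash
idsim transition --updates 50000 --seed 1 --out results --plot
idsim sweep --updates 100000 --replicates 20 --seed 1 --out results
idsim hysteresis --updates 200000 --replicates 20 --seed 1 --out results --plot
idsim sensitivity --updates 200000 --replicates 20 --seed 1 --out results
```

Each command writes a tidy CSV plus a JSON sidecar containing the fully
resolved parameter set; the sidecar alone suffices to regenerate the result.

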