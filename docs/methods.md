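# Methods

## Model

The simulator implements a minimal mechanism for affective polarization:
identity strength grows through rewarding in-group contact and shrinks
through aversive out-group contact, with the interaction structure — not the
agents' opinions — as the control variable.

State. `N` agents on a ring lattice (periodic boundary). Agent *i* has an
immutable identity label *kᵢ* ∈ {0, …, M−1} and a scaled strength
*wᵢ* ∈ [w_min, w_max]. The scaling *w* = 1 − exp(−w̃) maps an unbounded raw
strength onto the unit interval; the dynamics is closed in *w*, so the raw
variable never needs to be represented (it is exposed as a documented
bijection for testing). Bounds strictly inside (0, 1) prevent absorbing
states: *w* = 0 would mean an identity with no strength at all, *w* = 1
infinite strength, and either would freeze the learning process.

One time step (= one individual learning update):

1. **Focal pick.** One agent uniformly at random.
2. **Interaction set.** Its `n_loc` nearest ring sites (⌊n_loc/2⌋ per side,
   odd counts take the extra site clockwise) plus `n_glob` agents drawn
   uniformly without replacement from all agents sharing its identity,
   excluding the focal agent and its current local neighbors. If fewer
   candidates exist than `n_glob`, the interaction set simply shrinks.
3. **Utility.** *uᵢ* = Σⱼ *wᵢwⱼ*(2δ_{kᵢkⱼ} − 1): each same-identity partner
   contributes +*wᵢwⱼ*, each other-identity partner −*wᵢwⱼ*. Feedback is
   proportional to both parties' identification, so weak agents neither
   reward nor threaten much.
4. **Reinforcement.** *wᵢ* ← clamp(*wᵢ* + d·*uᵢ*·(1 − *wᵢ*)). The (1 − *wᵢ*)
   factor is the Jacobian of the strength scaling (in raw strength the
   update is simply Δw̃ = d·u), which damps learning near the upper bound.
5. **Exploration.** With probability `p_expl`, add (1 − *wᵢ*)·U with
   U ~ Uniform[−c_expl, c_expl], then clamp again. Only the focal agent
   explores, after its learning increment.
6. **Migration.** Each agent changes place with probability ε per time step,
   executed as an expected N·ε/2 uniformly chosen pair swaps per update
   (⌊N·ε/2⌋ swaps plus one more with the fractional probability). Identity
   and strength travel with the agent.

Only the focal agent learns in a step; partners provide feedback but are not
updated. This keeps "number of updates" identical to "number of individual
reinforcement learning steps", the time unit used by all experiments.

## Parameters

| name | default | meaning |
|---|---|---|
| `N` | 200 | agents (= ring sites) |
| `M` | 4 | identity labels, balanced N/M each at start |
| `n_loc` | 5 | local (constrained) ties per update |
| `n_glob` | 3 | global same-identity (chosen) ties per update |
| `d` | 0.5 | learning rate |
| `epsilon` | 0.02 | per-agent migration probability per update |
| `p_expl` | 0.2 | exploration probability per update |
| `c_expl` | 0.05 | exploration half-width |
| `w_min`, `w_max` | 0.05, 0.95 | hard strength bounds; also the initial strength |

The experiments hold `n_loc + n_glob = 8` so that the number of global ties
`n_glob` is the single control parameter of the interaction structure.

**Migration semantics.** ε is a *per-agent* rate: every agent relocates with
probability ε each time step, giving N·ε/2 = 2 expected pair swaps per update
at defaults. This intensity is load-bearing. The weak-identity (fluid) state
at `n_glob = 0` is only metastable: a locally nucleated strong cluster can
spread through the whole population, because a single strong in-group
neighbor outweighs many weak out-group neighbors in the utility. Migration
at ~2 swaps/update disperses nucleating clusters faster than they form and
keeps the all-local system fluid; at ~50× weaker mixing (one swap attempt
per update per *system*), nucleation wins and a dominant identity emerges
even with all ties local, erasing the fluid/solid distinction the model is
about. A scan of migration intensity places the fluid/dominant boundary near
0.15–0.25 swaps per update, so ε = 0.005 (0.5 swaps/update) sits just above
the boundary — consistent with the observation that hysteresis only *starts*
to break there (see Limitations).

## Experiments

* **transition_run** — one run from the balanced initial state (all
  strengths at w_min, labels randomly placed), recording per-identity mean
  strengths; baseline 5 local / 3 global ties, 50,000 updates. Shows the
  stochastic self-reinforcement of an initially random advantage.
* **regime_sweep** — fresh start for every (n_glob, replicate) cell,
  n_glob = 0…8 with n_loc = 8 − n_glob; final per-identity means are sorted
  descending *within* each replicate ("order of dominance") and averaged
  rank-wise. Averaging label-wise instead would wash out dominance, since
  which label wins varies by seed.
* **hysteresis_protocol** — one continuous history per replicate: 9 stages
  stepping n_glob 0→8, then 8 stages back down to 0, the population state
  carried across stages; rank-sorted means recorded at each stage end. The
  up/down branch gap is quantified by the **rank-1 hysteresis area**:
  Σ_g (down(g) − up(g)) for the strongest identity.
* **sensitivity_sweep** — the hysteresis protocol per migration rate
  (default ε ∈ {0.02, 0.005}), matched seeds across rates.

Stage length is a fixed update budget (default 200,000), not a convergence
criterion — reproducibility over adaptivity. Replicate *r* always uses seed
`base_seed + r`; results are independent of execution order.

## Determinism and the dual implementation

All randomness of a run flows through one splitmix64 stream in a frozen
draw order (focal pick → partner selection → exploration → migration; see
`idsim.model` for the exact contract). The production path is a numba
kernel; a deliberately naive straight-loop reference (`idsim.reference`)
implements the same contract, and the test suite requires **bit-identical**
trajectories between the two over 10⁴ updates at several parameter settings.
splitmix64 was chosen because its state transition is trivially identical in
compiled and interpreted code; utilities are summed in a fixed partner order
(ascending site, then selection order) so floating-point results are
reproducible to the last bit.

Numerical notes: double precision throughout; hard clamping after the
learning increment and again after exploration; rank ties broken by
ascending identity label (measure-zero under exploration noise); balanced
initial label counts with any remainder assigned to the lowest labels.

## What the experiments do and do not show

The simulator generates all of its own data; there is no empirical input.
Conclusions are therefore statements about the model: a one-dimensional
ring is a deliberately minimal stand-in for constrained geography, identity
labels never change (no conversion, only expression), and migration is
random rather than preference-driven (no Schelling-type sorting). Agreement
with the qualitative regime structure says nothing about parameter values in
real populations.

## Known limitations

* The fluid/solid boundary in migration intensity lies near 0.15–0.25
  swaps/update, slightly below the 0.5 swaps/update corresponding to
  ε = 0.005. At that rate early nucleation in the up branch is still rare
  (~2% of replicates per protocol), while the down-branch survivor erodes
  marginally *more* at ε = 0.02 than at 0.005. The net effect is that the
  rank-1 hysteresis area at ε = 0.005 is not reliably smaller than at
  ε = 0.02 at feasible replicate counts — the loop shrinks decisively only
  below ε ≈ 0.003. The directional sensitivity check in the acceptance
  suite documents this honestly rather than widening its condition.
* Exploration is applied as a separate clamped step after the learning
  increment. A single combined increment is an equally defensible reading;
  at the boundary it slightly weakens the upward noise ratchet. The regime
  structure is unchanged under either choice, but fine thresholds (such as
  the one above) can move.
* The per-update cost of global partner selection is O(N/M); for very large
  populations a resampling-based selection would be preferable.
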