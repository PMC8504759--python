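"""Core state types and the single-update stochastic dynamics.

The model: ``N`` agents sit on a one-dimensional ring lattice.  Agent ``i``
carries an immutable identity label ``k_i`` in ``0..M-1`` and a scaled
identity strength ``w_i`` confined to ``[w_min, w_max]``.  One time step picks
a focal agent uniformly, lets it interact with its ``n_loc`` nearest lattice
neighbors plus ``n_glob`` globally sampled agents that share its identity,
sums the interaction utility

    u_i = sum_j  w_i * w_j * (2*delta(k_i, k_j) - 1),

and applies the reinforcement update ``w_i += d * u_i * (1 - w_i)`` (the
``1 - w_i`` factor is the Jacobian of the scaling ``w = 1 - exp(-w_raw)``
that maps the unbounded raw strength onto the unit interval).  With
probability ``p_expl`` a damped uniform perturbation is then added, and
random migration mixes the lattice: each agent swaps ring positions with
probability ``epsilon`` per time step, realized as an expected
``N * epsilon / 2`` uniformly chosen pair swaps per update.  Migration
decouples cluster formation from the initial layout without introducing
Schelling-style preferential moves; its rate is what stabilizes the
weak-identity ("fluid") state when all interaction is local.

Determinism contract
--------------------
All randomness of one run flows through a single :class:`~idsim.rng.SplitMix64`
stream in a frozen draw order per update:

1. focal agent: ``randbelow(N)``;
2. global partners: partial Fisher-Yates over the eligible pool, one
   ``randbelow(P - t)`` per selected partner (no draws if ``n_glob == 0`` or
   the pool is empty);
3. exploration: one ``next_double`` Bernoulli trial, plus one ``next_double``
   magnitude draw only when the trial succeeds;
4. migration: with ``mu = N * epsilon / 2`` expected pair swaps per update,
   one ``next_double`` Bernoulli trial on the fractional part of ``mu``
   (only when that fraction is nonzero), then per executed swap one
   ``randbelow(N)`` and one ``randbelow(N - 1)`` for the pair.

Utility contributions are summed sequentially: local partners in ascending
site order, then global partners in selection order.  The numba kernel
(:mod:`idsim._kernel`) and the naive reference (:mod:`idsim.reference`)
reproduce this contract bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams
from .rng import SplitMix64

__all__ = [
    "PopulationState",
    "init_population",
    "scale_strength",
    "unscale_strength",
    "local_neighbor_indices",
    "sample_global_partners",
    "compute_utility",
    "reinforcement_update",
    "exploration_perturbation",
    "migration_step",
    "single_update",
    "run_updates",
]


# ---------------------------------------------------------------------------
# state


@dataclass
class PopulationState:
    """Mutable per-agent state of one simulation run.

    ``pos_of_agent`` maps agent index -> ring site and ``agent_at_site`` is
    its inverse; both are maintained in lockstep.  Identities never change
    during a run; only strengths and positions do.
    """

    identities: np.ndarray      # (N,) int64, labels 0..M-1
    strengths: np.ndarray       # (N,) float64 in [w_min, w_max]
    pos_of_agent: np.ndarray    # (N,) int64, permutation of 0..N-1
    agent_at_site: np.ndarray   # (N,) int64, inverse permutation
    rng: SplitMix64
    _members: list | None = field(default=None, repr=False)

    @property
    def N(self) -> int:
        return self.identities.shape[0]

    def members_of(self, label: int) -> np.ndarray:
        """Agent indices holding ``label``, ascending (cached: labels are
        immutable)."""
        if self._members is None:
            M = int(self.identities.max()) + 1
            self._members = [
                np.flatnonzero(self.identities == m) for m in range(M)
            ]
        return self._members[label]

    def copy(self) -> "PopulationState":
        return PopulationState(
            identities=self.identities.copy(),
            strengths=self.strengths.copy(),
            pos_of_agent=self.pos_of_agent.copy(),
            agent_at_site=self.agent_at_site.copy(),
            rng=self.rng.copy(),
        )


def init_population(params: ModelParams, rng: SplitMix64 | None = None) -> PopulationState:
    """Balanced initial population: all strengths at ``w_min``.

    Identity labels are assigned in balanced counts (``N // M`` each; if M
    does not divide N the remainder goes to the lowest labels) and the agents
    are placed on the ring by a random permutation drawn from the run stream
    (Fisher-Yates, one ``randbelow`` per swap).
    """
    if rng is None:
        rng = SplitMix64(params.seed)
    N, M = params.N, params.M
    counts = [N // M + (1 if m < N % M else 0) for m in range(M)]
    identities = np.repeat(np.arange(M, dtype=np.int64), counts)
    strengths = np.full(N, params.w_min, dtype=np.float64)

    pos = np.arange(N, dtype=np.int64)
    for i in range(N - 1, 0, -1):
        j = rng.randbelow(i + 1)
        pos[i], pos[j] = pos[j], pos[i]
    agent_at_site = np.empty(N, dtype=np.int64)
    agent_at_site[pos] = np.arange(N, dtype=np.int64)
    return PopulationState(identities, strengths, pos, agent_at_site, rng)


# ---------------------------------------------------------------------------
# elementary operations


def scale_strength(w_raw: float) -> float:
    """Map a raw strength in [0, inf) to the scaled strength 1 - exp(-w_raw).

    The dynamics runs entirely in scaled space; this bijection is exposed for
    documentation and round-trip checks.
    """
    if w_raw < 0:
        raise ValueError("raw strength must be non-negative")
    return 1.0 - math.exp(-w_raw)


def unscale_strength(w: float) -> float:
    """Inverse of :func:`scale_strength`: w -> -ln(1 - w)."""
    if not 0.0 <= w < 1.0:
        raise ValueError("scaled strength must lie in [0, 1)")
    return -math.log1p(-w)


def local_neighbor_indices(pos: int, n_loc: int, N: int) -> list[int]:
    """The ``n_loc`` ring sites nearest to ``pos``, ascending site order.

    Symmetric ``floor(n_loc / 2)`` sites on each side; an odd count takes the
    extra site clockwise (``pos + half + 1``).  Any fixed side convention is
    statistically equivalent under migration; this one is the documented
    canonical choice.
    """
    if not 0 <= pos < N:
        raise ValueError("pos must lie in [0, N)")
    if n_loc >= N:
        raise ValueError("n_loc must be smaller than the ring size")
    half = n_loc // 2
    sites = [(pos - k) % N for k in range(1, half + 1)]
    sites += [(pos + k) % N for k in range(1, half + 1)]
    if n_loc % 2:
        sites.append((pos + half + 1) % N)
    return sorted(sites)


def sample_global_partners(
    state: PopulationState,
    focal: int,
    n_glob: int,
    excluded,
    rng: SplitMix64,
) -> list[int]:
    """Sample global partners: uniform without replacement among agents that
    share the focal's identity, excluding the focal and ``excluded`` (its
    current local neighbors, to keep the interaction set duplicate-free).

    Returns ``min(n_glob, pool size)`` agents; an under-full pool simply
    shrinks the interaction set.  Selection is a partial Fisher-Yates shuffle
    over the pool in ascending-agent order, one ``randbelow`` per pick.
    """
    if n_glob == 0:
        return []
    excluded_set = set(int(e) for e in excluded)
    pool = [
        int(j)
        for j in state.members_of(int(state.identities[focal]))
        if j != focal and int(j) not in excluded_set
    ]
    P = len(pool)
    k = min(n_glob, P)
    for t in range(k):
        j = t + rng.randbelow(P - t)
        pool[t], pool[j] = pool[j], pool[t]
    return pool[:k]


def compute_utility(
    w_focal: float,
    focal_identity: int,
    partner_strengths,
    partner_identities,
) -> float:
    """Aggregate interaction utility of the focal agent.

    Each partner j contributes ``w_focal * w_j`` with positive sign when the
    identities match and negative sign otherwise.  Summation is sequential in
    the given partner order (part of the bit-level determinism contract).
    """
    if len(partner_strengths) != len(partner_identities):
        raise ValueError("partner strength/identity vectors differ in length")
    u = 0.0
    for wj, kj in zip(partner_strengths, partner_identities):
        u += w_focal * wj * (1.0 if kj == focal_identity else -1.0)
    return u


def _clamp(w: float, w_min: float, w_max: float) -> float:
    if w < w_min:
        return w_min
    if w > w_max:
        return w_max
    return w


def reinforcement_update(
    w: float, u: float, d: float, w_min: float, w_max: float
) -> float:
    """One reinforcement-learning step: ``w + d * u * (1 - w)``, clamped.

    Zero utility is a fixed point; the ``1 - w`` damping comes from the
    strength scaling, so gains saturate near the upper bound.
    """
    return _clamp(w + d * u * (1.0 - w), w_min, w_max)


def exploration_perturbation(
    w: float,
    p_expl: float,
    c_expl: float,
    w_min: float,
    w_max: float,
    rng: SplitMix64,
) -> float:
    """Explorative noise: with probability ``p_expl`` add ``(1 - w) * U``
    with ``U ~ Uniform[-c_expl, c_expl]``, then clamp.

    The Bernoulli trial always consumes one uniform draw; the magnitude draw
    is consumed only on success (draw-order contract).
    """
    if rng.next_double() < p_expl:
        u = rng.next_double()
        w = _clamp(w + (1.0 - w) * (c_expl * (2.0 * u - 1.0)), w_min, w_max)
    return w


def migration_step(state: PopulationState, epsilon: float, rng: SplitMix64) -> PopulationState:
    """Random migration: each agent swaps ring positions with probability
    ``epsilon`` per time step.

    Executed as ``mu = N * epsilon / 2`` expected pair swaps per update:
    ``floor(mu)`` swaps always, plus one more with probability ``mu mod 1``.
    Each swap exchanges the positions of two distinct uniformly chosen
    agents; strengths and identities travel with the agent.  Mutates and
    returns ``state``.
    """
    N = state.N
    mu = N * epsilon / 2.0
    n_swaps = int(mu)
    frac = mu - n_swaps
    if frac > 0.0 and rng.next_double() < frac:
        n_swaps += 1
    for _ in range(n_swaps):
        a = rng.randbelow(N)
        b = rng.randbelow(N - 1)
        if b >= a:
            b += 1
        pa, pb = state.pos_of_agent[a], state.pos_of_agent[b]
        state.pos_of_agent[a], state.pos_of_agent[b] = pb, pa
        state.agent_at_site[pa], state.agent_at_site[pb] = b, a
    return state


def single_update(state: PopulationState, params: ModelParams) -> PopulationState:
    """One full time step (focal pick -> interaction -> learning ->
    exploration -> migration).  Only the focal agent's strength changes;
    partners give feedback but do not learn in this step.  Mutates and
    returns ``state``."""
    rng = state.rng
    focal = rng.randbelow(params.N)
    fpos = int(state.pos_of_agent[focal])
    sites = local_neighbor_indices(fpos, params.n_loc, params.N)
    local_agents = [int(state.agent_at_site[s]) for s in sites]
    partners = list(local_agents)
    partners += sample_global_partners(state, focal, params.n_glob, local_agents, rng)

    wf = float(state.strengths[focal])
    kf = int(state.identities[focal])
    u = compute_utility(
        wf,
        kf,
        [float(state.strengths[j]) for j in partners],
        [int(state.identities[j]) for j in partners],
    )
    w = reinforcement_update(wf, u, params.d, params.w_min, params.w_max)
    w = exploration_perturbation(
        w, params.p_expl, params.c_expl, params.w_min, params.w_max, rng
    )
    state.strengths[focal] = w
    migration_step(state, params.epsilon, rng)
    return state


# ---------------------------------------------------------------------------
# run driver


def run_updates(
    state: PopulationState,
    params: ModelParams,
    n_updates: int,
    record_every: int | None = None,
    use_kernel: bool = True,
):
    """Advance ``state`` by ``n_updates`` time steps, recording per-identity
    mean strengths every ``record_every`` updates (default: never, i.e. one
    record at the end).

    Returns ``(times, mean_strengths)`` where ``times`` includes 0 (the state
    handed in) and ``mean_strengths`` has one length-M row per time.  Uses the
    compiled kernel when available, falling back to the pure-Python loop; both
    paths are bit-identical by contract.
    """
    from .summaries import mean_strengths_by_identity

    if record_every is None:
        record_every = n_updates
    if record_every < 1 or n_updates < 0:
        raise ValueError("record_every must be >= 1 and n_updates >= 0")

    M = params.M
    n_rec = n_updates // record_every
    times = np.concatenate(
        [[0], (np.arange(1, n_rec + 1) * record_every)]
    ).astype(np.int64)
    means = np.empty((n_rec + 1, M), dtype=np.float64)
    means[0] = mean_strengths_by_identity(state, M).mean_strengths

    if use_kernel:
        from ._kernel import HAVE_NUMBA, run_kernel

        if HAVE_NUMBA:
            run_kernel(state, params, n_updates, record_every, means)
            return times, means

    rec = 1
    for t in range(1, n_updates + 1):
        single_update(state, params)
        if t % record_every == 0:
            means[rec] = mean_strengths_by_identity(state, M).mean_strengths
            rec += 1
    return times, means
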