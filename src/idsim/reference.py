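"""Naive reference implementation of one update step (the test oracle).

A deliberately plain transcription of the dynamics — brute-force neighbor
search, explicit scans, no caching, no vectorization — that shares the
splitmix64 draw-order contract with :func:`idsim.model.single_update` and the
compiled kernel.  The equivalence tests demand bit-identical trajectories
between this loop and the optimized paths; keep it slow and obvious.
"""

from __future__ import annotations

from .model import PopulationState
from .params import ModelParams


def _brute_force_neighbor_sites(pos: int, n_loc: int, N: int) -> list[int]:
    """All sites ranked by ring distance (clockwise first at ties), first
    n_loc taken, returned ascending."""
    ranked = []
    for s in range(N):
        if s == pos:
            continue
        off = (s - pos) % N
        dist = min(off, N - off)
        clockwise_penalty = 0 if off == dist else 1
        ranked.append((dist, clockwise_penalty, s))
    ranked.sort()
    return sorted(s for _, _, s in ranked[:n_loc])


def reference_single_update(state: PopulationState, params: ModelParams) -> PopulationState:
    """One time step, computed the slow way. Mutates and returns ``state``."""
    rng = state.rng
    N = params.N

    focal = rng.randbelow(N)
    fpos = int(state.pos_of_agent[focal])
    kf = int(state.identities[focal])
    wf = float(state.strengths[focal])

    sites = _brute_force_neighbor_sites(fpos, params.n_loc, N)
    local_agents = [int(state.agent_at_site[s]) for s in sites]

    global_agents: list[int] = []
    if params.n_glob > 0:
        pool = [
            j
            for j in range(N)
            if int(state.identities[j]) == kf
            and j != focal
            and j not in local_agents
        ]
        P = len(pool)
        k = min(params.n_glob, P)
        for t in range(k):
            j = t + rng.randbelow(P - t)
            pool[t], pool[j] = pool[j], pool[t]
        global_agents = pool[:k]

    u = 0.0
    for j in local_agents:
        sign = 1.0 if int(state.identities[j]) == kf else -1.0
        u += wf * float(state.strengths[j]) * sign
    for j in global_agents:
        u += wf * float(state.strengths[j]) * 1.0

    w = wf + params.d * u * (1.0 - wf)
    w = min(max(w, params.w_min), params.w_max)

    if rng.next_double() < params.p_expl:
        u2 = rng.next_double()
        w = w + (1.0 - w) * (params.c_expl * (2.0 * u2 - 1.0))
        w = min(max(w, params.w_min), params.w_max)
    state.strengths[focal] = w

    mu = N * params.epsilon / 2.0
    n_swaps = int(mu)
    frac = mu - n_swaps
    if frac > 0.0 and rng.next_double() < frac:
        n_swaps += 1
    for _ in range(n_swaps):
        a = rng.randbelow(N)
        b = rng.randbelow(N - 1)
        if b >= a:
            b += 1
        pa, pb = int(state.pos_of_agent[a]), int(state.pos_of_agent[b])
        state.pos_of_agent[a], state.pos_of_agent[b] = pb, pa
        state.agent_at_site[pa], state.agent_at_site[pb] = b, a
    return state
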