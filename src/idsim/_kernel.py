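"""Compiled update loop.

This is the optimized execution path: a single numba ``njit`` function that
advances the population by many updates.  It reproduces, bit for bit, the
pure-Python :func:`idsim.model.single_update` (and the naive reference in
:mod:`idsim.reference`): identical splitmix64 state transitions, identical
draw order, identical floating-point expression and summation order.  Any
change here must keep that equivalence — it is enforced by the oracle tests.

If numba is unavailable the caller falls back to the Python loop
(``HAVE_NUMBA`` is False); results are identical either way, only slower.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S32 = np.uint64(32)
_S11 = np.uint64(11)
_INV53 = 2.0**-53


@njit(inline="always", cache=True)
def _next_u64(state):
    state = state + _GOLDEN
    z = state
    z = (z ^ (z >> _S30)) * _MIX1
    z = (z ^ (z >> _S27)) * _MIX2
    z = z ^ (z >> _S31)
    return state, z


@njit(inline="always", cache=True)
def _randbelow(z, n):
    # multiply-shift reduction of the top 32 bits; mirrors SplitMix64.randbelow
    return np.int64(((z >> _S32) * np.uint64(n)) >> _S32)


@njit(cache=True)
def _run(
    identities,
    strengths,
    pos_of_agent,
    agent_at_site,
    member_flat,
    member_start,
    id_counts,
    N,
    M,
    n_loc,
    n_glob,
    d,
    epsilon,
    p_expl,
    c_expl,
    w_min,
    w_max,
    rng_state,
    n_updates,
    record_every,
    means_out,
):
    state = rng_state
    half = n_loc // 2
    mu = N * epsilon / 2.0
    mu_int = int(mu)
    mu_frac = mu - mu_int
    nbr_sites = np.empty(n_loc, np.int64)
    nbr_agents = np.empty(n_loc, np.int64)
    pool = np.empty(N, np.int64)
    rec = 1

    for t in range(1, n_updates + 1):
        # 1. focal agent
        state, z = _next_u64(state)
        focal = _randbelow(z, N)
        fpos = pos_of_agent[focal]
        kf = identities[focal]
        wf = strengths[focal]

        # local neighbors: half sites each side (+1 clockwise if odd),
        # then insertion-sorted ascending to fix the summation order
        for q in range(half):
            nbr_sites[q] = (fpos - (q + 1)) % N
            nbr_sites[half + q] = (fpos + (q + 1)) % N
        if n_loc % 2 == 1:
            nbr_sites[n_loc - 1] = (fpos + half + 1) % N
        for a_ in range(1, n_loc):
            key = nbr_sites[a_]
            b_ = a_ - 1
            while b_ >= 0 and nbr_sites[b_] > key:
                nbr_sites[b_ + 1] = nbr_sites[b_]
                b_ -= 1
            nbr_sites[b_ + 1] = key
        for q in range(n_loc):
            nbr_agents[q] = agent_at_site[nbr_sites[q]]

        # 2. global same-identity partners (partial Fisher-Yates over pool)
        k_sel = 0
        if n_glob > 0:
            P = 0
            for idx in range(member_start[kf], member_start[kf + 1]):
                j = member_flat[idx]
                if j == focal:
                    continue
                is_nbr = False
                for q in range(n_loc):
                    if nbr_agents[q] == j:
                        is_nbr = True
                        break
                if not is_nbr:
                    pool[P] = j
                    P += 1
            k_sel = min(n_glob, P)
            for ts in range(k_sel):
                state, z = _next_u64(state)
                j = ts + _randbelow(z, P - ts)
                tmp = pool[ts]
                pool[ts] = pool[j]
                pool[j] = tmp

        # 3. utility: locals in ascending site order, then selected globals
        u = 0.0
        for q in range(n_loc):
            j = nbr_agents[q]
            if identities[j] == kf:
                u += wf * strengths[j] * 1.0
            else:
                u += wf * strengths[j] * -1.0
        for q in range(k_sel):
            j = pool[q]
            u += wf * strengths[j] * 1.0

        # 4. reinforcement update with hard clamping
        w = wf + d * u * (1.0 - wf)
        if w < w_min:
            w = w_min
        elif w > w_max:
            w = w_max

        # 5. exploration
        state, z = _next_u64(state)
        if np.float64(z >> _S11) * _INV53 < p_expl:
            state, z = _next_u64(state)
            u2 = np.float64(z >> _S11) * _INV53
            w = w + (1.0 - w) * (c_expl * (2.0 * u2 - 1.0))
            if w < w_min:
                w = w_min
            elif w > w_max:
                w = w_max
        strengths[focal] = w

        # 6. migration: mu = N*epsilon/2 expected pair swaps per update
        n_swaps = mu_int
        if mu_frac > 0.0:
            state, z = _next_u64(state)
            if np.float64(z >> _S11) * _INV53 < mu_frac:
                n_swaps += 1
        for sw in range(n_swaps):
            state, z = _next_u64(state)
            a = _randbelow(z, N)
            state, z = _next_u64(state)
            b = _randbelow(z, N - 1)
            if b >= a:
                b += 1
            pa = pos_of_agent[a]
            pb = pos_of_agent[b]
            pos_of_agent[a] = pb
            pos_of_agent[b] = pa
            agent_at_site[pa] = b
            agent_at_site[pb] = a

        if t % record_every == 0:
            for m in range(M):
                means_out[rec, m] = 0.0
            for i in range(N):
                means_out[rec, identities[i]] += strengths[i]
            for m in range(M):
                means_out[rec, m] /= id_counts[m]
            rec += 1

    return state


def run_kernel(state, params, n_updates, record_every, means_out):
    """Advance ``state`` in place via the compiled loop; fills ``means_out``
    rows 1.. with per-identity means at each record point."""
    M = params.M
    members = [state.members_of(m) for m in range(M)]
    member_flat = np.concatenate(members).astype(np.int64)
    member_start = np.zeros(M + 1, dtype=np.int64)
    member_start[1:] = np.cumsum([len(m) for m in members])
    id_counts = np.array([len(m) for m in members], dtype=np.float64)

    new_state = _run(
        state.identities,
        state.strengths,
        state.pos_of_agent,
        state.agent_at_site,
        member_flat,
        member_start,
        id_counts,
        params.N,
        M,
        params.n_loc,
        params.n_glob,
        params.d,
        params.epsilon,
        params.p_expl,
        params.c_expl,
        params.w_min,
        params.w_max,
        np.uint64(state.rng.state),
        n_updates,
        record_every,
        means_out,
    )
    state.rng.state = int(new_state)
    return state
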