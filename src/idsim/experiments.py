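"""Experiment protocols: transition run, regime sweep, hysteresis, sensitivity.

All protocols are Monte-Carlo experiments over independent replicates.
Replicate ``r`` of an experiment runs with seed ``base_seed + r``; its result
depends on that seed only, never on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .model import init_population, run_updates
from .params import ModelParams
from .summaries import mean_strengths_by_identity, rank_sort

logger = logging.getLogger("idsim")

__all__ = [
    "RunSpec",
    "Trajectory",
    "SweepResult",
    "HysteresisResult",
    "transition_run",
    "regime_sweep",
    "hysteresis_protocol",
    "sensitivity_sweep",
    "hysteresis_area",
]


@dataclass(frozen=True)
class RunSpec:
    """Experiment configuration: model parameters plus run management.

    ``record_every`` defaults to N updates (one expected sweep through the
    population); set it to 1 to record after every individual update.
    """

    params: ModelParams = field(default_factory=ModelParams)
    total_updates: int = 50_000
    record_every: int | None = None
    replicates: int = 1
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.total_updates < 1:
            raise ValueError("total_updates must be >= 1")
        if self.record_every is not None and self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def cadence(self) -> int:
        return self.record_every if self.record_every is not None else self.params.N


@dataclass(frozen=True)
class Trajectory:
    """Time series of per-identity mean strengths from a single run."""

    times: np.ndarray           # (R,) recorded update indices, starts at 0
    mean_strengths: np.ndarray  # (R, M)
    params: ModelParams


@dataclass(frozen=True)
class SweepResult:
    """Rank-sorted, replicate-averaged final strengths per n_glob value."""

    n_glob_values: np.ndarray            # (G,)
    rank_sorted_strengths: np.ndarray    # (G, M), each row non-increasing
    replicates: int


@dataclass(frozen=True)
class HysteresisResult:
    """Up-branch and down-branch sweeps from one continuous protocol."""

    up_branch: SweepResult      # n_glob = 0 .. g_max
    down_branch: SweepResult    # n_glob = g_max .. 0
    stage_updates: int


def _seed_params(spec: RunSpec, replicate: int, **overrides) -> ModelParams:
    return replace(spec.params, seed=spec.base_seed + replicate, **overrides)


def transition_run(spec: RunSpec, replicate: int = 0) -> Trajectory:
    """One run from the balanced w_min initial state, recording the four
    identity means over time (the single-run 'transition to dominance'
    protocol; baseline n_loc=5, n_glob=3, N=200, 50,000 updates)."""
    params = _seed_params(spec, replicate)
    state = init_population(params)
    times, means = run_updates(state, params, spec.total_updates, spec.cadence)
    return Trajectory(times, means, params)


def _final_means(params: ModelParams, total_updates: int) -> np.ndarray:
    state = init_population(params)
    run_updates(state, params, total_updates)
    return mean_strengths_by_identity(state, params.M).mean_strengths


def regime_sweep(
    spec: RunSpec,
    n_glob_values=range(9),
    total_connections: int = 8,
) -> SweepResult:
    """Fresh-start sweep over the number of global connections.

    For each ``n_glob`` the local count is ``total_connections - n_glob``;
    every (n_glob, replicate) cell starts anew from the balanced initial
    state, runs ``total_updates`` steps, and reports final per-identity means
    sorted descending, averaged rank-wise over replicates.
    """
    n_glob_values = np.asarray(list(n_glob_values), dtype=np.int64)
    out = np.empty((len(n_glob_values), spec.params.M), dtype=np.float64)
    for gi, g in enumerate(n_glob_values):
        finals = []
        for r in range(spec.replicates):
            params = _seed_params(
                spec, r, n_glob=int(g), n_loc=total_connections - int(g)
            )
            finals.append(_final_means(params, spec.total_updates))
        out[gi] = rank_sort(finals)
        logger.info("sweep n_glob=%d done (%d replicates)", g, spec.replicates)
    return SweepResult(n_glob_values, out, spec.replicates)


def hysteresis_protocol(
    spec: RunSpec,
    g_max: int = 8,
    total_connections: int = 8,
) -> HysteresisResult:
    """Stepwise up/down protocol within one continuous history per replicate.

    Starting from the balanced initial state at ``n_glob = 0``, run one stage
    of ``total_updates`` steps, record sorted means, increment ``n_glob`` by
    one (keeping ``n_loc + n_glob`` constant) *without* resetting the
    population, and repeat up to ``g_max``; then step back down to 0.  The
    up branch holds the stage-end values for n_glob = 0..g_max; the down
    branch those for g_max..0 (the g_max entry is shared — it is the turning
    point, not re-run).
    """
    ups = np.arange(g_max + 1)
    downs = np.arange(g_max, -1, -1)
    up_finals = [[] for _ in ups]
    down_finals = [[] for _ in downs]

    for r in range(spec.replicates):
        params = _seed_params(spec, r, n_glob=0, n_loc=total_connections)
        state = init_population(params)
        stage_sorted = {}
        for g in ups:
            params = replace(
                params, n_glob=int(g), n_loc=total_connections - int(g)
            )
            run_updates(state, params, spec.total_updates)
            means = mean_strengths_by_identity(state, params.M).mean_strengths
            stage_sorted[("up", int(g))] = np.sort(means)[::-1]
        for g in downs:
            if g == g_max:
                stage_sorted[("down", int(g))] = stage_sorted[("up", int(g))]
                continue
            params = replace(
                params, n_glob=int(g), n_loc=total_connections - int(g)
            )
            run_updates(state, params, spec.total_updates)
            means = mean_strengths_by_identity(state, params.M).mean_strengths
            stage_sorted[("down", int(g))] = np.sort(means)[::-1]
        for gi, g in enumerate(ups):
            up_finals[gi].append(stage_sorted[("up", int(g))])
        for gi, g in enumerate(downs):
            down_finals[gi].append(stage_sorted[("down", int(g))])
        logger.info("hysteresis replicate %d/%d done", r + 1, spec.replicates)

    up = SweepResult(
        ups.astype(np.int64),
        np.vstack([np.mean(f, axis=0) for f in up_finals]),
        spec.replicates,
    )
    down = SweepResult(
        downs.astype(np.int64),
        np.vstack([np.mean(f, axis=0) for f in down_finals]),
        spec.replicates,
    )
    return HysteresisResult(up, down, spec.total_updates)


def hysteresis_area(result: HysteresisResult, rank: int = 0) -> float:
    """Down-branch minus up-branch strength at the given rank, summed over
    the n_glob grid.  A strictly positive rank-0 area is the quantitative
    signature of hysteresis (the branch gap the protocol plots visually)."""
    up = result.up_branch
    down = result.down_branch
    down_aligned = down.rank_sorted_strengths[::-1]  # reorder to 0..g_max
    return float(np.sum(down_aligned[:, rank] - up.rank_sorted_strengths[:, rank]))


def sensitivity_sweep(spec: RunSpec, epsilon_values=(0.02, 0.005)) -> dict:
    """Hysteresis protocol per migration rate, matched seeds across rates.

    Lower migration leaves locally fixated clusters in place, so the
    hysteresis loop is expected to shrink as epsilon drops.
    """
    results = {}
    for eps in epsilon_values:
        eps_spec = replace(spec, params=replace(spec.params, epsilon=float(eps)))
        results[float(eps)] = hysteresis_protocol(eps_spec)
        logger.info("sensitivity epsilon=%g done", eps)
    return results
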