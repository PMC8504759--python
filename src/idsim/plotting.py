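"""Figures mirroring the three experiment protocols."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_STYLES = ["-", "--", "-.", ":"]


def plot_trajectory(traj, ax=None):
    """Per-identity mean strength vs. time, identities in order of final
    dominance (full to dotted lines)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    order = np.argsort(traj.mean_strengths[-1])[::-1]
    for rank, m in enumerate(order):
        ax.plot(
            traj.times,
            traj.mean_strengths[:, m],
            _STYLES[rank % len(_STYLES)],
            color="k",
            label=f"rank {rank + 1}",
        )
    ax.set_xlabel("learning updates")
    ax.set_ylabel("mean identity strength")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    return ax.figure


def plot_sweep(result, ax=None):
    """Rank-sorted, replicate-averaged final strengths vs. n_glob."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    M = result.rank_sorted_strengths.shape[1]
    for rank in range(M):
        ax.plot(
            result.n_glob_values,
            result.rank_sorted_strengths[:, rank],
            _STYLES[rank % len(_STYLES)],
            color="k",
            marker="o",
            label=f"rank {rank + 1}",
        )
    ax.set_xlabel("global connections $n_{glob}$")
    ax.set_ylabel("mean identity strength")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    return ax.figure


def plot_hysteresis(result, axes=None):
    """One panel per rank: up branch (full) vs. down branch (dashed)."""
    M = result.up_branch.rank_sorted_strengths.shape[1]
    if axes is None:
        _, axes = plt.subplots(1, M, figsize=(3 * M, 3), sharey=True)
    down_order = np.argsort(result.down_branch.n_glob_values)
    for rank, ax in enumerate(np.atleast_1d(axes)):
        ax.plot(
            result.up_branch.n_glob_values,
            result.up_branch.rank_sorted_strengths[:, rank],
            "-",
            color="k",
            label="up",
        )
        ax.plot(
            result.down_branch.n_glob_values[down_order],
            result.down_branch.rank_sorted_strengths[down_order, rank],
            "--",
            color="k",
            label="down",
        )
        ax.set_title(f"rank {rank + 1}")
        ax.set_xlabel("$n_{glob}$")
        ax.set_ylim(0, 1)
    np.atleast_1d(axes)[0].set_ylabel("mean identity strength")
    np.atleast_1d(axes)[0].legend(frameon=False)
    return np.atleast_1d(axes)[0].figure
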