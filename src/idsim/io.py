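"""Result writers and readers (CSV + JSON sidecar).

Every experiment writes a tidy CSV and a JSON sidecar holding the fully
resolved configuration; reading a written file reproduces the in-memory
result exactly (floats round-trip via shortest-repr formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiments import HysteresisResult, SweepResult, Trajectory
from .params import ModelParams


def write_sidecar(config: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# -- trajectory -------------------------------------------------------------

def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Long format: one row per (time, identity)."""
    M = traj.mean_strengths.shape[1]
    return pd.DataFrame(
        {
            "time": np.repeat(traj.times, M),
            "identity": np.tile(np.arange(M), len(traj.times)),
            "mean_strength": traj.mean_strengths.ravel(),
        }
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    trajectory_frame(traj).to_csv(path, index=False)


def read_trajectory(path: str | Path, params: ModelParams | None = None) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    times = df["time"].unique().astype(np.int64)
    M = df["identity"].nunique()
    means = df["mean_strength"].to_numpy().reshape(len(times), M)
    return Trajectory(times, means, params)


# -- sweep ------------------------------------------------------------------

def sweep_frame(result: SweepResult) -> pd.DataFrame:
    """Long format: one row per (n_glob, rank); rank 1 is the most dominant."""
    G, M = result.rank_sorted_strengths.shape
    return pd.DataFrame(
        {
            "n_glob": np.repeat(result.n_glob_values, M),
            "rank": np.tile(np.arange(1, M + 1), G),
            "mean_strength": result.rank_sorted_strengths.ravel(),
            "replicates": result.replicates,
        }
    )


def write_sweep(result: SweepResult, path: str | Path) -> None:
    sweep_frame(result).to_csv(path, index=False)


def read_sweep(path: str | Path) -> SweepResult:
    df = pd.read_csv(path, float_precision="round_trip")
    n_glob_values = df["n_glob"].unique().astype(np.int64)
    M = df["rank"].nunique()
    strengths = df["mean_strength"].to_numpy().reshape(len(n_glob_values), M)
    return SweepResult(n_glob_values, strengths, int(df["replicates"].iloc[0]))


# -- hysteresis -------------------------------------------------------------

def hysteresis_frame(result: HysteresisResult) -> pd.DataFrame:
    up = sweep_frame(result.up_branch).assign(branch="up")
    down = sweep_frame(result.down_branch).assign(branch="down")
    df = pd.concat([up, down], ignore_index=True)
    df["stage_updates"] = result.stage_updates
    return df[["branch", "n_glob", "rank", "mean_strength", "replicates", "stage_updates"]]


def write_hysteresis(result: HysteresisResult, path: str | Path) -> None:
    hysteresis_frame(result).to_csv(path, index=False)


def read_hysteresis(path: str | Path) -> HysteresisResult:
    df = pd.read_csv(path, float_precision="round_trip")

    def branch(name: str) -> SweepResult:
        sub = df[df["branch"] == name]
        n_glob_values = sub["n_glob"].unique().astype(np.int64)
        M = sub["rank"].nunique()
        strengths = sub["mean_strength"].to_numpy().reshape(len(n_glob_values), M)
        return SweepResult(n_glob_values, strengths, int(sub["replicates"].iloc[0]))

    return HysteresisResult(branch("up"), branch("down"), int(df["stage_updates"].iloc[0]))
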