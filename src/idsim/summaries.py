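"""Order parameters: per-identity means, rank sorting, dominance counts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class IdentitySummary:
    """Per-identity snapshot of a population.

    ``rank_order[r]`` is the identity label with the r-th largest mean
    strength (ties broken by ascending label, for determinism; ties have
    measure zero under exploration noise).
    """

    mean_strengths: np.ndarray  # (M,)
    counts: np.ndarray          # (M,) holders per identity
    rank_order: np.ndarray      # (M,) labels by descending mean strength


def mean_strengths_by_identity(state, M: int) -> IdentitySummary:
    """Arithmetic mean of w over the holders of each identity label.

    Positions do not enter: the summary commutes with migration.  An identity
    with zero holders is reported as NaN (cannot occur under balanced
    initialization with immutable labels).
    """
    if int(state.identities.max()) >= M:
        raise ValueError("state contains identity labels >= M")
    counts = np.bincount(state.identities, minlength=M).astype(np.int64)
    sums = np.bincount(state.identities, weights=state.strengths, minlength=M)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    # descending mean, ascending label at ties: sort on (-mean, label)
    order = np.lexsort((np.arange(M), -means))
    return IdentitySummary(means, counts, order.astype(np.int64))


def rank_sort(mean_vectors) -> np.ndarray:
    """Rank-wise average of per-replicate mean-strength vectors.

    Each replicate's vector is sorted descending ("order of dominance" within
    that run), then the sorted vectors are averaged position-wise.  This is
    NOT the sort of the averaged vectors: dominance is a per-run notion, and
    which label dominates varies across replicates.
    """
    arr = np.asarray(list(mean_vectors), dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one replicate vector, all of equal M")
    return np.sort(arr, axis=1)[:, ::-1].mean(axis=0)


def dominance_count(rank_averaged: np.ndarray, threshold: float) -> int:
    """Number of rank positions whose averaged strength exceeds ``threshold``."""
    return int(np.sum(np.asarray(rank_averaged) > threshold))
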