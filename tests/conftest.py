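import numpy as np
import pytest

from idsim import ModelParams, PopulationState, SplitMix64


@pytest.fixture
def paper_params():
    """Baseline parameters: N=200, M=4, n_loc=5, n_glob=3."""
    return ModelParams(seed=7)


@pytest.fixture
def small_params():
    """A small, fast configuration for property checks."""
    return ModelParams(N=24, M=3, n_loc=4, n_glob=2, seed=5)


def make_state(identities, positions=None, strengths=None, seed=0,
               w_min=0.05) -> PopulationState:
    """Hand-built population state for targeted scenarios."""
    identities = np.asarray(identities, dtype=np.int64)
    N = len(identities)
    pos = (np.arange(N, dtype=np.int64) if positions is None
           else np.asarray(positions, dtype=np.int64))
    w = (np.full(N, w_min) if strengths is None
         else np.asarray(strengths, dtype=np.float64))
    site = np.empty(N, dtype=np.int64)
    site[pos] = np.arange(N)
    return PopulationState(identities, w, pos, site, SplitMix64(seed))
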