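"""Model parameters and their validity constraints."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class ModelParams:
    """All scalar parameters of the identity-strength dynamics.

    Defaults are the baseline configuration of the model study: a ring of
    ``N=200`` agents split evenly over ``M=4`` identities, eight interaction
    partners per update (``n_loc + n_glob = 8``), learning rate ``d=0.5``,
    migration probability ``epsilon=0.02`` per update, strength exploration
    with probability ``p_expl=0.2`` and half-width ``c_expl=0.05``, and
    strengths confined to ``[w_min, w_max] = [0.05, 0.95]`` (open bounds 0/1
    would allow fixation: zero-strength or infinitely strong identities).

    Attributes
    ----------
    N : int
        Number of agents (= ring-lattice sites).
    M : int
        Number of identity labels; labels are fixed per agent for a whole run.
    n_loc : int
        Lattice neighbors each focal agent interacts with (constrained ties).
    n_glob : int
        Globally sampled same-identity partners (chosen ties).
    d : float
        Learning-rate constant of the reinforcement update.
    epsilon : float
        Per-agent migration probability per time step; executed as an
        expected ``N * epsilon / 2`` random pair swaps per update.
    p_expl : float
        Per-update probability of an explorative strength perturbation.
    c_expl : float
        Half-width of the uniform exploration variate.
    w_min, w_max : float
        Hard bounds on the scaled identity strength.
    seed : int
        Seed of the run's random stream.
    """

    N: int = 200
    M: int = 4
    n_loc: int = 5
    n_glob: int = 3
    d: float = 0.5
    epsilon: float = 0.02
    p_expl: float = 0.2
    c_expl: float = 0.05
    w_min: float = 0.05
    w_max: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.N >= 2, "N", "N must be >= 2"),
            (self.M >= 1, "M", "M must be >= 1"),
            (self.n_loc >= 0, "n_loc", "n_loc must be >= 0"),
            (self.n_glob >= 0, "n_glob", "n_glob must be >= 0"),
            (self.n_loc + self.n_glob >= 1, "n_loc",
             "n_loc + n_glob must be >= 1"),
            (self.n_loc < self.N, "n_loc", "n_loc must be < N"),
            (0.0 <= self.epsilon <= 1.0, "epsilon",
             "epsilon must be in [0, 1]"),
            (0.0 <= self.p_expl <= 1.0, "p_expl", "p_expl must be in [0, 1]"),
            (self.c_expl >= 0.0, "c_expl", "c_expl must be >= 0"),
            (self.d >= 0.0, "d", "d must be >= 0"),
            (0.0 < self.w_min < self.w_max < 1.0, "w_min",
             "bounds must satisfy 0 < w_min < w_max < 1"),
            (self.seed >= 0, "seed", "seed must be >= 0"),
        ]
        for ok, name, msg in checks:
            if not ok:
                raise ValueError(f"invalid ModelParams.{name}: {msg}")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
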