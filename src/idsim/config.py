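"""Configuration loading and resolution.

Precedence: CLI overrides > config file > baseline defaults.  The resolved
configuration is serialized verbatim into every output's JSON sidecar, so any
result can be regenerated from its sidecar alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .experiments import RunSpec
from .params import ModelParams


class ConfigError(ValueError):
    """Unknown key or invalid value in a configuration source."""


#: baseline values; n_loc/n_glob left unset so the total-connections
#: constraint can resolve whichever of the two the user supplies
_DEFAULTS = {
    "N": 200,
    "M": 4,
    "n_loc": None,
    "n_glob": None,
    "total_connections": 8,
    "d": 0.5,
    "epsilon": 0.02,
    "p_expl": 0.2,
    "c_expl": 0.05,
    "w_min": 0.05,
    "w_max": 0.95,
    "total_updates": 50_000,
    "record_every": None,
    "replicates": 1,
    "seed": 0,
}

_MODEL_KEYS = (
    "N", "M", "n_loc", "n_glob", "d", "epsilon",
    "p_expl", "c_expl", "w_min", "w_max",
)


@dataclass(frozen=True)
class ResolvedConfig:
    """Fully resolved parameter set (no missing keys)."""

    N: int
    M: int
    n_loc: int
    n_glob: int
    total_connections: int
    d: float
    epsilon: float
    p_expl: float
    c_expl: float
    w_min: float
    w_max: float
    total_updates: int
    record_every: int | None
    replicates: int
    seed: int

    def model_params(self) -> ModelParams:
        kwargs = {k: getattr(self, k) for k in _MODEL_KEYS}
        kwargs["seed"] = self.seed
        return ModelParams(**kwargs)

    def run_spec(self) -> RunSpec:
        return RunSpec(
            params=self.model_params(),
            total_updates=self.total_updates,
            record_every=self.record_every,
            replicates=self.replicates,
            base_seed=self.seed,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ResolvedConfig:
    """Merge defaults, an optional YAML/JSON file, and override values.

    Unknown keys in either source raise :class:`ConfigError` naming the key;
    invalid values raise ``ValueError`` naming the field (via
    :class:`~idsim.params.ModelParams` validation).

    When only one of ``n_loc`` / ``n_glob`` is given, the other resolves from
    the ``total_connections`` constraint (baseline: 8 ties per agent).  When
    neither is given, the baseline split n_loc=5 / n_glob=3 applies.
    """
    merged = dict(_DEFAULTS)
    for source_name, source in (
        ("config file", _read_file(path)),
        ("override", overrides or {}),
    ):
        for key, value in source.items():
            if key not in _DEFAULTS:
                raise ConfigError(f"unknown {source_name} key: {key!r}")
            if value is not None:
                merged[key] = value

    total = merged["total_connections"]
    if merged["n_loc"] is None and merged["n_glob"] is None:
        merged["n_glob"] = 3
        merged["n_loc"] = total - 3
    elif merged["n_loc"] is None:
        merged["n_loc"] = total - merged["n_glob"]
    elif merged["n_glob"] is None:
        merged["n_glob"] = total - merged["n_loc"]

    cfg = ResolvedConfig(**merged)
    cfg.model_params()  # trigger field-naming validation
    if cfg.total_updates < 1:
        raise ConfigError("invalid value for total_updates: must be >= 1")
    if cfg.replicates < 1:
        raise ConfigError("invalid value for replicates: must be >= 1")
    if cfg.record_every is not None and cfg.record_every < 1:
        raise ConfigError("invalid value for record_every: must be >= 1")
    return cfg


def _read_file(path: str | Path | None) -> dict:
    if path is None:
        return {}
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return data
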