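"""Default configuration values and YAML config loading.

Every numeric convention that the analysis depends on (prior bounds, noise
s.d., likelihood domains, ladder shape, iteration counts) lives here so that
it can be overridden from a YAML file without touching code.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Dict, Optional, Sequence, Tuple

import yaml

#: Uniform prior bounds per free parameter.  Affinities are log10 values.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "K": (-4.0, 0.0),
    "K1": (-4.0, 0.0),
    "K2": (-4.0, 0.0),
    "K3": (-4.0, 0.0),
    "Co": (1.0, 10.0),
    "Ns": (1.0, 10.0),  # integer-valued; bounds inclusive
    "alpha": (0.01, 10.0),
    "D": (0.0, 1.0),
}

#: Observation noise s.d. (concentration units); 10% of the fixed maximum 50.
DEFAULT_SIGMA = 5.0

#: Fixed maximum concentration, shared by every model variant.
MAX_CONCENTRATION = 50.0

#: Per-gene likelihood trust domains in % egg length (inclusive ends).
DEFAULT_DOMAINS: Dict[str, Tuple[float, float]] = {
    "Hb": (30.0, 70.0),
    "Kni": (40.0, 90.0),
    "Kr": (20.0, 80.0),
    "Gt": (10.0, 90.0),
}

DEFAULT_GRID_POINTS = 100
DEFAULT_LADDER_SIZE = 10
DEFAULT_LADDER_EXPONENT = 5.0
DEFAULT_N_RUNS = 10
DEFAULT_BURN_IN_FRACTION = 0.5
DEFAULT_PROPOSAL_VARIANCE = 0.1
DEFAULT_DISCRETE_PROBABILITY = 0.1
DEFAULT_N_POSTERIOR_SAMPLES = 100


@dataclass
class RunConfig:
    """Aggregated settings for an end-to-end run (simulate/fit/compare/cv)."""

    models: Sequence[str] = ("A6", "B7", "B7r", "C8", "D7", "D8")
    n_grid: int = DEFAULT_GRID_POINTS
    ladder_size: int = DEFAULT_LADDER_SIZE
    ladder_exponent: float = DEFAULT_LADDER_EXPONENT
    iterations: int = 2000
    burn_in_fraction: float = DEFAULT_BURN_IN_FRACTION
    n_runs: int = DEFAULT_N_RUNS
    sigma: float = DEFAULT_SIGMA
    bounds: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    domains: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAINS)
    )
    seed: int = 0
    outdir: str = "gapnet_out"
    dt: Optional[float] = None
    t_final: float = 1.0
    tie_synthesis_decay: bool = True
    n_posterior_samples: int = DEFAULT_N_POSTERIOR_SAMPLES

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw: Dict[str, Any] = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.bounds = {k: tuple(v) for k, v in cfg.bounds.items()}
        cfg.domains = {k: tuple(v) for k, v in cfg.domains.items()}
        return cfg

    def to_dict(self) -> Dict[str, Any]:
        d = asdict(self)
        d["models"] = list(self.models)
        return d
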