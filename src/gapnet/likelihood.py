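"""Gaussian iid observation model on per-gene trust domains, priors, and the
tempered posterior kernel.

The observed profile of each gap gene is the solver output at the final time
plus iid N(0, sigma^2) noise, evaluated only inside a per-gene interval of the
embryo (the domain mask).  Priors are bounded uniform on every free parameter,
with the site count Ns uniform on an integer range.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import model_spec as ms
from .config import (
    DEFAULT_BOUNDS,
    DEFAULT_DISCRETE_PROBABILITY,
    DEFAULT_DOMAINS,
    DEFAULT_PROPOSAL_VARIANCE,
    DEFAULT_SIGMA,
)
from .model_spec import GAP_GENES, ModelSpec, ParameterSet, pack, unpack
from .sampling import propose_mixed
from .solver import SolverInstabilityError, SpatialGrid, solve


@dataclass(frozen=True)
class DomainMask:
    """Per-gene trust interval in % egg length; ends inclusive."""

    intervals: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAINS)
    )

    def __post_init__(self) -> None:
        for gene, (lo, hi) in self.intervals.items():
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"domain for {gene} outside [0, 100]: {(lo, hi)}")

    def indices(self, grid: SpatialGrid) -> Dict[str, np.ndarray]:
        pos = grid.positions_percent
        out = {}
        for gene, (lo, hi) in self.intervals.items():
            idx = np.nonzero((pos >= lo) & (pos <= hi))[0]
            if idx.size == 0:
                raise ValueError(f"empty domain for {gene}")
            out[gene] = idx
        return out


@dataclass
class Observation:
    """Observed gap-gene profiles on the model grid."""

    Y: Mapping[str, np.ndarray]
    sigma: float = DEFAULT_SIGMA


def gaussian_log_density(residuals: np.ndarray, sigma: float) -> float:
    """Sum of iid N(0, sigma^2) log densities over all residuals."""
    r = np.asarray(residuals, dtype=float)
    n = r.size
    return -0.5 * n * math.log(2.0 * math.pi * sigma**2) - float(
        np.sum(r**2)
    ) / (2.0 * sigma**2)


def masked_log_likelihood(
    model_profiles: Mapping[str, np.ndarray],
    Y: Observation,
    mask_indices: Mapping[str, np.ndarray],
) -> float:
    total = 0.0
    for gene in sorted(mask_indices):
        idx = mask_indices[gene]
        resid = np.asarray(Y.Y[gene])[idx] - np.asarray(model_profiles[gene])[idx]
        total += gaussian_log_density(resid, Y.sigma)
    return total


def log_likelihood(
    theta: ParameterSet,
    Y: Observation,
    spec: ModelSpec,
    grid: SpatialGrid,
    mask: DomainMask,
    static_inputs: Mapping[str, np.ndarray],
    initial: Mapping[str, np.ndarray],
    t_final: float = 1.0,
    dt: Optional[float] = None,
) -> float:
    """Gaussian log likelihood of the solver output; -inf on solver failure."""
    try:
        profiles = solve(static_inputs, initial, spec, theta, grid,
                         t_final=t_final, dt=dt)
    except SolverInstabilityError:
        return -math.inf
    return masked_log_likelihood(profiles, Y, mask.indices(grid))


def log_prior_vector(
    x: np.ndarray,
    spec: ModelSpec,
    bounds: Mapping[str, Tuple[float, float]],
) -> float:
    """Bounded-uniform log prior on the packed free-parameter vector.

    Continuous parameters contribute -log(width); Ns contributes
    -log(number of admissible integers) and must be integer-valued in range.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(spec.free_params),):
        raise ValueError("parameter vector length mismatch")
    total = 0.0
    for name, v in zip(spec.free_params, x):
        lo, hi = bounds[name if name != "beta" else "alpha"]
        if name == "Ns":
            if abs(v - round(v)) > 1e-9:
                return -math.inf
            n_lo, n_hi = int(math.ceil(lo)), int(math.floor(hi))
            if not (n_lo <= round(v) <= n_hi):
                return -math.inf
            total -= math.log(n_hi - n_lo + 1)
        else:
            if not (lo <= v <= hi):
                return -math.inf
            total -= math.log(hi - lo)
    return total


def log_prior(theta: ParameterSet, spec: ModelSpec) -> float:
    return log_prior_vector(pack(theta, spec), spec, theta.bounds)


def sample_prior_vector(
    spec: ModelSpec,
    bounds: Mapping[str, Tuple[float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    out = np.empty(len(spec.free_params))
    for i, name in enumerate(spec.free_params):
        lo, hi = bounds[name if name != "beta" else "alpha"]
        if name == "Ns":
            n_lo, n_hi = int(math.ceil(lo)), int(math.floor(hi))
            out[i] = float(rng.integers(n_lo, n_hi + 1))
        else:
            out[i] = rng.uniform(lo, hi)
    return out


def log_posterior_at_temperature(
    theta: ParameterSet,
    Y: Observation,
    spec: ModelSpec,
    t: float,
    grid: SpatialGrid,
    mask: DomainMask,
    static_inputs: Mapping[str, np.ndarray],
    initial: Mapping[str, np.ndarray],
    t_final: float = 1.0,
    dt: Optional[float] = None,
) -> float:
    """t * log_likelihood + log_prior, the tempered posterior kernel."""
    if not (0.0 <= t <= 1.0):
        raise ValueError("temperature must lie in [0, 1]")
    lp = log_prior(theta, spec)
    if lp == -math.inf:
        return -math.inf
    if t == 0.0:
        return lp
    ll = log_likelihood(theta, Y, spec, grid, mask, static_inputs, initial,
                        t_final=t_final, dt=dt)
    return t * ll + lp


class GapGenePosterior:
    """Sampling target for one model variant on one dataset.

    Bridges packed parameter vectors to the solver-backed likelihood; exposes
    the ``log_likelihood`` / ``log_prior`` / ``sample_prior`` / ``propose``
    surface the samplers expect.
    """

    def __init__(
        self,
        spec: ModelSpec,
        Y: Observation,
        static_inputs: Mapping[str, np.ndarray],
        grid: SpatialGrid,
        initial: Optional[Mapping[str, np.ndarray]] = None,
        mask: Optional[DomainMask] = None,
        bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
        t_final: float = 1.0,
        dt: Optional[float] = None,
        proposal_variance: float = DEFAULT_PROPOSAL_VARIANCE,
        discrete_probability: float = DEFAULT_DISCRETE_PROBABILITY,
        proposal_scales: Optional[Mapping[str, float]] = None,
    ):
        from .solver import default_initial

        self.spec = spec
        self.Y = Y
        self.static_inputs = {k: np.asarray(v, dtype=float)
                              for k, v in static_inputs.items()}
        self.grid = grid
        self.initial = (dict(initial) if initial is not None
                        else default_initial(self.static_inputs, grid))
        self.mask = mask if mask is not None else DomainMask()
        self.mask_indices = self.mask.indices(grid)
        self.bounds = dict(bounds) if bounds is not None else dict(DEFAULT_BOUNDS)
        self.t_final = t_final
        self.dt = dt
        self.proposal_variance = proposal_variance
        self.discrete_probability = discrete_probability
        self.ns_index = (spec.free_params.index("Ns")
                         if "Ns" in spec.free_params else None)
        # optional per-parameter multipliers on the proposal s.d.
        self.scales = None
        if proposal_scales:
            self.scales = np.array(
                [float(proposal_scales.get(n, 1.0)) for n in spec.free_params]
            )
        self.n_unstable = 0

    @property
    def dim(self) -> int:
        return len(self.spec.free_params)

    def to_parameters(self, x: np.ndarray) -> ParameterSet:
        return unpack(x, self.spec, sigma=self.Y.sigma, bounds=self.bounds)

    def solve(self, x: np.ndarray) -> Dict[str, np.ndarray]:
        return solve(self.static_inputs, self.initial, self.spec,
                     self.to_parameters(x), self.grid,
                     t_final=self.t_final, dt=self.dt, max_retries=0)

    def log_likelihood(self, x: np.ndarray) -> float:
        try:
            profiles = self.solve(x)
        except SolverInstabilityError:
            self.n_unstable += 1
            return -math.inf
        return masked_log_likelihood(profiles, self.Y, self.mask_indices)

    def log_prior(self, x: np.ndarray) -> float:
        return log_prior_vector(x, self.spec, self.bounds)

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray:
        return sample_prior_vector(self.spec, self.bounds, rng)

    def propose(
        self, x: np.ndarray, rng: np.random.Generator
    ) -> Tuple[np.ndarray, float]:
        return propose_mixed(
            x,
            rng,
            ns_index=self.ns_index,
            p_discrete=self.discrete_probability,
            variance=self.proposal_variance,
            scales=self.scales,
        )
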