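"""Fractional-occupancy regulatory terms feeding the production rate.

A regulator at concentration ``u`` with log10 affinity ``logKa``, cooperativity
``Co`` and ``Ns`` binding sites occupies its target with probability

    phi = S / (1 + S),    S = sum_{j=1..Ns} C(Ns, j) Co^(j-1) v^j,

where ``v = u * 10**logKa``.  ``S`` is the occupied part of a single-target
partition function with statistical weight ``Co^(j-1) v^j`` for configurations
with ``j`` bound sites; it has the closed form ``((1 + Co v)^Ns - 1) / Co``.

Multiple activators (or repressors) of one target are combined with a
noisy-OR rule: ``P = 1 - prod_r (1 - phi_r)``.  The combination rule is
pluggable (see :func:`regulatory_input`'s ``combine`` argument) because the
occupancy algebra upstream of this module admits variants.

Dual regulation (Hb on Kr) contributes the ordinary occupancy to the
activation side and the fully-bound fraction ``Co^(Ns-1) v^Ns / (1 + S)`` to
the repression side, so low regulator levels activate and saturating levels
repress.
"""
from __future__ import annotations

from typing import Callable, Dict, Mapping, Sequence, Tuple, Union

import numpy as np

from .model_spec import ModelSpec, ParameterSet

ArrayLike = Union[float, np.ndarray]


def _partition_sum(u: ArrayLike, logKa: float, Co: float, Ns: int) -> np.ndarray:
    v = np.asarray(u, dtype=float) * 10.0 ** logKa
    return ((1.0 + Co * v) ** Ns - 1.0) / Co


def site_occupancy(u: ArrayLike, logKa: float, Co: float, Ns: int) -> np.ndarray:
    """Fraction of time the target is occupied by this regulator; in [0, 1].

    Monotone non-decreasing in ``u``, ``Co`` and ``Ns``; 0 at ``u = 0`` and
    approaching 1 as ``u`` grows.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("negative regulator concentration")
    if Ns < 1 or int(Ns) != Ns:
        raise ValueError(f"Ns must be a positive integer, got {Ns}")
    if Co < 1:
        raise ValueError(f"cooperativity must be >= 1, got {Co}")
    S = _partition_sum(u, logKa, Co, int(Ns))
    return S / (1.0 + S)


def saturated_occupancy(
    u: ArrayLike, logKa: float, Co: float, Ns: int
) -> np.ndarray:
    """Probability that *all* Ns sites are bound (the fully-bound term).

    Used as the repressive arm of dual regulation: it stays near zero until
    the regulator saturates its sites.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("negative regulator concentration")
    v = u * 10.0 ** logKa
    S = _partition_sum(u, logKa, Co, int(Ns))
    return (Co ** (Ns - 1)) * v ** Ns / (1.0 + S)


def noisy_or(occupancies: Sequence[np.ndarray]) -> np.ndarray:
    """1 - prod(1 - phi); the empty combination is 0."""
    if len(occupancies) == 0:
        return np.asarray(0.0)
    acc = np.ones_like(np.asarray(occupancies[0], dtype=float))
    for phi in occupancies:
        acc = acc * (1.0 - np.asarray(phi))
    return 1.0 - acc


CombineRule = Callable[[Sequence[np.ndarray]], np.ndarray]


def regulatory_input(
    state: Mapping[str, ArrayLike],
    spec: ModelSpec,
    params: ParameterSet,
    target: str,
    combine: CombineRule = noisy_or,
) -> Tuple[np.ndarray, np.ndarray]:
    """Combined activation P_A and repression P_B for one gap gene.

    ``state`` maps gene names (dynamic gap genes plus static inputs) to
    concentrations at one or more spatial points.
    """
    Co, Ns = params.Co, params.Ns
    act, rep = [], []
    for edge in spec.edges_for(target):
        u = state[edge.regulator]
        logKa = params.affinity(spec.affinity_map[edge.edge_class])
        if edge.mode in ("activator", "dual"):
            act.append(site_occupancy(u, logKa, Co, Ns))
        if edge.mode == "repressor":
            rep.append(site_occupancy(u, logKa, Co, Ns))
        elif edge.mode == "dual":
            rep.append(saturated_occupancy(u, logKa, Co, Ns))
    return combine(act), combine(rep)


def production(
    state: Mapping[str, ArrayLike],
    spec: ModelSpec,
    params: ParameterSet,
    target: str,
    combine: CombineRule = noisy_or,
) -> np.ndarray:
    """Production rate alpha * P_A * (1 - P_B); always within [0, alpha]."""
    p_a, p_b = regulatory_input(state, spec, params, target, combine=combine)
    return params.alpha * p_a * (1.0 - p_b)


def production_field(
    state: Mapping[str, np.ndarray],
    spec: ModelSpec,
    params: ParameterSet,
    targets: Sequence[str],
    combine: CombineRule = noisy_or,
) -> np.ndarray:
    """Stacked production rates for several targets; shape (n_targets, n_x)."""
    return np.stack(
        [production(state, spec, params, g, combine=combine) for g in targets]
    )
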