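"""The six competing model parameterizations and parameter-vector plumbing.

A model variant is a regulatory topology (set of edges, each tagged with an
edge class such as ``Hb^R``) plus an *affinity map* assigning every edge class
to one of the binding-affinity parameters {K, K1, K2, K3}.  The variants:

============ ======================================================
name         distinguishing features
============ ======================================================
A6           global K everywhere except Hb^R and Kr^R -> K1
B7           Kr^R gets its own K2
B7r          like B7 but Kr^R -> K1 and Bcd^A -> K3
C8           B7 plus Bcd^A -> K3 (both K2 and K3 free)
D7           B7 plus the Bcd -> Kr activation edge
D8           C8 plus the Bcd -> Kr activation edge
============ ======================================================

Synthesis and decay are tied to a single rate ``alpha`` by default (the
variants count them as one open parameter), so the open-parameter counts are
6, 7, 7, 8, 7, 8.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .config import DEFAULT_BOUNDS, DEFAULT_SIGMA, MAX_CONCENTRATION

GAP_GENES: Tuple[str, ...] = ("Hb", "Kr", "Kni", "Gt")
STATIC_INPUTS: Tuple[str, ...] = ("Bcd", "Cad", "Tll")
MODEL_NAMES: Tuple[str, ...] = ("A6", "B7", "B7r", "C8", "D7", "D8")

EDGE_CLASSES: Tuple[str, ...] = (
    "Bcd^A", "Bcd^R", "Cad^A", "Hb^A", "Hb^D", "Hb^R",
    "Gt^R", "Kr^R", "Kni^R", "Tll^R",
)

_MODES = ("activator", "repressor", "dual")


class InvalidModelError(ValueError):
    """Raised for a model name outside the six defined variants."""


class MissingEdgeError(KeyError):
    """Raised when resolving an edge that the model does not contain."""


@dataclass(frozen=True)
class RegulatoryEdge:
    regulator: str
    target: str
    mode: str
    edge_class: str

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "dual" and (self.regulator, self.target) != ("Hb", "Kr"):
            raise ValueError("dual regulation is defined only for the Hb->Kr edge")


@dataclass(frozen=True)
class ModelSpec:
    name: str
    edges: Tuple[RegulatoryEdge, ...]
    affinity_map: Mapping[str, str]
    free_params: Tuple[str, ...]
    max_concentration: float = MAX_CONCENTRATION
    has_bcd_kr_edge: bool = False
    tie_synthesis_decay: bool = True

    def edges_for(self, target: str) -> Tuple[RegulatoryEdge, ...]:
        return tuple(e for e in self.edges if e.target == target)

    @property
    def n_free(self) -> int:
        return len(self.free_params)


@dataclass
class ParameterSet:
    """Free parameter values plus fixed configuration (sigma, bounds).

    ``values`` maps each free parameter name to its value; ``Ns`` is stored as
    a float but must be integer-valued.  When ``tie_synthesis_decay`` is set
    (the default) the decay rate equals ``alpha``; otherwise ``beta_value``
    must be provided.
    """

    values: Dict[str, float]
    sigma: float = DEFAULT_SIGMA
    bounds: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    tie_synthesis_decay: bool = True
    beta_value: Optional[float] = None
    max_concentration: float = MAX_CONCENTRATION

    @property
    def Ns(self) -> int:
        return int(round(self.values["Ns"]))

    @property
    def Co(self) -> float:
        return float(self.values["Co"])

    @property
    def alpha(self) -> float:
        return float(self.values["alpha"])

    @property
    def beta(self) -> float:
        if self.tie_synthesis_decay:
            return self.alpha
        if self.beta_value is None:
            raise ValueError("beta_value required when synthesis/decay untied")
        return float(self.beta_value)

    @property
    def D(self) -> float:
        return float(self.values["D"])

    def affinity(self, label: str) -> float:
        """Log10 binding affinity for parameter label K/K1/K2/K3."""
        return float(self.values[label])

    def in_bounds(self) -> bool:
        for name, v in self.values.items():
            lo, hi = self.bounds[name]
            if not (lo <= v <= hi):
                return False
        ns = self.values.get("Ns")
        if ns is not None and abs(ns - round(ns)) > 1e-9:
            return False
        return True


def _load_topology(path: Optional[str] = None) -> Dict:
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("gapnet.data").joinpath("topology.yaml")
    return yaml.safe_load(ref.read_text())


def _edges_from_config(raw: Iterable[Mapping]) -> List[RegulatoryEdge]:
    return [
        RegulatoryEdge(
            regulator=e["regulator"],
            target=e["target"],
            mode=e["mode"],
            edge_class=e["class"],
        )
        for e in raw
    ]


def _affinity_map(name: str) -> Dict[str, str]:
    amap = {c: "K" for c in EDGE_CLASSES}
    amap["Hb^R"] = "K1"
    amap["Kr^R"] = "K1" if name in ("A6", "B7r") else "K2"
    if name in ("B7r", "C8", "D8"):
        amap["Bcd^A"] = "K3"
    return amap


def _free_params(amap: Mapping[str, str]) -> Tuple[str, ...]:
    labels = ["K", "K1"]
    for extra in ("K2", "K3"):
        if extra in amap.values():
            labels.append(extra)
    return tuple(labels + ["Co", "Ns", "alpha", "D"])


def build_model(
    name: str,
    topology_path: Optional[str] = None,
    tie_synthesis_decay: bool = True,
) -> ModelSpec:
    """Construct one of the six model variants.

    Raises :class:`InvalidModelError` for any other name.
    """
    if name not in MODEL_NAMES:
        raise InvalidModelError(
            f"unknown model {name!r}; expected one of {MODEL_NAMES}"
        )
    topo = _load_topology(topology_path)
    edges = _edges_from_config(topo["edges"])
    has_bcd_kr = name in ("D7", "D8")
    if has_bcd_kr:
        edges.append(_edges_from_config([topo["optional_edges"]["bcd_kr"]])[0])
    amap = _affinity_map(name)
    free = _free_params(amap)
    if not tie_synthesis_decay:
        free = free[:-1] + ("beta", "D")  # decouple: beta becomes free
    return ModelSpec(
        name=name,
        edges=tuple(edges),
        affinity_map=amap,
        free_params=free,
        has_bcd_kr_edge=has_bcd_kr,
        tie_synthesis_decay=tie_synthesis_decay,
    )


def resolve_affinity(
    spec: ModelSpec, params: ParameterSet, edge: RegulatoryEdge
) -> float:
    """Log10 affinity of ``edge`` under the model's affinity map."""
    if edge not in spec.edges:
        raise MissingEdgeError(
            f"edge {edge.regulator}->{edge.target} not in model {spec.name}"
        )
    return params.affinity(spec.affinity_map[edge.edge_class])


def pack(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Flatten a ParameterSet into the model's free-parameter vector."""
    return np.array([params.values[n] for n in spec.free_params], dtype=float)


def unpack(
    vector: np.ndarray,
    spec: ModelSpec,
    sigma: float = DEFAULT_SIGMA,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> ParameterSet:
    """Inverse of :func:`pack`.  The Ns entry is rounded to the nearest int."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (len(spec.free_params),):
        raise ValueError(
            f"expected vector of length {len(spec.free_params)} for "
            f"{spec.name}, got shape {vector.shape}"
        )
    values = {n: float(v) for n, v in zip(spec.free_params, vector)}
    if "Ns" in values:
        values["Ns"] = float(round(values["Ns"]))
    beta_value = values.pop("beta", None)
    return ParameterSet(
        values=values,
        sigma=sigma,
        bounds=dict(bounds) if bounds is not None else dict(DEFAULT_BOUNDS),
        tie_synthesis_decay=spec.tie_synthesis_decay,
        beta_value=beta_value,
    )


def mid_prior_parameters(
    spec: ModelSpec,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    sigma: float = DEFAULT_SIGMA,
    overrides: Optional[Mapping[str, float]] = None,
) -> ParameterSet:
    """ParameterSet at the midpoint of every prior interval (Ns rounded)."""
    b = dict(bounds) if bounds is not None else dict(DEFAULT_BOUNDS)
    values = {}
    for name in spec.free_params:
        lo, hi = b[name if name != "beta" else "alpha"]
        values[name] = (lo + hi) / 2.0
    values["Ns"] = float(round(values["Ns"]))
    if overrides:
        values.update({k: float(v) for k, v in overrides.items() if k in values})
    beta_value = values.pop("beta", None)
    return ParameterSet(
        values=values,
        sigma=sigma,
        bounds=b,
        tie_synthesis_decay=spec.tie_synthesis_decay,
        beta_value=beta_value,
    )
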