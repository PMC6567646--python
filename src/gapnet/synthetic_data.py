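"""Synthetic expression profiles with the statistical structure the analysis
assumes: four static regulator gradients on a 100-point axis, a forward model
run, and iid Gaussian observation noise.  Everything is deterministic given a
seed, and profiles round-trip through a simple (gene, position, value) CSV.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_BOUNDS, MAX_CONCENTRATION
from .model_spec import (
    GAP_GENES,
    ModelSpec,
    ParameterSet,
    build_model,
    mid_prior_parameters,
)
from .solver import SpatialGrid, default_initial, solve

INPUT_GENES: Tuple[str, ...] = ("Bcd", "Cad", "HbMat", "Tll")
KNOWN_GENES: Tuple[str, ...] = GAP_GENES + INPUT_GENES

#: Ground-truth parameter values used by default in recovery experiments.
#: Mid-prior values, except: K3 sits one log10 unit above K so variants with a
#: separate anterior-activator affinity are distinguishable, the gap-gene
#: cross-repression affinities (K1/K2) are raised to act on order-one
#: concentrations, and D is small enough not to flatten the domains.
DEFAULT_TRUTH_OVERRIDES: Dict[str, float] = {
    "K": -2.0,
    "K1": -0.5,
    "K2": -0.5,
    "K3": -1.0,
    "Co": 3.0,
    "Ns": 5.0,
    "alpha": 5.0,
    "D": 0.1,
}


class ProfileFormatError(ValueError):
    """Malformed profile CSV (bad columns, rows, genes or positions)."""


@dataclass(frozen=True)
class MaternalInputSpec:
    """Parametric shapes for the static regulator profiles (in % e.l.)."""

    bcd_amplitude: float = MAX_CONCENTRATION
    bcd_lambda: float = 20.0          # anterior exponential decay length
    cad_center: float = 45.0          # posterior sigmoid midpoint
    cad_width: float = 8.0
    hb_center: float = 45.0           # maternal anterior step midpoint
    hb_width: float = 4.0
    tll_anterior_width: float = 6.0   # terminal bumps
    tll_posterior_width: float = 10.0
    tll_anterior_height: float = 0.6  # relative to max_concentration
    max_concentration: float = MAX_CONCENTRATION


def make_inputs(
    ispec: MaternalInputSpec, grid: SpatialGrid
) -> Dict[str, np.ndarray]:
    """Static regulator profiles on the grid, all within [0, max_conc]."""
    x = grid.positions_percent
    c = ispec.max_concentration
    bcd = ispec.bcd_amplitude * np.exp(-x / ispec.bcd_lambda)
    cad = c / (1.0 + np.exp(-(x - ispec.cad_center) / ispec.cad_width))
    hb = c / (1.0 + np.exp((x - ispec.hb_center) / ispec.hb_width))
    tll = c * (
        ispec.tll_anterior_height * np.exp(-(x / ispec.tll_anterior_width) ** 2)
        + np.exp(-(((100.0 - x) / ispec.tll_posterior_width) ** 2))
    )
    profiles = {"Bcd": bcd, "Cad": cad, "HbMat": hb, "Tll": tll}
    for gene, prof in profiles.items():
        if np.any(prof > c + 1e-9):
            raise ValueError(
                f"{gene} profile exceeds the maximum concentration {c}"
            )
        if np.any(prof < 0):
            raise ValueError(f"{gene} profile has negative values")
    return profiles


@dataclass
class SyntheticDataset:
    grid: SpatialGrid
    inputs: Dict[str, np.ndarray]
    truth: ParameterSet
    clean: Dict[str, np.ndarray]
    observed: Dict[str, np.ndarray]
    sigma: float
    seed: int
    model_name: str


def default_truth(
    spec: ModelSpec,
    sigma: float,
    overrides: Optional[Mapping[str, float]] = None,
) -> ParameterSet:
    merged = dict(DEFAULT_TRUTH_OVERRIDES)
    if overrides:
        merged.update(overrides)
    return mid_prior_parameters(spec, sigma=sigma, overrides=merged)


def simulate_dataset(
    model_name: str,
    theta_star: Optional[ParameterSet] = None,
    sigma: float = 0.05,
    seed: int = 0,
    grid: Optional[SpatialGrid] = None,
    input_spec: Optional[MaternalInputSpec] = None,
    t_final: float = 1.0,
    dt: Optional[float] = None,
) -> SyntheticDataset:
    """Forward-simulate a model variant and add iid Gaussian noise.

    The default noise s.d. is scaled to the order-one output concentrations
    of the synthesis/decay-tied model (about 10% of a typical domain height).
    """
    grid = grid or SpatialGrid()
    spec = build_model(model_name)
    theta = theta_star if theta_star is not None else default_truth(spec, sigma)
    if not theta.in_bounds():
        raise ValueError("theta_star outside prior bounds")
    ispec = input_spec or MaternalInputSpec()
    inputs = make_inputs(ispec, grid)
    initial = default_initial(inputs, grid)
    clean = solve(inputs, initial, spec, theta, grid, t_final=t_final, dt=dt)
    rng = np.random.default_rng(seed)
    observed = {
        g: clean[g] + rng.normal(0.0, sigma, size=grid.n_points)
        for g in GAP_GENES
    }
    return SyntheticDataset(
        grid=grid, inputs=inputs, truth=theta, clean=clean,
        observed=observed, sigma=sigma, seed=seed, model_name=model_name,
    )


def write_profiles(
    profiles: Mapping[str, np.ndarray],
    path: str | Path,
    grid: SpatialGrid,
) -> None:
    """CSV with columns (gene, position_percent_el, value), full precision."""
    rows = []
    pos = grid.positions_percent
    for gene in profiles:
        vals = np.asarray(profiles[gene], dtype=float)
        if vals.shape != pos.shape:
            raise ValueError(f"profile for {gene} does not match the grid")
        for p, v in zip(pos, vals):
            rows.append((gene, repr(float(p)), repr(float(v))))
    with open(path, "w") as fh:
        fh.write("gene,position_percent_el,value\n")
        for gene, p, v in rows:
            fh.write(f"{gene},{p},{v}\n")


def read_profiles(
    path: str | Path,
    expected_genes: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Inverse of :func:`write_profiles`; returns (positions, profiles).

    Validates the header, gene names, position range and monotonicity, and
    reports the offending row number on failure.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as err:
        raise ProfileFormatError(f"cannot parse {path}: {err}") from err
    required = ["gene", "position_percent_el", "value"]
    if list(df.columns) != required:
        raise ProfileFormatError(
            f"expected columns {required}, got {list(df.columns)}"
        )
    for col in ("position_percent_el", "value"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ProfileFormatError(
                f"non-numeric {col} at row {int(bad[0]) + 2}"
            )
    df["position_percent_el"] = df["position_percent_el"].astype(float)
    df["value"] = df["value"].astype(float)
    out_of_range = df.index[
        (df.position_percent_el < 0) | (df.position_percent_el > 100)
    ]
    if len(out_of_range):
        raise ProfileFormatError(
            f"position outside [0, 100] at row {int(out_of_range[0]) + 2}"
        )
    genes = list(dict.fromkeys(df.gene))
    allowed = set(expected_genes) if expected_genes is not None else set(KNOWN_GENES)
    unknown = [g for g in genes if g not in allowed]
    if unknown:
        raise ProfileFormatError(f"unexpected gene name(s): {unknown}")
    positions = None
    profiles: Dict[str, np.ndarray] = {}
    for gene in genes:
        sub = df[df.gene == gene]
        pos = sub.position_percent_el.to_numpy()
        if np.any(np.diff(pos) <= 0):
            row = int(sub.index[np.argmax(np.diff(pos) <= 0) + 1]) + 2
            raise ProfileFormatError(
                f"non-monotone positions for {gene} at row {row}"
            )
        if positions is None:
            positions = pos
        elif pos.shape != positions.shape or not np.array_equal(pos, positions):
            raise ProfileFormatError(f"grid mismatch for gene {gene}")
        profiles[gene] = sub.value.to_numpy()
    return positions, profiles


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write observed/clean/input CSVs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_profiles(ds.observed, outdir / "observed.csv", ds.grid)
    write_profiles(ds.clean, outdir / "clean.csv", ds.grid)
    write_profiles(ds.inputs, outdir / "inputs.csv", ds.grid)
    manifest = {
        "model_name": ds.model_name,
        "seed": ds.seed,
        "sigma": ds.sigma,
        "n_grid": ds.grid.n_points,
        "theta_star": ds.truth.values,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_dataset(outdir: str | Path) -> SyntheticDataset:
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    grid = SpatialGrid(n_points=manifest["n_grid"])
    _, observed = read_profiles(outdir / "observed.csv")
    _, clean = read_profiles(outdir / "clean.csv")
    _, inputs = read_profiles(outdir / "inputs.csv")
    spec = build_model(manifest["model_name"])
    truth = ParameterSet(values=dict(manifest["theta_star"]),
                         sigma=manifest["sigma"])
    return SyntheticDataset(
        grid=grid, inputs=inputs, truth=truth, clean=clean,
        observed=observed, sigma=manifest["sigma"], seed=manifest["seed"],
        model_name=manifest["model_name"],
    )
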