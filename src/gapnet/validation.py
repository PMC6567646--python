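"""Convergence diagnostics and the sequential spatial cross-validation check.

Convergence is monitored on scalar traces (by default the model
log-likelihood) with the Gelman-Rubin potential scale reduction factor,
recomputed on growing prefixes (first 50 samples, then bins of 10) so the
approach to R < 1.2 is visible.

The over-fitting check fits the model on the anterior-most 60% of grid
positions, predicts the next 5%, then grows the training window in 5% steps
(8 folds on a 100-point grid, tiling 60-100%).  Prediction accuracy is the
per-point mean predictive log-likelihood over posterior draws, compared to
full-data posterior predictive values with a Welch t-test.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .likelihood import DomainMask, GapGenePosterior, Observation, gaussian_log_density
from .model_spec import GAP_GENES, ModelSpec, ParameterSet
from .sampling import make_ladder, pt_run
from .solver import SpatialGrid, default_initial, solve


def gelman_rubin(traces: np.ndarray, corrected: bool = False) -> float:
    """Potential scale reduction factor for m chains of n scalar samples.

    With W the mean within-chain variance and B/n the variance of the chain
    means, the pooled variance is var+ = (n-1)/n W + B/n and R =
    sqrt(var+ / W).  ``corrected=True`` adds the sampling-variability term
    B/(mn), i.e. uses (m+1)/m * B/n, as the classic diagnostic does.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("traces must be (m_chains, n_samples)")
    m, n = traces.shape
    if m < 2:
        raise ValueError("the diagnostic uses multiple chains (m >= 2)")
    if n < 2:
        raise ValueError("need at least 2 samples per chain")
    W = float(np.mean(np.var(traces, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(traces, axis=1), ddof=1))
    var_plus = (n - 1) / n * W + B_over_n
    if corrected:
        var_plus += B_over_n / m
    if W == 0.0:
        return 1.0 if var_plus == 0.0 else math.inf
    return math.sqrt(var_plus / W)


@dataclass
class ShrinkFactorSeries:
    checkpoints: np.ndarray
    R_values: np.ndarray
    R_values_corrected: np.ndarray
    threshold: float = 1.2

    def first_converged(self) -> Optional[int]:
        """First checkpoint from which R stays below the threshold."""
        below = self.R_values < self.threshold
        for k in range(len(below)):
            if np.all(below[k:]):
                return int(self.checkpoints[k])
        return None


def shrink_evolution(
    traces: np.ndarray,
    start: int = 50,
    step: int = 10,
    threshold: float = 1.2,
) -> ShrinkFactorSeries:
    """R on the first 50, 60, 70, ... samples of each chain."""
    traces = np.asarray(traces, dtype=float)
    m, n = traces.shape
    if n < start:
        raise ValueError(f"need at least {start} samples, got {n}")
    checkpoints = np.arange(start, n + 1, step)
    r = np.array([gelman_rubin(traces[:, :c]) for c in checkpoints])
    rc = np.array([gelman_rubin(traces[:, :c], corrected=True)
                   for c in checkpoints])
    return ShrinkFactorSeries(checkpoints, r, rc, threshold)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Welch unequal-variance t-test; two-sided p via Welch-Satterthwaite df.

    Two identical-mean zero-variance samples give (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        ma, mb = float(np.mean(a)), float(np.mean(b))
        if math.isclose(ma, mb, rel_tol=1e-12, abs_tol=1e-12):
            return 0.0, 1.0
        return math.inf if ma > mb else -math.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def cv_schedule(
    n_points: int,
    train_fraction: float = 0.60,
    step_fraction: float = 0.05,
    anterior_first: bool = True,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """(train indices, test indices) per fold; test sets tile the tail.

    On 100 points the training sets hold 60, 65, ..., 95 points and each test
    set is the next 5 points, so 8 folds cover positions 60-100% exactly.
    """
    n_test = int(round(step_fraction * n_points))
    if n_test < 1:
        raise ValueError("grid too small for the requested test fraction")
    order = np.arange(n_points) if anterior_first else np.arange(n_points)[::-1]
    folds = []
    n_train = int(round(train_fraction * n_points))
    while n_train + n_test <= n_points:
        folds.append((order[:n_train].copy(),
                      order[n_train:n_train + n_test].copy()))
        n_train += n_test
    return folds


@dataclass
class CVConfig:
    n_iter: int = 500
    ladder_size: int = 6
    ladder_exponent: float = 5.0
    seed: int = 0
    n_posterior_samples: int = 100
    burn_in_fraction: float = 0.5
    train_fraction: float = 0.60
    step_fraction: float = 0.05
    anterior_first: bool = True
    t_final: float = 1.0
    dt: Optional[float] = None
    refit: bool = True
    fixed_params: Optional[ParameterSet] = None


@dataclass
class CVResult:
    fold_log_liks: np.ndarray
    mean: float
    full_data_log_liks: np.ndarray
    welch_t: float
    welch_p: float
    folds: List[Tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def _predictive_mean_loglik(
    draws: Sequence[ParameterSet],
    posterior: GapGenePosterior,
    test_idx: np.ndarray,
    spec: ModelSpec,
) -> float:
    """Per-point mean log-likelihood on test positions, averaged over draws."""
    vals = []
    for theta in draws:
        profiles = solve(posterior.static_inputs, posterior.initial, spec,
                         theta, posterior.grid, t_final=posterior.t_final,
                         dt=posterior.dt)
        total, n = 0.0, 0
        for gene in GAP_GENES:
            resid = (np.asarray(posterior.Y.Y[gene])[test_idx]
                     - profiles[gene][test_idx])
            total += gaussian_log_density(resid, posterior.Y.sigma)
            n += resid.size
        vals.append(total / n)
    return float(np.mean(vals))


def _posterior_draws(
    posterior: GapGenePosterior, config: CVConfig, seed: int
) -> List[ParameterSet]:
    ladder = make_ladder(config.ladder_size, config.ladder_exponent)
    ens = pt_run(posterior, ladder=ladder, n_iter=config.n_iter, seed=seed)
    burn = int(config.burn_in_fraction * config.n_iter)
    trace = ens.posterior_trace(burn)
    rng = np.random.default_rng(seed + 10_000)
    rows = rng.integers(trace.shape[0], size=config.n_posterior_samples)
    return [posterior.to_parameters(trace[r]) for r in rows]


def sequential_cv(
    Y: Observation,
    spec: ModelSpec,
    static_inputs: Mapping[str, np.ndarray],
    grid: SpatialGrid,
    config: Optional[CVConfig] = None,
    mask: Optional[DomainMask] = None,
) -> CVResult:
    """Sequential spatial cross-validation with a Welch over-fitting test.

    Each fold refits the model with the likelihood restricted to training
    positions (intersected with the per-gene trust domains), draws posterior
    samples and scores the next block of positions.  With ``refit=False`` and
    ``fixed_params`` the prediction uses that single parameter set, which is
    the cheap no-fitting variant.
    """
    config = config or CVConfig()
    mask = mask or DomainMask()
    folds = cv_schedule(grid.n_points, config.train_fraction,
                        config.step_fraction, config.anterior_first)
    base_idx = mask.indices(grid)
    fold_vals = []
    for k, (train_idx, test_idx) in enumerate(folds):
        posterior = GapGenePosterior(
            spec, Y, static_inputs, grid, mask=mask,
            t_final=config.t_final, dt=config.dt,
        )
        posterior.mask_indices = {
            g: np.intersect1d(base_idx[g], train_idx) for g in base_idx
        }
        if config.refit:
            draws = _posterior_draws(posterior, config, config.seed + 101 * k)
        else:
            if config.fixed_params is None:
                raise ValueError("refit=False requires fixed_params")
            draws = [config.fixed_params]
        fold_vals.append(
            _predictive_mean_loglik(draws, posterior, test_idx, spec)
        )
    # full-data posterior predictive reference
    posterior_full = GapGenePosterior(
        spec, Y, static_inputs, grid, mask=mask,
        t_final=config.t_final, dt=config.dt,
    )
    if config.refit:
        full_draws = _posterior_draws(posterior_full, config,
                                      config.seed + 99_991)
    else:
        full_draws = [config.fixed_params] * max(2, len(folds))
    all_idx = np.arange(grid.n_points)
    full_vals = np.array([
        _predictive_mean_loglik([theta], posterior_full, all_idx, spec)
        for theta in full_draws
    ])
    fold_vals = np.asarray(fold_vals)
    t, p = welch_t_test(fold_vals, full_vals)
    return CVResult(
        fold_log_liks=fold_vals,
        mean=float(np.mean(fold_vals)),
        full_data_log_liks=full_vals,
        welch_t=t,
        welch_p=p,
        folds=folds,
    )
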