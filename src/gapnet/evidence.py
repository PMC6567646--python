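"""Thermodynamic-integration marginal likelihoods and Bayes factors.

The log marginal likelihood is the integral over t in [0, 1] of the expected
log likelihood under the tempered posterior; with samples at a ladder of
temperatures the integral is evaluated by the trapezoid rule

    log p(Y) ~= sum_i 0.5 (t_{i+1} - t_i) (E_{t_{i+1}} + E_{t_i}).

The sampled ladder starts at t_1 = (1/N)^5 > 0; by default the quadrature is
extended with a t = 0 node whose expectation is estimated from prior draws
(under t = 0 the tempered posterior is the prior).  Pass
``include_prior_node=False`` for the sampled-nodes-only variant.

Bayes factors are differences of log evidences, reported on the 2 ln(B) scale
with the conventional evidence-strength categories at thresholds 2, 6, 10.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .sampling import Target, TemperedEnsemble, make_ladder, pt_run

KASS_RAFTERY_CATEGORIES = (
    (2.0, "Not worth more than a bare mention"),
    (6.0, "Substantial"),
    (10.0, "Strong"),
    (math.inf, "Very strong"),
)


@dataclass
class EvidenceEstimate:
    log_z: float
    se: float
    per_temperature_E: np.ndarray
    ladder: np.ndarray
    n_runs: int
    per_run: List[float] = field(default_factory=list)
    n_failed: int = 0
    model_name: str = ""


@dataclass
class BayesFactorReport:
    model_a: str
    model_b: str
    log_bf: float
    two_ln_bf: float
    category: str
    favored: str


def expected_log_lik(trace: np.ndarray, burn_in: int = 0) -> float:
    """Post-burn-in arithmetic mean of a log-likelihood trace."""
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("expected a 1-D trace")
    kept = trace[burn_in:]
    if kept.size == 0:
        raise ValueError("no samples left after burn-in")
    return float(np.mean(kept))


def thermodynamic_integral(
    ladder: Sequence[float], e_values: Sequence[float]
) -> float:
    """Trapezoid quadrature of E_t[log L] over the given temperature nodes."""
    t = np.asarray(ladder, dtype=float)
    e = np.asarray(e_values, dtype=float)
    if t.shape != e.shape:
        raise ValueError("ladder and E values must have the same length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("ladder must be strictly increasing")
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("temperatures must lie in [0, 1]")
    return float(np.sum(0.5 * np.diff(t) * (e[1:] + e[:-1])))


def prior_expected_log_lik(
    target: Target, rng: np.random.Generator, n_samples: int = 200
) -> float:
    """Monte-Carlo estimate of E_{t=0}[log L] from prior draws.

    Draws with non-finite log likelihood (e.g. unstable solver runs) are
    dropped; an error is raised if none survive.
    """
    vals = []
    for _ in range(n_samples):
        ll = target.log_likelihood(target.sample_prior(rng))
        if math.isfinite(ll):
            vals.append(ll)
    if not vals:
        raise RuntimeError("no finite prior log-likelihood draws")
    return float(np.mean(vals))


def evidence_from_run(
    ensemble: TemperedEnsemble,
    burn_in: int,
    e0: Optional[float] = None,
) -> Tuple[float, np.ndarray, np.ndarray]:
    """(log_z, nodes, E values) for one tempered run.

    ``e0`` extends the quadrature with a t = 0 node; omit it for the
    sampled-nodes-only variant.
    """
    e_vals = np.array([
        expected_log_lik(ensemble.loglik_trace[:, c], burn_in)
        for c in range(ensemble.n_chains)
    ])
    nodes = np.asarray(ensemble.ladder, dtype=float)
    if e0 is not None and nodes[0] > 0.0:
        nodes = np.concatenate([[0.0], nodes])
        e_vals = np.concatenate([[e0], e_vals])
    return thermodynamic_integral(nodes, e_vals), nodes, e_vals


def estimate_evidence(
    target: Target,
    ladder: Optional[np.ndarray] = None,
    n_iter: int = 1000,
    n_runs: int = 10,
    seed: int = 0,
    burn_in_fraction: float = 0.5,
    include_prior_node: bool = True,
    n_prior_samples: int = 200,
    model_name: str = "",
    run_seeds: Optional[Sequence[int]] = None,
) -> EvidenceEstimate:
    """Replicate PT runs and average their thermodynamic integrals.

    ``log_z`` is the mean over runs and ``se`` the run-to-run standard
    deviation divided by sqrt(n).  Failed runs are excluded and counted.
    ``run_seeds`` overrides the per-run seeds derived from ``seed``.
    """
    ladder = make_ladder() if ladder is None else np.asarray(ladder, dtype=float)
    burn_in = int(burn_in_fraction * n_iter)
    seeds = [int(s.generate_state(1)[0])
             for s in np.random.SeedSequence(seed).spawn(n_runs + 1)]
    if run_seeds is not None:
        if len(run_seeds) != n_runs:
            raise ValueError("run_seeds must have length n_runs")
        seeds = list(run_seeds) + [seeds[-1]]
    e0 = None
    if include_prior_node:
        rng0 = np.random.default_rng(seeds[-1])
        e0 = prior_expected_log_lik(target, rng0, n_prior_samples)
    per_run: List[float] = []
    e_stack: List[np.ndarray] = []
    nodes = ladder
    n_failed = 0
    for k in range(n_runs):
        try:
            ens = pt_run(target, ladder=ladder, n_iter=n_iter, seed=seeds[k])
            log_z, nodes, e_vals = evidence_from_run(ens, burn_in, e0=e0)
        except Exception:
            n_failed += 1
            continue
        if not math.isfinite(log_z):
            n_failed += 1
            continue
        per_run.append(log_z)
        e_stack.append(e_vals)
    if not per_run:
        raise RuntimeError("all evidence runs failed")
    arr = np.asarray(per_run)
    se = float(np.std(arr, ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
    return EvidenceEstimate(
        log_z=float(np.mean(arr)),
        se=se,
        per_temperature_E=np.mean(np.stack(e_stack), axis=0),
        ladder=nodes,
        n_runs=arr.size,
        per_run=per_run,
        n_failed=n_failed,
        model_name=model_name,
    )


def classify(two_ln_bf: float) -> str:
    """Evidence-strength category from |2 ln B|; bins [0,2), [2,6), [6,10), [10,inf)."""
    v = abs(two_ln_bf)
    for threshold, label in KASS_RAFTERY_CATEGORIES:
        if v < threshold:
            return label
    return KASS_RAFTERY_CATEGORIES[-1][1]


def bayes_factor(a: EvidenceEstimate, b: EvidenceEstimate) -> BayesFactorReport:
    """Bayes factor of model a over model b from their log evidences."""
    log_bf = a.log_z - b.log_z
    two_ln_bf = 2.0 * log_bf
    favored = a.model_name if log_bf >= 0 else b.model_name
    return BayesFactorReport(
        model_a=a.model_name,
        model_b=b.model_name,
        log_bf=log_bf,
        two_ln_bf=two_ln_bf,
        category=classify(two_ln_bf),
        favored=favored,
    )
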