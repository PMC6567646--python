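"""Metropolis-Hastings with a mixed discrete/continuous proposal, and the
parallel-tempering ensemble with neighbour-exchange moves.

The within-chain proposal perturbs the integer site-count parameter by +/-1
with probability 1/10 (continuous parameters untouched) and otherwise adds
independent N(0, 0.1) increments to every continuous parameter.  Both branches
are symmetric, so the Hastings correction is zero.

Tempering raises only the likelihood to a power t in (0, 1]; the chain ladder
follows t_i = (i/N)^5 by default, and one exchange sweep proposes N
neighbour swaps, picking the first chain uniformly and the neighbour up/down
with probability 1/2 (forced at the ladder ends, with the asymmetric
edge-selection probability entering the acceptance ratio).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Protocol, Sequence, Tuple

import numpy as np


class Target(Protocol):
    """What the samplers need from a posterior: a factored log density."""

    def log_likelihood(self, x: np.ndarray) -> float: ...

    def log_prior(self, x: np.ndarray) -> float: ...

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray: ...

    def propose(
        self, x: np.ndarray, rng: np.random.Generator
    ) -> Tuple[np.ndarray, float]: ...


@dataclass
class FunctionTarget:
    """Adapter building a Target from plain callables (used for toy targets)."""

    loglik: Callable[[np.ndarray], float]
    logprior: Callable[[np.ndarray], float]
    prior_sampler: Callable[[np.random.Generator], np.ndarray]
    proposal: Optional[
        Callable[[np.ndarray, np.random.Generator], Tuple[np.ndarray, float]]
    ] = None
    proposal_variance: float = 0.1

    def log_likelihood(self, x: np.ndarray) -> float:
        return float(self.loglik(x))

    def log_prior(self, x: np.ndarray) -> float:
        return float(self.logprior(x))

    def sample_prior(self, rng: np.random.Generator) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.prior_sampler(rng), dtype=float))

    def propose(self, x, rng):
        if self.proposal is not None:
            return self.proposal(x, rng)
        step = rng.normal(0.0, math.sqrt(self.proposal_variance), size=x.shape)
        return x + step, 0.0


def propose_mixed(
    x: np.ndarray,
    rng: np.random.Generator,
    ns_index: Optional[int] = None,
    p_discrete: float = 0.1,
    variance: float = 0.1,
    scales: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, float]:
    """Mixed proposal; returns (x_new, log q-ratio) with q-ratio always 0.

    With probability ``p_discrete`` the entry at ``ns_index`` moves +/-1 (each
    direction with probability 1/2) and nothing else changes; otherwise every
    other entry gets an independent Gaussian increment of variance
    ``variance`` (optionally scaled per-parameter via ``scales``).
    """
    x_new = np.array(x, dtype=float, copy=True)
    if ns_index is not None and rng.random() < p_discrete:
        x_new[ns_index] += 1.0 if rng.random() < 0.5 else -1.0
    else:
        sd = np.full(x_new.shape, math.sqrt(variance))
        if scales is not None:
            sd = sd * np.asarray(scales, dtype=float)
        incr = rng.normal(0.0, 1.0, size=x_new.shape) * sd
        if ns_index is not None:
            incr[ns_index] = 0.0
        x_new += incr
    return x_new, 0.0


@dataclass
class ChainState:
    x: np.ndarray
    log_lik: float
    log_prior: float
    temperature: float


def _accept(log_alpha: float, rng: np.random.Generator) -> bool:
    if log_alpha >= 0:
        return True
    return math.log(rng.random()) < log_alpha


def mh_step(
    state: ChainState, target: Target, rng: np.random.Generator
) -> Tuple[ChainState, bool]:
    """One Metropolis-Hastings update of a single (possibly tempered) chain.

    The acceptance ratio uses t * log_likelihood + log_prior at the chain's
    temperature.  Returns (new_state, accepted).
    """
    x_new, log_q = target.propose(state.x, rng)
    lp_new = target.log_prior(x_new)
    if lp_new == -math.inf:
        return state, False
    ll_new = target.log_likelihood(x_new)
    t = state.temperature
    if t == 0.0:
        log_alpha = lp_new - state.log_prior + log_q
    elif ll_new == -math.inf:
        return state, False
    elif state.log_lik == -math.inf:
        log_alpha = math.inf  # escaping an invalid start point
    else:
        log_alpha = (
            t * (ll_new - state.log_lik) + (lp_new - state.log_prior) + log_q
        )
    if _accept(log_alpha, rng):
        return ChainState(x_new, ll_new, lp_new, t), True
    return state, False


def make_ladder(n: int = 10, exponent: float = 5.0) -> np.ndarray:
    """Temperatures ((i/n)^exponent for i = 1..n); last entry is exactly 1."""
    if n < 2:
        raise ValueError("ladder needs at least 2 temperatures")
    i = np.arange(1, n + 1, dtype=float)
    t = (i / n) ** exponent
    t[-1] = 1.0
    return t


def _edge_log_prob(i: int, j: int, n: int) -> float:
    """log p of selecting neighbour j from chain i (1 at the ends, else 1/2)."""
    if i == 0 or i == n - 1:
        return 0.0
    return -math.log(2.0)


def exchange_log_ratio(
    t_i: float, t_j: float, ll_i: float, ll_j: float
) -> float:
    """Log of the likelihood factor of the swap acceptance ratio:
    (t_i - t_j) * (log L_j - log L_i)."""
    if ll_i == ll_j:
        return 0.0
    return (t_i - t_j) * (ll_j - ll_i)


@dataclass
class TemperedEnsemble:
    chains: List[ChainState]
    ladder: np.ndarray
    theta_trace: np.ndarray  # (n_iter, n_chains, dim)
    loglik_trace: np.ndarray  # (n_iter, n_chains)
    seed: Optional[int] = None
    mh_accepts: np.ndarray = field(default_factory=lambda: np.zeros(0))
    mh_proposals: np.ndarray = field(default_factory=lambda: np.zeros(0))
    exchange_accepts: int = 0
    exchange_proposals: int = 0

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def acceptance_rates(self) -> dict:
        with np.errstate(invalid="ignore", divide="ignore"):
            within = self.mh_accepts / np.maximum(self.mh_proposals, 1)
        ex = (self.exchange_accepts / self.exchange_proposals
              if self.exchange_proposals else float("nan"))
        return {"within_chain": within.tolist(), "exchange": ex}

    def posterior_trace(self, burn_in: int = 0) -> np.ndarray:
        """Trace of the untempered (t = 1) chain, after burn-in."""
        return self.theta_trace[burn_in:, -1, :]

    def posterior_loglik(self, burn_in: int = 0) -> np.ndarray:
        return self.loglik_trace[burn_in:, -1]


def exchange_sweep(
    chains: List[ChainState],
    rng: np.random.Generator,
) -> Tuple[int, int]:
    """Propose n_chains neighbour swaps in place; returns (accepted, proposed).

    A swap exchanges the states (x, log_lik, log_prior) of two neighbouring
    temperature slots; the temperatures stay attached to the slots.
    """
    n = len(chains)
    if n < 2:
        return 0, 0
    accepted = 0
    for _ in range(n):
        i = int(rng.integers(n))
        if i == 0:
            j = 1
        elif i == n - 1:
            j = n - 2
        else:
            j = i + 1 if rng.random() < 0.5 else i - 1
        ci, cj = chains[i], chains[j]
        log_q = _edge_log_prob(j, i, n) - _edge_log_prob(i, j, n)
        log_alpha = (
            exchange_log_ratio(ci.temperature, cj.temperature,
                               ci.log_lik, cj.log_lik)
            + log_q
        )
        if _accept(log_alpha, rng):
            chains[i] = ChainState(cj.x, cj.log_lik, cj.log_prior,
                                   ci.temperature)
            chains[j] = ChainState(ci.x, ci.log_lik, ci.log_prior,
                                   cj.temperature)
            accepted += 1
    return accepted, n


def pt_run(
    target: Target,
    ladder: Optional[np.ndarray] = None,
    n_iter: int = 1000,
    seed: int = 0,
    initial: Optional[Sequence[np.ndarray]] = None,
) -> TemperedEnsemble:
    """Parallel-tempered MCMC: alternate one MH sweep and one exchange sweep.

    Chains start from independent prior draws (or ``initial``).  Fully
    deterministic given ``seed``.  The returned traces cover every
    temperature; the last chain is the untempered posterior chain.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ladder = make_ladder() if ladder is None else np.asarray(ladder, dtype=float)
    if np.any(np.diff(ladder) <= 0) or ladder[-1] != 1.0:
        raise ValueError("ladder must be strictly increasing and end at 1")
    rng = np.random.default_rng(seed)
    n_chains = len(ladder)
    chains: List[ChainState] = []
    for c in range(n_chains):
        x0 = (np.asarray(initial[c], dtype=float) if initial is not None
              else target.sample_prior(rng))
        chains.append(
            ChainState(
                x=np.atleast_1d(x0),
                log_lik=target.log_likelihood(np.atleast_1d(x0)),
                log_prior=target.log_prior(np.atleast_1d(x0)),
                temperature=float(ladder[c]),
            )
        )
    dim = chains[0].x.size
    theta_trace = np.empty((n_iter, n_chains, dim))
    loglik_trace = np.empty((n_iter, n_chains))
    mh_accepts = np.zeros(n_chains)
    mh_proposals = np.zeros(n_chains)
    ex_acc = 0
    ex_prop = 0
    for it in range(n_iter):
        for c in range(n_chains):
            chains[c], ok = mh_step(chains[c], target, rng)
            mh_proposals[c] += 1
            mh_accepts[c] += ok
        a, p = exchange_sweep(chains, rng)
        ex_acc += a
        ex_prop += p
        for c in range(n_chains):
            theta_trace[it, c, :] = chains[c].x
            loglik_trace[it, c] = chains[c].log_lik
    return TemperedEnsemble(
        chains=chains,
        ladder=ladder,
        theta_trace=theta_trace,
        loglik_trace=loglik_trace,
        seed=seed,
        mh_accepts=mh_accepts,
        mh_proposals=mh_proposals,
        exchange_accepts=ex_acc,
        exchange_proposals=ex_prop,
    )


def metropolis(
    logpdf: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    variance: float = 0.1,
) -> np.ndarray:
    """Plain random-walk Metropolis on an unnormalized log density.

    Convenience for toy targets and for equal-budget comparisons against the
    tempered ensemble; returns the (n_iter, dim) trace.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    lp = float(logpdf(x))
    sd = math.sqrt(variance)
    out = np.empty((n_iter, x.size))
    for it in range(n_iter):
        x_new = x + rng.normal(0.0, sd, size=x.shape)
        lp_new = float(logpdf(x_new))
        if _accept(lp_new - lp, rng):
            x, lp = x_new, lp_new
        out[it] = x
    return out
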