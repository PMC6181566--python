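"""Exact stochastic simulation (Gillespie SSA) of the integer model.

Receptor counts are small at individual synapses (a handful to ~100),
so demographic noise matters.  The continuous-time Markov jump process
has 2N+2 reaction channels for N synapses:

* ``bind(i)``       w_i -> w_i+1, p -> p-1   propensity alpha*p*(s_i-w_i)
* ``unbind(i)``     w_i -> w_i-1, p -> p+1   propensity beta*w_i
* ``externalize``   p -> p+1                 propensity gamma
* ``internalize``   p -> p-1                 propensity delta*p

(7 synapses give the canonical 16 channels.)  The direct-method SSA
draws exponential waiting times from the total propensity and picks a
channel proportionally.  States are sampled on a fixed time grid by
carrying the piecewise-constant state between events, which yields
unbiased time averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .params import RateConstants, filling_fraction

__all__ = [
    "ReactionChannel",
    "StochasticRun",
    "build_reactions",
    "stationary_initial_state",
    "gillespie_run",
    "validate_against_ode",
]

#: Default sampling interval for statistics: 1 s of simulated time.
DEFAULT_SAMPLE_DT = 1.0 / 60.0
#: Default burn-in discarded before steady-state statistics, minutes.
DEFAULT_BURN_IN = 2.0


@dataclass(frozen=True)
class ReactionChannel:
    """One elementary reaction: kind plus synapse index (None for pool)."""

    kind: str  # 'bind' | 'unbind' | 'externalize' | 'internalize'
    synapse: Optional[int] = None


def build_reactions(N: int) -> List[ReactionChannel]:
    """The 2N+2 reaction channels of an N-synapse system."""
    if N < 0:
        raise ValueError("synapse count must be >= 0")
    channels = [ReactionChannel("bind", i) for i in range(N)]
    channels += [ReactionChannel("unbind", i) for i in range(N)]
    channels.append(ReactionChannel("externalize"))
    channels.append(ReactionChannel("internalize"))
    return channels


@dataclass
class StochasticRun:
    """Grid-sampled integer states from one SSA run, plus bookkeeping."""

    seed: int
    times: np.ndarray  # minutes
    w: np.ndarray  # (n_samples, N) int
    p: np.ndarray  # (n_samples,) int
    slots: np.ndarray
    rates: RateConstants
    event_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def n_synapses(self) -> int:
        return self.w.shape[1]


def stationary_initial_state(
    rates: RateConstants, slots: Sequence[int]
) -> Tuple[np.ndarray, int]:
    """Integer state at the rounded long-term fixed point: (w0, p0)."""
    s = np.asarray(slots)
    F = filling_fraction(rates)
    w0 = np.rint(F * s).astype(np.int64)
    p0 = int(round(rates.gamma / rates.delta)) if rates.delta > 0 else 0
    return w0, p0


def gillespie_run(
    slots: Sequence[int],
    rates: RateConstants,
    t_end: float,
    seed: int,
    w0: Optional[Sequence[int]] = None,
    p0: Optional[int] = None,
    sample_dt: float = DEFAULT_SAMPLE_DT,
) -> StochasticRun:
    """Exact SSA run sampled on a fixed grid.

    Starts from the rounded long-term fixed point unless (w0, p0) are
    given.  If all propensities vanish before ``t_end`` the state is
    frozen for the remainder of the run.  Identical seeds reproduce
    identical runs bit for bit.
    """
    s = np.asarray(slots, dtype=np.int64)
    if np.any(s < 0):
        raise ValueError("slot counts must be non-negative integers")
    N = s.size
    if w0 is None or p0 is None:
        w_init, p_init = stationary_initial_state(rates, s)
        if w0 is None:
            w0 = w_init
        if p0 is None:
            p0 = p_init
    w = np.asarray(w0, dtype=np.int64).copy()
    p = int(p0)
    if np.any(w < 0) or np.any(w > s) or p < 0:
        raise ValueError("initial state must satisfy 0 <= w_i <= s_i, p >= 0")
    if sample_dt <= 0 or t_end <= 0:
        raise ValueError("t_end and sample_dt must be positive")

    rng = np.random.default_rng(seed)
    n_samples = int(round(t_end / sample_dt)) + 1
    sample_times = np.arange(n_samples) * sample_dt
    w_out = np.empty((n_samples, N), dtype=np.int64)
    p_out = np.empty(n_samples, dtype=np.int64)
    counts = {"bind": 0, "unbind": 0, "externalize": 0, "internalize": 0}

    alpha, beta, gamma, delta = rates.alpha, rates.beta, rates.gamma, rates.delta
    t = 0.0
    next_sample = 0
    prop = np.empty(2 * N + 2)
    while next_sample < n_samples:
        prop[:N] = alpha * p * (s - w)
        prop[N : 2 * N] = beta * w
        prop[2 * N] = gamma
        prop[2 * N + 1] = delta * p
        total = float(prop.sum())
        if total <= 0.0:
            t_next = np.inf  # frozen state: fill remaining samples
        else:
            t_next = t + rng.exponential(1.0 / total)
        while next_sample < n_samples and sample_times[next_sample] <= t_next:
            w_out[next_sample] = w
            p_out[next_sample] = p
            next_sample += 1
        if t_next > t_end or not np.isfinite(t_next):
            break
        t = t_next
        cum = np.cumsum(prop)
        j = int(np.searchsorted(cum, rng.random() * total, side="right"))
        j = min(j, 2 * N + 1)
        if j < N:
            w[j] += 1
            p -= 1
            counts["bind"] += 1
        elif j < 2 * N:
            w[j - N] -= 1
            p += 1
            counts["unbind"] += 1
        elif j == 2 * N:
            p += 1
            counts["externalize"] += 1
        else:
            p -= 1
            counts["internalize"] += 1
    # any samples not yet written (frozen state) keep the last state
    while next_sample < n_samples:
        w_out[next_sample] = w
        p_out[next_sample] = p
        next_sample += 1

    return StochasticRun(
        seed=seed,
        times=sample_times,
        w=w_out,
        p=p_out,
        slots=s,
        rates=rates,
        event_counts=counts,
    )


def validate_against_ode(
    rates: RateConstants,
    slots: Sequence[int],
    n_runs: int,
    t_end: float,
    seeds: Sequence[int],
    w0: Optional[Sequence[int]] = None,
    p0: Optional[int] = None,
    sample_dt: float = 0.1,
    dt_ode: float = 0.002,
) -> Dict[str, float]:
    """Compare ensemble-mean SSA trajectories with the Euler ODE solution.

    Returns the maximum absolute z-score (mean minus ODE prediction over
    the standard error of the ensemble mean) across samples, separately
    for each synapse's w_i and the pool.  Validates that the stochastic
    model's average behavior matches the mean-field equations.
    """
    from .dynamics import SystemState, integrate

    if n_runs < 2:
        raise ValueError("need at least 2 runs for a standard error")
    seeds = list(seeds)[:n_runs]
    if len(seeds) < n_runs:
        raise ValueError("not enough seeds supplied")
    s = np.asarray(slots, dtype=np.int64)
    if w0 is None or p0 is None:
        w_init, p_init = stationary_initial_state(rates, s)
        w0 = w_init if w0 is None else w0
        p0 = p_init if p0 is None else p0

    runs = [
        gillespie_run(s, rates, t_end, seed, w0=w0, p0=p0, sample_dt=sample_dt)
        for seed in seeds
    ]
    w_stack = np.stack([r.w for r in runs]).astype(float)  # (runs, samples, N)
    p_stack = np.stack([r.p for r in runs]).astype(float)

    state0 = SystemState(t=0.0, s=s.astype(float), w=np.asarray(w0, float), p=float(p0))
    traj = integrate(state0, rates, t_end=t_end, dt=dt_ode, sample_every=sample_dt)
    n = min(traj.times.size, runs[0].times.size)

    def max_z(stack: np.ndarray, ref: np.ndarray) -> float:
        mean = stack.mean(axis=0)[:n]
        se = stack.std(axis=0, ddof=1)[:n] / np.sqrt(len(runs))
        resid = np.abs(mean - ref[:n])
        z = np.where(se > 0, resid / np.maximum(se, 1e-300), np.where(resid > 0, np.inf, 0.0))
        return float(z.max())

    report = {
        "n_runs": float(len(runs)),
        "max_z_p": max_z(p_stack, traj.p),
        "max_z_w": max(
            max_z(w_stack[:, :, i], traj.w[:, i]) for i in range(s.size)
        ),
    }
    return report
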