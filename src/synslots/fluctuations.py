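"""Spontaneous efficacy fluctuations and their power-law scaling.

At the stochastic steady state a synapse's bound-receptor count
fluctuates around its mean F*s_i.  The coefficient of variation

    CV_i = 100 * sd(w_i) / mean(w_i)    [percent]

declines approximately with one over the square root of the mean
occupancy: fitting CV = a*(F*s)^b by ordinary least squares in log10
space yields exponents b near -1/2.  In the large-pool limit the slots
fill independently (binomial occupancy), predicting
CV = 100*sqrt((1-F)/(F*s)), i.e. a = 100*sqrt(1-F) and b = -1/2; a
small pool adds correlations that steepen and raise the curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gillespie import DEFAULT_BURN_IN, StochasticRun, gillespie_run
from .params import (
    DEFAULT_BETA,
    DEFAULT_DELTA,
    DEFAULT_PHI,
    RateConstants,
    filling_fraction,
)

__all__ = [
    "PowerLawFit",
    "cv_per_synapse",
    "binomial_cv",
    "fit_power_law",
    "cv_experiment",
]

DEFAULT_SLOTS = (1, 2, 5, 10, 20, 50, 100)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(CV%) against log10(mean occupancy)."""

    a: float  # CV% at unit mean occupancy (10^intercept)
    b: float  # exponent (slope in log-log space)
    stderr_b: float
    r_squared: float
    n_points: int


def cv_per_synapse(run: StochasticRun, burn_in: float = DEFAULT_BURN_IN) -> np.ndarray:
    """Per-synapse CV (%) of the bound-receptor count after burn-in.

    Synapses whose post-burn-in mean occupancy is zero have an
    undefined CV and are reported as NaN (excluded from fits).
    """
    if burn_in >= run.times[-1]:
        raise ValueError("burn-in must be shorter than the run")
    w = run.w[run.times >= burn_in].astype(float)
    mean = w.mean(axis=0)
    sd = w.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    return cv


def binomial_cv(F: float, slots) -> np.ndarray:
    """Independent-slot (large pool) prediction: 100*sqrt((1-F)/(F*s))."""
    s = np.asarray(slots, dtype=float)
    return 100.0 * np.sqrt((1.0 - F) / (F * s))


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> PowerLawFit:
    """Fit y = a * x^b by unweighted OLS on (log10 x, log10 y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two (x, y) pairs")
    if np.any(x <= 0) or np.any(y <= 0) or not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("power-law fit requires positive finite x and y")
    res = stats.linregress(np.log10(x), np.log10(y))
    return PowerLawFit(
        a=float(10.0 ** res.intercept),
        b=float(res.slope),
        stderr_b=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
    )


def _average_cvs(
    rates: RateConstants,
    slots: Sequence[int],
    n_runs: int,
    duration: float,
    burn_in: float,
    seeds: Sequence[int],
    sample_dt: float,
) -> np.ndarray:
    cvs = np.stack(
        [
            cv_per_synapse(
                gillespie_run(slots, rates, duration, seed, sample_dt=sample_dt),
                burn_in=burn_in,
            )
            for seed in list(seeds)[:n_runs]
        ]
    )
    return np.nanmean(cvs, axis=0)


def cv_experiment(
    mode: str = "filling",
    grid: Sequence[float] = (0.5, 0.7, 0.9),
    slots: Sequence[int] = DEFAULT_SLOTS,
    phi: float = DEFAULT_PHI,
    alpha_fixed: float = 0.0093,
    beta: float = DEFAULT_BETA,
    delta: float = DEFAULT_DELTA,
    n_runs: int = 10,
    duration: float = 30.0,
    burn_in: float = DEFAULT_BURN_IN,
    sample_dt: float = 1.0 / 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fluctuation scaling across a parameter grid.

    ``mode='filling'``: vary the target filling fraction F over ``grid``
    at fixed relative pool size ``phi``, calibrating alpha and gamma.
    ``mode='pool'``: hold alpha fixed at ``alpha_fixed`` and vary the
    target phi over ``grid``, setting gamma accordingly (the filling
    fraction then co-varies).

    For each grid point runs ``n_runs`` independent SSA simulations of
    ``duration`` simulated minutes, averages each synapse's CV across
    runs, and fits the CV power law against the theoretical mean
    occupancies F*s_i.  Seeds are spawned deterministically from
    ``seed``, so repeated calls reproduce the same table.
    """
    if mode not in ("filling", "pool"):
        raise ValueError("mode must be 'filling' or 'pool'")
    if not len(grid):
        raise ValueError("grid must be non-empty")
    S = float(np.sum(slots))
    child_seeds = np.random.SeedSequence(seed).spawn(len(grid))
    rows = []
    for point, ss in zip(grid, child_seeds):
        if mode == "filling":
            rates = RateConstants.from_targets(point, phi, S, beta=beta, delta=delta)
            F, phi_point = point, phi
        else:
            rates = RateConstants.with_fixed_alpha(point, S, alpha_fixed, beta=beta, delta=delta)
            F, phi_point = filling_fraction(rates), point
        run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]
        cvs = _average_cvs(rates, slots, n_runs, duration, burn_in, run_seeds, sample_dt)
        occ = F * np.asarray(slots, dtype=float)
        ok = np.isfinite(cvs) & (cvs > 0)
        fit = fit_power_law(occ[ok], cvs[ok])
        rows.append(
            {
                "mode": mode,
                "F": F,
                "phi": phi_point,
                "alpha": rates.alpha,
                "gamma": rates.gamma,
                "a": fit.a,
                "b": fit.b,
                "stderr_b": fit.stderr_b,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows)
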