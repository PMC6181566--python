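"""Closed-form steady states on the two timescales of the model.

Receptor binding/unbinding to slots (seconds) is much faster than
receptor turnover at the surface (minutes).  The model therefore has

* a **long-term** fixed point where the pool equilibrates at
  ``p_inf = gamma/delta`` and every synapse holds ``w_i = F*s_i``, and
* a **fast-timescale** quasi-steady state at fixed total receptor
  number R (turnover frozen), where the total bound receptor number
  W* solves the quadratic ``W*^2 - W*(S+R+rho) + R*S = 0`` with
  ``rho = beta/alpha``; only the '-' root is physical
  (the '+' root exceeds min(S, R)).

The fast filling fraction ``F* = W*/S`` is again identical for all
synapses, so any redistribution of receptors acts multiplicatively.
F* is most sensitive to the rate ratio rho when R = S, where the
derivative dF*/drho diverges as rho -> 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .params import RateConstants, filling_fraction

__all__ = [
    "SteadyState",
    "FastEquilibrium",
    "long_term_steady_state",
    "fast_equilibrium",
    "fast_equilibrium_unstable_root",
    "max_fast_filling_fraction",
    "fast_filling_sensitivity",
]


@dataclass(frozen=True)
class SteadyState:
    """Long-term fixed point of the full model."""

    F: float
    p_inf: float
    w_inf: np.ndarray
    W_inf: float
    R_inf: float


@dataclass(frozen=True)
class FastEquilibrium:
    """Quasi-steady state at fixed total receptor number R."""

    W_star: float
    F_star: float
    p_star: float
    w_star: Optional[np.ndarray] = None


def long_term_steady_state(rates: RateConstants, slots: Sequence[float]) -> SteadyState:
    """Fixed point of the full dynamics, independent of initial conditions.

    ``p_inf = gamma/delta``, ``w_i = F*s_i``, ``R_inf = gamma/delta + F*S``.
    """
    s = np.asarray(slots, dtype=float)
    if np.any(s < 0):
        raise ValueError("slot counts must be non-negative")
    if rates.delta == 0:
        raise ValueError("no finite pool fixed point for delta = 0")
    F = filling_fraction(rates)
    p_inf = rates.gamma / rates.delta
    w_inf = F * s
    W_inf = float(w_inf.sum())
    return SteadyState(F=F, p_inf=p_inf, w_inf=w_inf, W_inf=W_inf, R_inf=p_inf + W_inf)


def _check_fast_args(R: float, S: float, rho: float) -> None:
    if R < 0 or S < 0 or rho < 0:
        raise ValueError(f"R, S and rho must be non-negative, got ({R}, {S}, {rho})")


def _stable_root(R: float, S: float, rho: float) -> float:
    # '-' root of W^2 - W(S+R+rho) + RS = 0, evaluated as 2RS/(b+sqrt(disc))
    # to avoid catastrophic cancellation near R=S, rho->0.
    b = S + R + rho
    disc = b * b - 4.0 * R * S  # = (S-R)^2 + rho^2 + 2*rho*(S+R) >= 0
    denom = b + math.sqrt(max(disc, 0.0))
    if denom == 0.0:
        return 0.0
    return 2.0 * R * S / denom


def fast_equilibrium(
    R: float, S: float, rho: float, slots: Optional[Sequence[float]] = None
) -> FastEquilibrium:
    """Quasi-steady state of receptor redistribution at fixed R.

    Returns the physical ('-') root W*, the common filling fraction
    ``F* = W*/S``, the pool ``p* = R - W*`` and, if a slot vector is
    supplied, the per-synapse occupancies ``w_i* = F* s_i``.
    """
    _check_fast_args(R, S, rho)
    W = _stable_root(R, S, rho)
    F_star = W / S if S > 0 else 0.0
    w_star = None
    if slots is not None:
        w_star = F_star * np.asarray(slots, dtype=float)
    return FastEquilibrium(W_star=W, F_star=F_star, p_star=R - W, w_star=w_star)


def fast_equilibrium_unstable_root(R: float, S: float, rho: float) -> float:
    """The '+' root of the same quadratic; exceeds min(S, R), unphysical.

    Exposed for verification only; it is never a valid bound-receptor count.
    """
    _check_fast_args(R, S, rho)
    b = S + R + rho
    disc = b * b - 4.0 * R * S
    return 0.5 * (b + math.sqrt(max(disc, 0.0)))


def max_fast_filling_fraction(R: float, S: float) -> float:
    """Limit of F* as rho -> 0+: min(1, R/S)."""
    if S <= 0:
        raise ValueError("S must be positive")
    if R < 0:
        raise ValueError("R must be non-negative")
    return min(1.0, R / S)


def fast_filling_sensitivity(R: float, S: float, rho: float) -> float:
    """dF*/drho: sensitivity of the fast filling fraction to beta/alpha.

    Always negative (more unbinding lowers occupancy).  At rho = 0,

        dF*/drho = (1/(2S)) * (1 - (R+S)/|R-S|),

    which diverges to -inf when R = S: the filling fraction reacts
    most sensitively exactly when receptor and slot numbers match.
    The divergence is reported as ``-inf`` rather than raising.
    """
    _check_fast_args(R, S, rho)
    if S == 0:
        raise ValueError("S must be positive")
    b = R + S + rho
    disc = 0.25 * b * b - R * S
    if disc <= 0.0:
        # only possible at rho = 0, R = S
        return -math.inf
    return (0.5 - 0.25 * b / math.sqrt(disc)) / S
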