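"""Reduced slow dynamics of the total receptor number.

Under the separation of timescales, receptor redistribution among the
slots equilibrates essentially instantaneously, so the only slow
variable is the total receptor number R = W + p.  Replacing the pool by
its fast quasi-steady value p*(R) = R - W*(R) gives the scalar ODE

    dR/dt = gamma + delta * F*(R) * S - delta * R,

with F*(R) from the fast equilibrium at rho = beta/alpha.  Starting
from R ~ 0 the system first accumulates receptors at rate ~gamma; once
the filling fraction saturates near its long-term value F, R relaxes
exponentially to ``gamma/delta + F*S`` with time constant 1/delta.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .params import RateConstants
from .steady import fast_equilibrium

__all__ = ["reduced_rdot", "integrate_reduced"]


def reduced_rdot(R: float, rates: RateConstants, S: float) -> float:
    """dR/dt of the reduced one-dimensional dynamics."""
    if R < 0 or S < 0:
        raise ValueError("R and S must be non-negative")
    F_star = fast_equilibrium(R, S, rates.rho).F_star
    return rates.gamma + rates.delta * F_star * S - rates.delta * R


def integrate_reduced(
    R0: float,
    rates: RateConstants,
    S: float,
    t_end: float,
    dt: float = 0.01,
) -> Tuple[np.ndarray, np.ndarray]:
    """Euler trajectory of the reduced dynamics; returns (times, R).

    Converges monotonically to ``gamma/delta + F*S`` from any R0 >= 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if R0 < 0:
        raise ValueError("R0 must be non-negative")
    n_steps = int(round(t_end / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    R = np.empty(n_steps + 1)
    R[0] = R0
    for k in range(n_steps):
        R[k + 1] = max(R[k] + dt * reduced_rdot(R[k], rates, S), 0.0)
    return times, R
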