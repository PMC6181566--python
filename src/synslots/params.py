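"""Kinetic parameters of the receptor--slot competition model.

A local group of N synapses competes for neurotransmitter receptors
(e.g. AMPA receptor complexes) from a shared dendritic pool.  Four
mass-action rates govern the dynamics:

* ``alpha`` -- binding of a pooled receptor to an empty slot,
  per (receptor x empty slot) per minute,
* ``beta``  -- unbinding of a slot-bound receptor back into the pool,
  per bound receptor per minute,
* ``gamma`` -- externalization (addition) of new receptors to the pool,
  receptors per minute,
* ``delta`` -- internalization (removal) of pooled receptors,
  per pooled receptor per minute.

The canonical time unit everywhere in this package is the **minute**.
Rates quoted in the literature as inverse mean lifetimes (e.g.
``beta = (43 s)^-1``) are stored as ``60/43`` per minute.

Two dimensionless targets summarize the steady state and are used for
calibration: the filling fraction ``F`` (fraction of slots occupied,
``F = 1/(1 + beta*delta/(alpha*gamma))``) and the relative pool size
``phi = p_inf / W_inf`` (pooled over synaptically bound receptors).
Given (F, phi, total slots S) and the measured beta, delta, the unknown
rates follow from

    gamma = delta * phi * F * S
    alpha = beta / (phi * S * (1 - F))

Alternatively, holding alpha fixed and targeting a pool size phi gives

    gamma = delta * (S*phi - beta/alpha)

with an implied filling fraction ``F = 1 - beta/(alpha*phi*S)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LN2",
    "DEFAULT_BETA",
    "DEFAULT_DELTA",
    "DEFAULT_PHI",
    "DEFAULT_F_CHOICES",
    "RateConstants",
    "DerivedQuantities",
    "minutes",
    "per_minute",
    "halflife_to_rate",
    "filling_fraction",
    "calibrate_alpha",
    "calibrate_gamma",
    "gamma_for_pool_with_fixed_alpha",
    "implied_filling_fraction",
    "relative_pool_size",
    "derived_quantities",
]

LN2 = math.log(2.0)

#: Unbinding rate from slots, (43 s)^-1 expressed per minute.
DEFAULT_BETA = 60.0 / 43.0
#: Internalization rate, (14 min)^-1.
DEFAULT_DELTA = 1.0 / 14.0
#: Relative pool size p_inf/W_inf of mature hippocampal cultures (72%/28%).
DEFAULT_PHI = 2.67
#: Filling fractions explored throughout: half, moderately and nearly full.
DEFAULT_F_CHOICES = (0.5, 0.7, 0.9)

_MINUTES_PER_UNIT = {
    "s": 1.0 / 60.0,
    "sec": 1.0 / 60.0,
    "second": 1.0 / 60.0,
    "seconds": 1.0 / 60.0,
    "min": 1.0,
    "minute": 1.0,
    "minutes": 1.0,
    "h": 60.0,
    "hour": 60.0,
    "hours": 60.0,
    "d": 1440.0,
    "day": 1440.0,
    "days": 1440.0,
}


def minutes(value: float, unit: str = "min") -> float:
    """Convert a duration given in ``unit`` to minutes."""
    try:
        factor = _MINUTES_PER_UNIT[unit]
    except KeyError:
        raise ValueError(f"unknown time unit {unit!r}") from None
    return value * factor


def per_minute(value: float, unit: str = "min") -> float:
    """Convert a rate given per ``unit`` to per minute.

    ``per_minute(1/43, 's')`` is the slot-unbinding rate beta of a
    receptor with a 43 s mean dwell time.
    """
    return value / minutes(1.0, unit)


def halflife_to_rate(halflife: float, unit: str = "min") -> float:
    """First-order rate constant (per minute) from a half-life.

    The mean lifetime of the exponential process is ``halflife/ln 2``;
    a 10 min surface half-life gives a mean pool dwell time of ~14 min.
    """
    h = minutes(halflife, unit)
    if h <= 0:
        raise ValueError(f"half-life must be positive, got {halflife} {unit}")
    return LN2 / h


@dataclass(frozen=True)
class RateConstants:
    """The four kinetic rates, all per minute (gamma: receptors per minute)."""

    alpha: float
    beta: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "delta"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def rho(self) -> float:
        """Unbinding/binding ratio beta/alpha (in receptor-count units)."""
        if self.alpha == 0:
            raise ZeroDivisionError("rho undefined for alpha = 0")
        return self.beta / self.alpha

    @property
    def removal_ratio(self) -> float:
        """(beta*delta)/(alpha*gamma), the control parameter of F."""
        denom = self.alpha * self.gamma
        if denom == 0:
            raise ZeroDivisionError("removal ratio undefined for alpha*gamma = 0")
        return (self.beta * self.delta) / denom

    @classmethod
    def from_targets(
        cls,
        F: float,
        phi: float = DEFAULT_PHI,
        S: float = 188.0,
        beta: float = DEFAULT_BETA,
        delta: float = DEFAULT_DELTA,
    ) -> "RateConstants":
        """Calibrate alpha and gamma from target filling fraction and pool size."""
        return cls(
            alpha=calibrate_alpha(F, phi, S, beta),
            beta=beta,
            gamma=calibrate_gamma(F, phi, S, delta),
            delta=delta,
        )

    @classmethod
    def with_fixed_alpha(
        cls,
        phi: float,
        S: float,
        alpha: float,
        beta: float = DEFAULT_BETA,
        delta: float = DEFAULT_DELTA,
    ) -> "RateConstants":
        """Hold alpha fixed; choose gamma so the steady state has pool ratio phi."""
        return cls(
            alpha=alpha,
            beta=beta,
            gamma=gamma_for_pool_with_fixed_alpha(phi, S, alpha, beta, delta),
            delta=delta,
        )


@dataclass(frozen=True)
class DerivedQuantities:
    """Dimensionless summary of a parameterization at total slot count S."""

    F: float
    phi: float
    rho: float
    removal_ratio: float
    S: float


def filling_fraction(rates: RateConstants) -> float:
    """Long-term filling fraction F = 1/(1 + beta*delta/(alpha*gamma)).

    Every synapse's steady-state occupancy is ``w_i = F * s_i``; F is
    shared by the whole local group.
    """
    ag = rates.alpha * rates.gamma
    bd = rates.beta * rates.delta
    if ag == 0:
        if bd > 0:
            return 0.0
        raise ValueError("filling fraction undefined: alpha*gamma = beta*delta = 0")
    return 1.0 / (1.0 + bd / ag)


def calibrate_alpha(F: float, phi: float, S: float, beta: float = DEFAULT_BETA) -> float:
    """Binding rate achieving filling fraction F: alpha = beta/(phi*S*(1-F))."""
    if not 0.0 < F < 1.0:
        raise ValueError(f"target filling fraction must be in (0, 1), got {F}")
    if phi <= 0 or S <= 0:
        raise ValueError("phi and S must be positive for alpha calibration")
    return beta / (phi * S * (1.0 - F))


def calibrate_gamma(F: float, phi: float, S: float, delta: float = DEFAULT_DELTA) -> float:
    """Externalization rate achieving pool ratio phi: gamma = delta*phi*F*S.

    Equivalently ``gamma/delta = p_inf = phi*F*S``.
    """
    if min(F, phi, S, delta) < 0:
        raise ValueError("calibrate_gamma requires non-negative inputs")
    return delta * phi * F * S


def gamma_for_pool_with_fixed_alpha(
    phi: float,
    S: float,
    alpha: float,
    beta: float = DEFAULT_BETA,
    delta: float = DEFAULT_DELTA,
) -> float:
    """Externalization rate for pool ratio phi with alpha held fixed.

    gamma = delta*(S*phi - beta/alpha); the implied filling fraction is
    ``1 - beta/(alpha*phi*S)``.  The target is unreachable when
    ``S*phi < beta/alpha`` (the pool would have to be negative); equality
    sits on the boundary and yields gamma = 0.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if phi < 0 or S < 0:
        raise ValueError("phi and S must be non-negative")
    excess = S * phi - beta / alpha
    if excess < 0:
        raise ValueError(
            f"pool target unreachable with fixed alpha: S*phi = {S * phi:g} "
            f"< beta/alpha = {beta / alpha:g}"
        )
    return delta * excess


def implied_filling_fraction(
    phi: float, S: float, alpha: float, beta: float = DEFAULT_BETA
) -> float:
    """Filling fraction implied by the fixed-alpha pool calibration."""
    if alpha <= 0 or phi <= 0 or S <= 0:
        raise ValueError("alpha, phi and S must be positive")
    return 1.0 - beta / (alpha * phi * S)


def relative_pool_size(p: float, W: float) -> float:
    """Relative pool size phi = p/W (pooled over bound receptors)."""
    if W <= 0:
        raise ValueError(f"relative pool size undefined for total bound W = {W}")
    return p / W


def derived_quantities(rates: RateConstants, slots) -> DerivedQuantities:
    """Dimensionless summary (F, phi, rho, removal ratio) for a slot vector."""
    S = float(sum(slots))
    F = filling_fraction(rates)
    if rates.delta == 0:
        raise ValueError("phi undefined for delta = 0 (no pool fixed point)")
    W_inf = F * S
    phi = (rates.gamma / rates.delta) / W_inf if W_inf > 0 else math.inf
    return DerivedQuantities(
        F=F, phi=phi, rho=rates.rho, removal_ratio=rates.removal_ratio, S=S
    )
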