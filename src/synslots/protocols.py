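"""Scripted plasticity experiments on the receptor--slot model.

* pool steps: sudden doubling/zeroing of the dendritic receptor pool,
  demonstrating fast multiplicative scaling of all synapses;
* slot steps: instantaneous growth of slot numbers in stimulated
  synapses, inducing homosynaptic potentiation plus a *transient*
  heterosynaptic depression of the unstimulated synapses that recovers
  on the slow receptor-turnover timescale 1/delta;
* a waveform-driven LTP model: the stimulated synapses' binding rate
  alpha ramps to 4x over 17 s and linearly returns within 2 min
  (CaMKII activation time course), while spine volume rises
  sigmoidally to 5x over 2 min and decays exponentially (tau = 5 min)
  to a sustained 2x; slot counts scale with volume^(2/3) (surface
  area scaling);
* the lognormal slot-count sampler used to illustrate multiplicative
  scaling across a realistic weight distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dynamics import (
    DEFAULT_DT,
    DEFAULT_SAMPLE_EVERY,
    Event,
    Trajectory,
    integrate,
    steady_initial_state,
)
from .params import RateConstants, calibrate_alpha
from .steady import fast_equilibrium

__all__ = [
    "Segment",
    "Waveform",
    "LTPSpec",
    "ltp_alpha_factor",
    "ltp_volume_factor",
    "pool_step_protocol",
    "slot_step_protocol",
    "heterosynaptic_change_curve",
    "ltp_protocol",
    "ltp_peak_sweep",
    "lognormal_slot_sampler",
]


@dataclass(frozen=True)
class Segment:
    """One piece of a piecewise waveform on [t0, t1)."""

    t0: float
    t1: float
    fn: Callable[[np.ndarray], np.ndarray]


class Waveform:
    """Piecewise-defined, continuous time course.

    Before the first segment the waveform sits at ``baseline``; between
    and after segments it holds the last segment's end value.  Factories
    below guarantee continuity at the joins.
    """

    def __init__(self, baseline: float, segments: Sequence[Segment]):
        self.baseline = float(baseline)
        self.segments = sorted(segments, key=lambda seg: seg.t0)

    def value(self, t):
        t_arr = np.asarray(t, dtype=float)
        out = np.full(t_arr.shape, self.baseline)
        for seg in self.segments:
            in_seg = (t_arr >= seg.t0) & (t_arr < seg.t1)
            if np.any(in_seg):
                out[in_seg] = seg.fn(t_arr[in_seg])
            after = t_arr >= seg.t1
            if np.any(after) and np.isfinite(seg.t1):
                out[after] = seg.fn(np.asarray(seg.t1))
        return out if out.ndim else float(out)

    __call__ = value


def ltp_alpha_factor(
    onset: float,
    peak: float = 4.0,
    rise: float = 17.0 / 60.0,
    fall: float = 2.0,
) -> Waveform:
    """Relative change of the binding rate during LTP induction.

    Linear rise from 1x to ``peak`` over ``rise`` minutes, then linear
    return to baseline over ``fall`` minutes.
    """
    t1 = onset + rise
    t2 = t1 + fall
    return Waveform(
        1.0,
        [
            Segment(onset, t1, lambda t: 1.0 + (peak - 1.0) * (t - onset) / rise),
            Segment(t1, t2, lambda t: peak - (peak - 1.0) * (t - t1) / fall),
        ],
    )


def ltp_volume_factor(
    onset: float,
    peak: float = 5.0,
    sustained: float = 2.0,
    rise: float = 2.0,
    tau: float = 5.0,
) -> Waveform:
    """Relative spine-volume change during LTP induction.

    Sigmoidal (logistic) rise from 1x to ``peak`` over ``rise`` minutes
    -- midpoint at the half-rise, steepness chosen so the raw logistic
    covers 1%..99% of its amplitude across the rise window, then pinned
    so the endpoints are met exactly -- followed by exponential decay
    to ``sustained`` with time constant ``tau`` minutes.
    """
    t_mid = onset + rise / 2.0
    k = 2.0 * math.log(99.0) / rise
    sig0 = 1.0 / (1.0 + math.exp(k * rise / 2.0))
    sig1 = 1.0 / (1.0 + math.exp(-k * rise / 2.0))

    def logistic(t):
        sig = 1.0 / (1.0 + np.exp(-k * (np.asarray(t) - t_mid)))
        return 1.0 + (peak - 1.0) * (sig - sig0) / (sig1 - sig0)

    t_peak = onset + rise

    def decay(t):
        return sustained + (peak - sustained) * np.exp(-(np.asarray(t) - t_peak) / tau)

    return Waveform(1.0, [Segment(onset, t_peak, logistic), Segment(t_peak, math.inf, decay)])


@dataclass(frozen=True)
class LTPSpec:
    """Waveform parameters of the homosynaptic LTP model."""

    stimulated: Tuple[int, ...] = (1, 2)  # 0-based indices
    onset: float = 2.0  # minutes
    alpha_peak: float = 4.0
    alpha_rise: float = 17.0 / 60.0
    alpha_fall: float = 2.0
    volume_peak: float = 5.0
    volume_sustained: float = 2.0
    volume_rise: float = 2.0
    volume_tau: float = 5.0
    slot_exponent: float = 2.0 / 3.0

    def alpha_waveform(self) -> Waveform:
        return ltp_alpha_factor(self.onset, self.alpha_peak, self.alpha_rise, self.alpha_fall)

    def volume_waveform(self) -> Waveform:
        return ltp_volume_factor(
            self.onset, self.volume_peak, self.volume_sustained,
            self.volume_rise, self.volume_tau,
        )

    def slot_factor(self, t):
        """Relative slot-count change: (volume factor)^(2/3)."""
        return np.asarray(self.volume_waveform().value(t)) ** self.slot_exponent


def _relative_series(traj: Trajectory) -> pd.DataFrame:
    return traj.relative_change(baseline_index=0)


def pool_step_protocol(
    rates: RateConstants,
    slots: Sequence[float] = (40.0, 60.0, 80.0),
    step: float = 2.0,
    t_step: float = 2.0,
    t_end: float = 60.0,
    dt: float = DEFAULT_DT,
    sample_every: float = DEFAULT_SAMPLE_EVERY,
) -> Tuple[Trajectory, pd.DataFrame]:
    """Pool manipulation: scale the pool by ``step`` (0 empties it).

    Starts at the long-term fixed point; all synapses change by the
    same relative factor at every time (multiplicative scaling), and
    the system slowly returns to the original fixed point.
    """
    state0 = steady_initial_state(rates, slots)
    if step == 0.0:
        event = Event(time=t_step, kind="set_pool", value=0.0)
    else:
        event = Event(time=t_step, kind="scale_pool", value=step)
    traj = integrate(state0, rates, schedule=[event], t_end=t_end, dt=dt,
                     sample_every=sample_every)
    return traj, _relative_series(traj)


def slot_step_protocol(
    rates: RateConstants,
    slots: Sequence[float] = (20.0, 40.0, 60.0, 80.0),
    targets: Tuple[int, ...] = (0, 2),
    factor: float = 2.0,
    t_step: float = 2.0,
    t_end: float = 90.0,
    dt: float = DEFAULT_DT,
    sample_every: float = DEFAULT_SAMPLE_EVERY,
) -> Tuple[Trajectory, pd.DataFrame]:
    """Instantaneous slot growth in the target synapses.

    Returns the trajectory and a series with the mean relative change
    of stimulated (``homo``) and unstimulated (``hetero``) synapses.
    The heterosynaptic depression is transient: it recovers on the
    1/delta timescale while the stimulated synapses stay elevated.
    """
    state0 = steady_initial_state(rates, slots)
    event = Event(time=t_step, kind="scale_slots", value=factor, targets=tuple(targets))
    traj = integrate(state0, rates, schedule=[event], t_end=t_end, dt=dt,
                     sample_every=sample_every)
    rel = _relative_series(traj)
    n = traj.n_synapses
    homo_cols = [f"rel_w_{i + 1}" for i in targets]
    hetero_cols = [f"rel_w_{i + 1}" for i in range(n) if i not in targets]
    rel["homo"] = rel[homo_cols].mean(axis=1)
    rel["hetero"] = rel[hetero_cols].mean(axis=1)
    return traj, rel


def heterosynaptic_change_curve(
    S_prime,
    F: float,
    phi: float,
    S: float,
    rho: Optional[float] = None,
):
    """Analytic peak heterosynaptic change (F* - F)/F after a slot step.

    The pre-induction system has total slots ``S``, filling fraction
    ``F`` and pool ratio ``phi`` (so R = (1+phi)*F*S receptors).
    Homosynaptic induction changes the total slot count to ``S_prime``
    while R is still unchanged; unstimulated synapses move to the fast
    equilibrium F*(R, S_prime), giving a relative change (F*-F)/F --
    negative for S' > S (hetero-LTD), positive for S' < S (hetero-LTP),
    and attenuated by large phi or F.

    ``rho`` defaults to the calibrated beta/alpha = phi*S*(1-F).
    """
    if rho is None:
        rho = phi * S * (1.0 - F)
    R = (1.0 + phi) * F * S
    S_prime_arr = np.atleast_1d(np.asarray(S_prime, dtype=float))
    out = np.array(
        [(fast_equilibrium(R, sp, rho).F_star - F) / F for sp in S_prime_arr]
    )
    return out if np.ndim(S_prime) else float(out[0])


def ltp_protocol(
    rates: RateConstants,
    slots: Sequence[float] = (20.0, 40.0, 60.0, 80.0),
    spec: LTPSpec = LTPSpec(),
    t_end: float = 32.0,
    dt: float = DEFAULT_DT,
    sample_every: float = DEFAULT_SAMPLE_EVERY,
) -> Tuple[Trajectory, pd.DataFrame, dict]:
    """Waveform-driven LTP in the stimulated synapses.

    Returns the trajectory, relative-change series and a dict with the
    peak relative homosynaptic change (max over stimulated synapses and
    time) and the peak heterosynaptic change (min over unstimulated).
    """
    slots0 = np.asarray(slots, dtype=float)
    n = slots0.size
    stim = np.zeros(n, dtype=bool)
    stim[list(spec.stimulated)] = True

    alpha_f = spec.alpha_waveform()
    vol_f = spec.volume_waveform()
    exponent = spec.slot_exponent
    base_alpha = rates.alpha

    def alpha_waveform(t: float) -> np.ndarray:
        a = np.full(n, base_alpha)
        a[stim] = base_alpha * alpha_f.value(t)
        return a

    def slot_waveform(t: float) -> np.ndarray:
        s = slots0.copy()
        s[stim] = slots0[stim] * vol_f.value(t) ** exponent
        return s

    state0 = steady_initial_state(rates, slots0)
    traj = integrate(
        state0, rates, t_end=t_end, dt=dt, sample_every=sample_every,
        alpha_waveform=alpha_waveform, slot_waveform=slot_waveform,
    )
    rel = _relative_series(traj)
    rel_w = rel[[f"rel_w_{i + 1}" for i in range(n)]].to_numpy()
    peaks = {
        "peak_homo": float(np.nanmax(rel_w[:, stim])),
        "peak_hetero": float(np.nanmin(rel_w[:, ~stim])) if (~stim).any() else math.nan,
    }
    return traj, rel, peaks


def ltp_peak_sweep(
    phi_grid: Sequence[float],
    F_values: Sequence[float] = (0.5, 0.7, 0.9),
    slots: Sequence[float] = (20.0, 40.0, 60.0, 80.0),
    spec: LTPSpec = LTPSpec(),
    beta: Optional[float] = None,
    delta: Optional[float] = None,
    t_end: float = 32.0,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Peak homo-/heterosynaptic changes over a (phi, F) grid.

    Peak homosynaptic LTP grows with the relative pool size phi (more
    receptors to recruit) and peak |hetero LTD| shrinks with phi (the
    pool buffers the unstimulated synapses); both are reduced by a
    high filling fraction.
    """
    from .params import DEFAULT_BETA, DEFAULT_DELTA

    if not len(phi_grid) or not len(F_values):
        raise ValueError("phi_grid and F_values must be non-empty")
    beta = DEFAULT_BETA if beta is None else beta
    delta = DEFAULT_DELTA if delta is None else delta
    S = float(np.sum(slots))
    rows = []
    for F in F_values:
        for phi in phi_grid:
            rates = RateConstants.from_targets(F, phi, S, beta=beta, delta=delta)
            _, _, peaks = ltp_protocol(rates, slots, spec, t_end=t_end, dt=dt)
            rows.append({"phi": phi, "F": F, **peaks})
    return pd.DataFrame(rows)


def lognormal_slot_sampler(
    n_synapses: int,
    mean: float = 1.0,
    sd: float = 0.2,
    target_mean_slots: float = 100.0,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Per-synapse slot counts from a scaled lognormal distribution.

    Draws are lognormal with the given mean and standard deviation *of
    the variate itself* (the underlying normal parameters are solved
    from them), then rescaled so the sample mean equals
    ``target_mean_slots`` exactly.
    """
    if n_synapses <= 0:
        raise ValueError("n_synapses must be positive")
    if mean <= 0 or sd < 0 or target_mean_slots <= 0:
        raise ValueError("mean and target_mean_slots must be positive, sd >= 0")
    if sd == 0:
        return np.full(n_synapses, float(target_mean_slots))
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n_synapses)
    return draws * (target_mean_slots / draws.mean())
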