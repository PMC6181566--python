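"""Deterministic (mean-field) dynamics of receptor--slot competition.

The full model is the coupled nonlinear ODE system

    dw_i/dt = -beta*w_i + alpha_i(t) * p * (s_i(t) - w_i)
    dp/dt   = -delta*p + gamma + sum_i beta*w_i
              - sum_i alpha_i(t) * p * (s_i(t) - w_i)

integrated with the forward Euler method.  Perturbation experiments are
expressed as instantaneous :class:`Event`s (pool scaling/setting, slot
scaling/setting) and/or smooth per-synapse waveforms for the binding
rate alpha_i(t) and the slot counts s_i(t) (used by the LTP protocol).

Slot-shrinking events or waveforms that would leave a synapse holding
more receptors than slots return the excess to the pool, conserving
receptor number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import RateConstants

__all__ = [
    "SystemState",
    "Event",
    "Trajectory",
    "derivatives",
    "integrate",
    "steady_initial_state",
]

#: Default Euler step, minutes. About 10x below the fastest relaxation
#: time 1/(beta + alpha*p) under the standard parameterization.
DEFAULT_DT = 0.005
#: Default sampling interval, minutes.
DEFAULT_SAMPLE_EVERY = 0.05

_EVENT_KINDS = ("scale_pool", "set_pool", "scale_slots", "set_slots")


@dataclass
class SystemState:
    """Instantaneous state: time, slot counts, bound receptors, pool."""

    t: float
    s: np.ndarray
    w: np.ndarray
    p: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.s.shape != self.w.shape or self.s.ndim != 1:
            raise ValueError("s and w must be 1-d arrays of equal length")
        if np.any(self.s < 0) or np.any(self.w < 0) or self.p < 0:
            raise ValueError("slot counts, occupancies and pool must be >= 0")
        if np.any(self.w > self.s * (1 + 1e-12) + 1e-12):
            raise ValueError("occupancy w_i must not exceed slot count s_i")

    @property
    def n_synapses(self) -> int:
        return self.s.size

    def copy(self) -> "SystemState":
        return SystemState(t=self.t, s=self.s.copy(), w=self.w.copy(), p=self.p)


@dataclass(frozen=True)
class Event:
    """Instantaneous perturbation applied at a scheduled time.

    ``scale_pool``/``set_pool`` act on the pool (targets ignored);
    ``scale_slots``/``set_slots`` act on the slot counts of the target
    synapse indices (all synapses if targets is None).
    """

    time: float
    kind: str
    value: float
    targets: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {_EVENT_KINDS}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.value < 0:
            raise ValueError("event value must be >= 0")


@dataclass
class Trajectory:
    """Time-sampled states plus derived totals W(t) and R(t)."""

    times: np.ndarray
    w: np.ndarray  # (n_samples, N)
    p: np.ndarray
    s: np.ndarray  # (n_samples, N)
    meta: dict = field(default_factory=dict)

    @property
    def W(self) -> np.ndarray:
        return self.w.sum(axis=1)

    @property
    def R(self) -> np.ndarray:
        return self.W + self.p

    @property
    def n_synapses(self) -> int:
        return self.w.shape[1]

    def final_state(self) -> SystemState:
        return SystemState(t=float(self.times[-1]), s=self.s[-1].copy(),
                           w=self.w[-1].copy(), p=float(self.p[-1]))

    def relative_change(self, baseline_index: int = 0) -> pd.DataFrame:
        """Per-synapse and pool relative changes vs an early baseline sample."""
        w0 = self.w[baseline_index]
        p0 = self.p[baseline_index]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_w = np.where(w0 > 0, (self.w - w0) / w0, np.nan)
            rel_p = (self.p - p0) / p0 if p0 > 0 else np.full_like(self.p, np.nan)
        data = {"time_min": self.times}
        for i in range(self.n_synapses):
            data[f"rel_w_{i + 1}"] = rel_w[:, i]
        data["rel_p"] = rel_p
        return pd.DataFrame(data)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_min": self.times}
        for i in range(self.n_synapses):
            data[f"w_{i + 1}"] = self.w[:, i]
        data["p"] = self.p
        data["W"] = self.W
        data["R"] = self.R
        return pd.DataFrame(data)


def derivatives(
    state: SystemState,
    rates: RateConstants,
    alpha_i: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, float]:
    """Time derivatives (dw, dp) of the full model at ``state``.

    ``alpha_i`` optionally overrides the binding rate per synapse
    (the time-varying LTP generalization); default is the common alpha.
    """
    s, w, p = state.s, state.w, state.p
    if alpha_i is None:
        a = rates.alpha
    else:
        a = np.asarray(alpha_i, dtype=float)
        if a.shape != s.shape:
            raise ValueError("alpha_i must match the number of synapses")
    binding = a * p * (s - w)
    dw = -rates.beta * w + binding
    dp = -rates.delta * p + rates.gamma + rates.beta * float(w.sum()) - float(
        np.sum(binding)
    )
    return dw, dp


def _apply_event(state: SystemState, event: Event) -> None:
    if event.kind == "scale_pool":
        state.p *= event.value
    elif event.kind == "set_pool":
        state.p = event.value
    else:
        idx = (
            np.arange(state.n_synapses)
            if event.targets is None
            else np.asarray(event.targets, dtype=int)
        )
        if event.kind == "scale_slots":
            state.s[idx] = state.s[idx] * event.value
        else:
            state.s[idx] = event.value
        _return_excess_to_pool(state)


def _return_excess_to_pool(state: SystemState) -> None:
    # slots shrunk below current occupancy: excess receptors rejoin the pool
    excess = np.maximum(state.w - state.s, 0.0)
    if excess.any():
        state.p += float(excess.sum())
        state.w = np.minimum(state.w, state.s)


def _clip_with_tolerance(state: SystemState, dt: float, tol: float) -> None:
    scale = max(1.0, float(state.s.max(initial=1.0)), abs(state.p))
    low = state.w.min(initial=0.0)
    over = float(np.max(state.w - state.s, initial=0.0))
    if low < -tol * scale or over > tol * scale or state.p < -tol * scale:
        raise RuntimeError(
            f"Euler step overshoot at t={state.t:.4f} min exceeds tolerance; "
            f"reduce dt (currently {dt} min)"
        )
    np.clip(state.w, 0.0, state.s, out=state.w)
    state.p = max(state.p, 0.0)


def integrate(
    state0: SystemState,
    rates: RateConstants,
    schedule: Sequence[Event] = (),
    t_end: float = 30.0,
    dt: float = DEFAULT_DT,
    sample_every: float = DEFAULT_SAMPLE_EVERY,
    alpha_waveform: Optional[Callable[[float], np.ndarray]] = None,
    slot_waveform: Optional[Callable[[float], np.ndarray]] = None,
    overshoot_tol: float = 1e-6,
) -> Trajectory:
    """Forward-Euler integration of the full model.

    Parameters
    ----------
    schedule
        Instantaneous events, applied atomically at the step whose time
        grid point is nearest their scheduled time.
    alpha_waveform, slot_waveform
        Optional callables ``t -> per-synapse array`` giving the
        absolute binding rates alpha_i(t) and slot counts s_i(t);
        re-evaluated every step.  Slot waveforms that drop below the
        current occupancy return the excess receptors to the pool.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_end < state0.t:
        raise ValueError("t_end must be >= initial time")
    state = state0.copy()
    n_steps = int(round((t_end - state.t) / dt))
    stride = max(1, int(round(sample_every / dt)))

    events = sorted(schedule, key=lambda e: e.time)
    event_steps = [int(round((e.time - state0.t) / dt)) for e in events]
    next_event = 0

    times, ws, ps, ss = [], [], [], []

    def record() -> None:
        times.append(state.t)
        ws.append(state.w.copy())
        ps.append(state.p)
        ss.append(state.s.copy())

    for k in range(n_steps + 1):
        while next_event < len(events) and event_steps[next_event] <= k:
            _apply_event(state, events[next_event])
            next_event += 1
        if slot_waveform is not None:
            state.s = np.asarray(slot_waveform(state.t), dtype=float)
            _return_excess_to_pool(state)
        if k % stride == 0 or k == n_steps:
            record()
        if k == n_steps:
            break
        alpha_i = None
        if alpha_waveform is not None:
            alpha_i = np.asarray(alpha_waveform(state.t), dtype=float)
        dw, dp = derivatives(state, rates, alpha_i=alpha_i)
        state.w = state.w + dt * dw
        state.p = state.p + dt * dp
        state.t = state0.t + (k + 1) * dt
        _clip_with_tolerance(state, dt, overshoot_tol)

    traj = Trajectory(
        times=np.asarray(times),
        w=np.asarray(ws),
        p=np.asarray(ps),
        s=np.asarray(ss),
        meta={"dt": dt, "sample_every": sample_every, "t_end": t_end,
              "events": [(e.time, e.kind, e.value, e.targets) for e in events]},
    )
    return traj


def steady_initial_state(rates: RateConstants, slots: Sequence[float]) -> SystemState:
    """System state at the long-term fixed point (the usual starting point)."""
    from .steady import long_term_steady_state

    ss = long_term_steady_state(rates, slots)
    s = np.asarray(slots, dtype=float)
    return SystemState(t=0.0, s=s, w=ss.w_inf.copy(), p=ss.p_inf)
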