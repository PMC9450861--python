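"""Per-gait-cycle iterative-learning adaptation of stimulation parameters.

Two feedback variables are measured each gait cycle and compared with
their mean over the previous five cycles:

* ``t_s`` — each channel's delivered stimulation time (total duration
  with amplitude strictly above C_min).  If the deviation ``dt = t_s(n)
  - mean(t_s over previous 5)`` exceeds 0.04 s in magnitude, the
  channel's time coefficient tau moves one step L = 0.01 s:
  ``tau + L`` for ``dt < -0.04``, ``tau - L`` for ``dt > 0.04``,
  clamped to [0.01, 1] s.  The channel's envelope cut-off frequency
  ``f_c = 1/(2*pi*tau)`` is recomputed after every update.

* ``phi_TO`` — the sagittal shank angle at toe-off, per side.  If its
  deviation from the 5-cycle mean exceeds 2 degrees in magnitude, the
  LG pulse width moves one step L_PW = 20 us (``+L_PW`` for
  ``dphi < -2``, ``-L_PW`` for ``dphi > 2``), clamped to [250, 500] us.

Deviations at exactly the threshold produce no update (strict
inequalities, dead zone).  No updates happen until the history ring
buffer holds five complete cycles (warm-up); the current cycle enters
the buffer only after it has been compared, so the buffer is strictly
the *previous* five cycles.

``flip_tau_sign`` inverts the tau update direction.  The default (off)
follows the printed update law; the flag exists because a shorter
stimulation time increasing tau lengthens the envelope, which for
gate-truncated bursts is the de-stabilizing direction.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .response_core import Muscle, Side, cutoff_frequency

Channel = tuple[Side, Muscle]

#: Printed iterative-learning constants.
L_STEP = 0.01           # tau step, seconds
L_PW = 20.0             # pulse-width step, microseconds
DT_THRESHOLD = 0.04     # stimulation-time dead zone, seconds
DPHI_THRESHOLD = 2.0    # toe-off angle dead zone, degrees
TAU_BOUNDS = (0.01, 1.0)
PW_BOUNDS = (250.0, 500.0)


class HistoryNotFull(RuntimeError):
    """Warm-up signal: fewer than five cycles recorded, no update performed."""


@dataclass(frozen=True)
class CycleMetrics:
    """Per-cycle feedback: stimulation times per channel, toe-off angle per side."""

    n: int
    t_s: dict                 # Channel -> seconds
    phi_to: dict = field(default_factory=dict)   # Side -> degrees

    def __post_init__(self) -> None:
        for ch, v in self.t_s.items():
            if v < 0:
                raise ValueError(f"negative stimulation time for {ch}: {v}")


@dataclass
class AdaptiveState:
    """Mutable parameter set: tau per channel, LG pulse width per side,
    plus the 5-cycle metrics ring buffer and the update constants."""

    tau: dict = field(default_factory=dict)       # Channel -> seconds
    pw_lg: dict = field(default_factory=dict)     # Side -> microseconds
    history: deque = field(default_factory=lambda: deque(maxlen=5))
    l_step: float = L_STEP
    l_pw: float = L_PW
    dt_threshold: float = DT_THRESHOLD
    dphi_threshold: float = DPHI_THRESHOLD
    tau_bounds: tuple = TAU_BOUNDS
    pw_bounds: tuple = PW_BOUNDS
    flip_tau_sign: bool = False
    cutoff_hz: dict = field(default_factory=dict)  # Channel -> hertz

    @classmethod
    def default(cls, tau_init: float = 0.1, pw_init: float = 300.0,
                **kwargs) -> "AdaptiveState":
        tau = {(side, muscle): tau_init for side in Side for muscle in Muscle}
        pw = {side: pw_init for side in Side}
        state = cls(tau=tau, pw_lg=pw, **kwargs)
        state.cutoff_hz = {ch: cutoff_frequency(v) for ch, v in tau.items()}
        return state


def measure_stimulation_time(amplitudes, c_min: float, dt: float) -> float:
    """Delivered stimulation time within one cycle, in seconds.

    Counts samples whose amplitude is strictly above C_min (gate open and
    envelope positive), summed across branches; empty traces give 0.
    """
    amp = np.asarray(amplitudes, dtype=float)
    if amp.size == 0:
        return 0.0
    return float(np.count_nonzero(amp > c_min + 1e-12)) * dt


def mean_of_history(history, channel: Channel) -> float:
    """Mean stimulation time of ``channel`` over the 5-cycle buffer."""
    if len(history) < 5:
        raise HistoryNotFull(f"history holds {len(history)} cycles, need 5")
    return float(np.mean([m.t_s[channel] for m in history]))


def mean_phi_of_history(history, side: Side) -> float:
    """Mean toe-off shank angle of ``side`` over the 5-cycle buffer."""
    if len(history) < 5:
        raise HistoryNotFull(f"history holds {len(history)} cycles, need 5")
    vals = [m.phi_to[side] for m in history if side in m.phi_to]
    if len(vals) < 5:
        raise HistoryNotFull(f"only {len(vals)} toe-off angles recorded for {side.value}")
    return float(np.mean(vals))


def update_tau(state: AdaptiveState, channel: Channel, t_current: float) -> float:
    """Apply one tau update for ``channel`` given the current cycle's t_s."""
    if channel not in state.tau:
        raise ValueError(f"unknown channel {channel!r}")
    dt = t_current - mean_of_history(state.history, channel)
    step = 0.0
    if dt < -state.dt_threshold:
        step = state.l_step
    elif dt > state.dt_threshold:
        step = -state.l_step
    if state.flip_tau_sign:
        step = -step
    lo, hi = state.tau_bounds
    new_tau = min(max(state.tau[channel] + step, lo), hi)
    state.tau[channel] = new_tau
    state.cutoff_hz[channel] = cutoff_frequency(new_tau)
    return new_tau


def update_pw(state: AdaptiveState, side: Side, phi_current: float) -> float:
    """Apply one LG pulse-width update for ``side`` given the current phi_TO."""
    if side not in state.pw_lg:
        raise ValueError(f"unknown side {side!r}")
    dphi = phi_current - mean_phi_of_history(state.history, side)
    step = 0.0
    if dphi < -state.dphi_threshold:
        step = state.l_pw
    elif dphi > state.dphi_threshold:
        step = -state.l_pw
    lo, hi = state.pw_bounds
    new_pw = min(max(state.pw_lg[side] + step, lo), hi)
    state.pw_lg[side] = new_pw
    return new_pw


def record_cycle(state: AdaptiveState, metrics: CycleMetrics) -> AdaptiveState:
    """Compare the current cycle against the previous five, update, push.

    With a full buffer, tau is updated for every channel present in
    ``metrics.t_s`` and the LG pulse width for every side present in
    ``metrics.phi_to``; during warm-up nothing changes.  The metrics are
    appended to the ring buffer afterwards (the buffer is strictly the
    previous five cycles at comparison time).
    """
    if len(state.history) >= 5:
        for channel, t_cur in metrics.t_s.items():
            update_tau(state, channel, t_cur)
        for side, phi_cur in metrics.phi_to.items():
            try:
                update_pw(state, side, phi_cur)
            except HistoryNotFull:
                pass  # fewer than 5 recorded toe-off angles for this side
    state.history.append(metrics)
    return state
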