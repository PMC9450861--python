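"""Event-triggered eight-channel stimulation-sequence generation.

Each of the eight channels (4 muscles x 2 legs) owns one or two *branches*.
A branch pairs a triggering gait-event impulse with a phase gate:

=======  ========  ===========  ==================
muscle   branch    trigger      gate (phase in)
=======  ========  ===========  ==================
TA       SW        I_SW         {SW, TSW}
LG       LR        I_LR         {LR}
LG       PS        I_PS         {PS}
BF       SW        I_SW         {SW, TSW}
RF       LR        I_LR         {LR}
RF       TSW       I_TSW        {TSW}
=======  ========  ===========  ==================

When a branch's gate is open, its amplitude is

    C(t) = H(t - t_impulse) * (C_max - C_min) + C_min,

i.e. the normalized envelope stretched onto the muscle's calibrated
current range; with no impulse received the gated output rests at C_min,
and a closed gate outputs 0.  A new qualifying impulse restarts the
branch clock (no superposition), so amplitude can never exceed C_max;
outputs are clamped to [0, C_max] regardless and saturations counted.

The two branches of LG (and of RF) are gated by mutually exclusive
phases, so at most one branch contributes at any instant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gait_fsm import EventImpulse, ImpulseKind, Phase
from .response_core import Muscle, Side, TransferFunctionParams, cutoff_frequency

#: Pulse-width bounds for the adapted LG channels, microseconds.
PW_BOUNDS = (250.0, 500.0)


@dataclass(frozen=True)
class Branch:
    name: str
    trigger: ImpulseKind
    gate_phases: frozenset


BRANCHES: dict[Muscle, tuple[Branch, ...]] = {
    Muscle.TA: (Branch("SW", ImpulseKind.I_SW, frozenset({Phase.SW, Phase.TSW})),),
    Muscle.LG: (Branch("LR", ImpulseKind.I_LR, frozenset({Phase.LR})),
                Branch("PS", ImpulseKind.I_PS, frozenset({Phase.PS}))),
    Muscle.BF: (Branch("SW", ImpulseKind.I_SW, frozenset({Phase.SW, Phase.TSW})),),
    Muscle.RF: (Branch("LR", ImpulseKind.I_LR, frozenset({Phase.LR})),
                Branch("TSW", ImpulseKind.I_TSW, frozenset({Phase.TSW}))),
}


class ConfigurationError(ValueError):
    """Raised when channel calibration is missing or inconsistent."""


def _branch(muscle_id: Muscle, name: str) -> Branch:
    for br in BRANCHES[muscle_id]:
        if br.name == name:
            return br
    raise ValueError(f"unknown branch {name!r} for muscle {muscle_id.value}")


def state_gate(muscle_id: Muscle, branch: str, phase: Phase) -> int:
    """Phase gate bit for one muscle branch (1 = stimulation enabled)."""
    return int(phase in _branch(muscle_id, branch).gate_phases)


@dataclass
class MuscleChannelConfig:
    """Per-channel calibration and envelope parameters.

    C_min/C_max are the participant's calibrated current thresholds in mA
    (visible contraction / maximal comfortable contraction); delta_c is
    their difference.  Pulse width is constant except for the LG channels,
    whose pulse width is adapted cycle-by-cycle within PW_BOUNDS.
    """

    muscle_id: Muscle
    side: Side
    c_min: float
    c_max: float
    pulse_width_us: float = 300.0
    stim_frequency_hz: float = 25.0
    tau: float = 0.1
    transfer: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.c_min < self.c_max):
            raise ConfigurationError(
                f"{self.side.value} {self.muscle_id.value}: need 0 < C_min < C_max, "
                f"got C_min={self.c_min}, C_max={self.c_max}")
        if self.muscle_id is Muscle.LG and not (
                PW_BOUNDS[0] <= self.pulse_width_us <= PW_BOUNDS[1]):
            raise ConfigurationError(
                f"LG pulse width must lie in {PW_BOUNDS} us, got {self.pulse_width_us}")
        self._rebuild_transfer()

    @property
    def delta_c(self) -> float:
        return self.c_max - self.c_min

    @property
    def cutoff_hz(self) -> float:
        return cutoff_frequency(self.tau)

    def _rebuild_transfer(self) -> None:
        self.transfer = {
            br.name: TransferFunctionParams.normalized(
                self.tau, muscle_id=self.muscle_id, side=self.side, trigger=br.trigger)
            for br in BRANCHES[self.muscle_id]
        }

    def set_tau(self, tau: float) -> None:
        """Update the channel's time coefficient (all branches share it)."""
        self.tau = float(tau)
        self._rebuild_transfer()


@dataclass(frozen=True)
class StimulusCommand:
    """One amplitude sample for one channel at one instant."""

    t: float
    side: Side
    muscle_id: Muscle
    amplitude_ma: float
    pulse_width_us: float


def _gated_amplitude(cfg: MuscleChannelConfig, branch_impulse_t: dict,
                     phase: Phase, t: float) -> tuple[float, bool]:
    """Raw (unclamped) amplitude plus a flag for would-be saturation."""
    from .response_core import impulse_response

    total = 0.0
    for br in BRANCHES[cfg.muscle_id]:
        if phase not in br.gate_phases:
            continue
        env = 0.0
        t_imp = branch_impulse_t.get(br.name)
        if t_imp is not None and t >= t_imp:
            env = impulse_response(cfg.transfer[br.name], t - t_imp)
        total += env * cfg.delta_c + cfg.c_min
    saturated = total > cfg.c_max + 1e-12
    return total, saturated


def channel_amplitude(cfg: MuscleChannelConfig, active_impulse: EventImpulse | None,
                      phase: Phase, t: float) -> float:
    """Amplitude (mA) of one channel given its most recent impulse.

    The convolution with a unit impulse is the time-shifted envelope; an
    impulse whose kind does not trigger any branch of this muscle is
    ignored.  Output is clamped to [0, C_max].
    """
    branch_t: dict[str, float] = {}
    if active_impulse is not None:
        if t < active_impulse.t:
            raise ValueError("t precedes the active impulse time")
        for br in BRANCHES[cfg.muscle_id]:
            if br.trigger == active_impulse.kind:
                branch_t[br.name] = active_impulse.t
    raw, _ = _gated_amplitude(cfg, branch_t, phase, t)
    return min(max(raw, 0.0), cfg.c_max)


#: Typical calibration currents (mA) for healthy adults; per-participant
#: values normally come from a measurement session via the config file.
DEFAULT_CALIBRATION: dict[Muscle, tuple[float, float]] = {
    Muscle.TA: (10.0, 25.0),
    Muscle.LG: (12.0, 28.0),
    Muscle.BF: (15.0, 35.0),
    Muscle.RF: (15.0, 35.0),
}


def default_channels(tau_init: float = 0.1, pulse_width_us: float = 300.0,
                     stim_frequency_hz: float = 25.0) -> dict:
    """Build the 8-channel configuration map from default calibration."""
    channels = {}
    for side in Side:
        for muscle, (cmin, cmax) in DEFAULT_CALIBRATION.items():
            channels[(side, muscle)] = MuscleChannelConfig(
                muscle_id=muscle, side=side, c_min=cmin, c_max=cmax,
                pulse_width_us=pulse_width_us, stim_frequency_hz=stim_frequency_hz,
                tau=tau_init)
    return channels


class ReflexiveController:
    """Streaming controller: routes impulses to branches, emits 8 commands/tick."""

    def __init__(self, channels: dict) -> None:
        expected = {(side, muscle) for side in Side for muscle in Muscle}
        missing = expected - set(channels)
        if missing:
            names = sorted(f"{s.value}.{m.value}" for s, m in missing)
            raise ConfigurationError(f"missing calibration for channels: {names}")
        self.channels: dict = dict(channels)
        self._branch_impulse_t: dict = {key: {} for key in self.channels}
        self.saturation_count = 0

    def notify_impulse(self, impulse: EventImpulse) -> None:
        """Restart the clocks of every branch triggered by this impulse."""
        for (side, muscle), cfg in self.channels.items():
            if side != impulse.side:
                continue
            for br in BRANCHES[muscle]:
                if br.trigger == impulse.kind:
                    self._branch_impulse_t[(side, muscle)][br.name] = impulse.t

    def set_tau(self, side: Side, muscle: Muscle, tau: float) -> None:
        self.channels[(side, muscle)].set_tau(tau)

    def set_pulse_width(self, side: Side, muscle: Muscle, pw_us: float) -> None:
        self.channels[(side, muscle)].pulse_width_us = float(pw_us)

    def tick(self, t: float, phase_by_side: dict, new_impulses=()) -> list[StimulusCommand]:
        """Emit one command per channel for time ``t`` (8 commands)."""
        for imp in new_impulses:
            self.notify_impulse(imp)
        commands = []
        for (side, muscle), cfg in sorted(
                self.channels.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)):
            phase = phase_by_side.get(side)
            if phase is None:
                amp = 0.0
            else:
                raw, sat = _gated_amplitude(
                    cfg, self._branch_impulse_t[(side, muscle)], phase, t)
                if sat:
                    self.saturation_count += 1
                amp = min(max(raw, 0.0), cfg.c_max)
            commands.append(StimulusCommand(t, side, muscle, amp, cfg.pulse_width_us))
        return commands


def generate_channel_trace(cfg: MuscleChannelConfig, t: np.ndarray,
                           phases: np.ndarray, impulses,
                           return_saturation: bool = False):
    """Vectorized amplitude trace for one channel over a sample grid.

    ``phases`` holds one Phase per sample; ``impulses`` are this side's
    event impulses (any kinds — non-triggering kinds are ignored).  The
    most recent triggering impulse drives each branch (restart semantics),
    matching the streaming :class:`ReflexiveController` sample-for-sample.
    Returns amplitudes in mA, clamped to [0, C_max]; with
    ``return_saturation`` also the count of clamped samples.
    """
    from .response_core import impulse_response

    t = np.asarray(t, dtype=float)
    phase_vals = np.array([getattr(p, "value", p) for p in phases])
    amp = np.zeros_like(t)
    for br in BRANCHES[cfg.muscle_id]:
        gate = np.isin(phase_vals, [p.value for p in br.gate_phases])
        if not gate.any():
            continue
        times = np.sort([imp.t for imp in impulses if imp.kind == br.trigger])
        contrib = np.full_like(t, cfg.c_min)
        if len(times):
            idx = np.searchsorted(times, t, side="right") - 1
            has = idx >= 0
            dt = np.zeros_like(t)
            dt[has] = t[has] - times[idx[has]]
            env = np.zeros_like(t)
            env[has] = impulse_response(cfg.transfer[br.name], dt[has])
            contrib = env * cfg.delta_c + cfg.c_min
        amp += np.where(gate, contrib, 0.0)
    n_sat = int(np.count_nonzero(amp > cfg.c_max + 1e-12))
    clamped = np.minimum(np.maximum(amp, 0.0), cfg.c_max)
    if return_saturation:
        return clamped, n_sat
    return clamped
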