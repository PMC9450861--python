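"""Synthetic treadmill-gait sensor streams with ground-truth labels.

The generator emulates the sensor signals of a two-leg treadmill walking
session — heel and toe insole force and sagittal shank angle per leg —
so the detector, controller and adaptation loop are testable without
hardware.  Each gait cycle is laid out from a phase schedule (fractions
of the cycle spent in LR/ST/PS/SW/TSW); heel force is on from heel
strike to heel off, toe force from foot flat to toe off, and the shank
angle follows a smooth monotone-piecewise curve that attains ``phi_TO``
at toe-off, dips during swing, and rises through the terminal-swing
threshold angle exactly at the scheduled STA instant.

All scheduled event times are snapped to the sample grid and contact
transitions ramp within a fraction of one sample period, so a correct
detector reproduces the ground truth with at most one sample of latency.
Cycle duration shrinks linearly with belt speed (1.4 s at 1.0 km/h to
1.0 s at 2.0 km/h by default) and the speed protocol ramps up and then
down, each visited level contributing ``cycles_per_level`` cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .adaptive_ilc import AdaptiveState, CycleMetrics, measure_stimulation_time, record_cycle
from .gait_fsm import (DetectionResult, EventKind, EventImpulse, FsmConfig, GaitEvent,
                       MatchStats, Phase, detect_stream, evaluate_detection)
from .reflexive_controller import (MuscleChannelConfig, default_channels,
                                   generate_channel_trace)
from .response_core import Muscle, Side

_PHASE_ORDER = (Phase.LR, Phase.ST, Phase.PS, Phase.SW, Phase.TSW)

DEFAULT_PHASE_FRACTIONS = {Phase.LR: 0.10, Phase.ST: 0.30, Phase.PS: 0.10,
                           Phase.SW: 0.37, Phase.TSW: 0.13}


def _snap(x: float, dt: float) -> float:
    return round(x / dt) * dt


@dataclass
class GaitModelParams:
    """Parameters of one synthetic gait cycle at a given belt speed.

    ``cycle_duration`` and ``phi_to_deg`` default to speed-derived values:
    duration interpolates linearly between ``duration_at_1kmh`` and
    ``duration_at_2kmh``; the toe-off shank angle ramps from 10 deg at
    1.0 km/h to 14 deg at 2.0 km/h, deliberately kept below the
    terminal-swing threshold angle so the swing-phase threshold crossing
    happens at the scheduled STA instant rather than at toe-off.
    """

    speed_kmh: float = 1.0
    cycle_duration: float | None = None
    phase_fractions: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_FRACTIONS))
    contact_force_amplitude: float = 100.0
    shank_angle_amplitude: float = 20.0      # angle at heel strike, degrees
    phi_to_deg: float | None = None
    swing_min_angle_deg: float = -10.0
    sta_crossing_deg: float = 15.0
    noise_sd_force: float = 2.0              # a.u., additive Gaussian
    noise_sd_angle: float = 0.5              # degrees, additive Gaussian
    sample_rate: float = 100.0
    contact_ramp_s: float = 0.005
    duration_at_1kmh: float = 1.4
    duration_at_2kmh: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.phase_fractions.get(p, 0.0) for p in _PHASE_ORDER)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phase fractions must sum to 1, got {total}")
        if any(self.phase_fractions[p] <= 0 for p in _PHASE_ORDER):
            raise ValueError("phase fractions must all be positive")
        if self.noise_sd_force < 0 or self.noise_sd_angle < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.cycle_duration is not None and self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")
        if not (0 < self.contact_ramp_s < 1.0 / self.sample_rate):
            raise ValueError("contact_ramp_s must lie within one sample period")
        phi_to = self.resolved_phi_to()
        if not (self.swing_min_angle_deg < phi_to < self.sta_crossing_deg
                < self.shank_angle_amplitude):
            raise ValueError(
                "need swing_min < phi_TO < STA threshold < heel-strike angle, got "
                f"{self.swing_min_angle_deg} / {phi_to} / {self.sta_crossing_deg} / "
                f"{self.shank_angle_amplitude}")

    def resolved_duration(self) -> float:
        if self.cycle_duration is not None:
            return self.cycle_duration
        slope = self.duration_at_2kmh - self.duration_at_1kmh
        return self.duration_at_1kmh + (self.speed_kmh - 1.0) * slope

    def resolved_phi_to(self) -> float:
        if self.phi_to_deg is not None:
            return self.phi_to_deg
        return 10.0 + 4.0 * (self.speed_kmh - 1.0)


@dataclass
class SpeedProtocol:
    """Up-then-down treadmill speed ramp; each visited level contributes
    ``cycles_per_level`` gait cycles (levels revisited on the way down
    count again)."""

    start_kmh: float = 1.0
    stop_kmh: float = 2.0
    step_kmh: float = 0.2
    cycles_per_level: int = 15

    def __post_init__(self) -> None:
        if self.cycles_per_level < 1:
            raise ValueError("cycles_per_level must be >= 1")
        span = self.stop_kmh - self.start_kmh
        if span < 0:
            raise ValueError("stop speed must be >= start speed")
        if span > 0:
            if self.step_kmh <= 0:
                raise ValueError("step must be positive")
            n = span / self.step_kmh
            if abs(n - round(n)) > 1e-9:
                raise ValueError("step must divide (stop - start) exactly")

    def levels(self) -> list[float]:
        span = self.stop_kmh - self.start_kmh
        n = int(round(span / self.step_kmh)) if span > 0 else 0
        up = [self.start_kmh + i * self.step_kmh for i in range(n + 1)]
        down = [self.stop_kmh - i * self.step_kmh for i in range(1, n + 1)]
        return up + down

    def cycle_speeds(self) -> list[float]:
        return [lv for lv in self.levels() for _ in range(self.cycles_per_level)]


@dataclass
class CycleSchedule:
    """Grid-snapped event times of one cycle (all in seconds)."""

    t_hs: float
    t_ff: float
    t_ho: float
    t_to: float
    t_sta: float
    t_end: float
    phi_to: float
    speed_kmh: float


def build_cycle_schedule(params: GaitModelParams, t0: float) -> CycleSchedule:
    dt = 1.0 / params.sample_rate
    T = _snap(params.resolved_duration(), dt)
    f = params.phase_fractions
    t_hs = _snap(t0, dt)
    t_ff = _snap(t_hs + f[Phase.LR] * T, dt)
    t_ho = _snap(t_hs + (f[Phase.LR] + f[Phase.ST]) * T, dt)
    t_to = _snap(t_hs + (f[Phase.LR] + f[Phase.ST] + f[Phase.PS]) * T, dt)
    t_sta = _snap(t_hs + (1.0 - f[Phase.TSW]) * T, dt)
    t_end = _snap(t_hs + T, dt)
    times = (t_hs, t_ff, t_ho, t_to, t_sta, t_end)
    if any(b - a < dt / 2 for a, b in zip(times, times[1:])):
        raise ValueError("cycle too short for the requested phase fractions "
                         "at this sample rate")
    return CycleSchedule(t_hs, t_ff, t_ho, t_to, t_sta, t_end,
                         params.resolved_phi_to(), params.speed_kmh)


def _contact_knots(schedules, amp, ramp, on_attr, off_attr):
    xs, ys = [], []
    for sch in schedules:
        t_on = getattr(sch, on_attr)
        t_off = getattr(sch, off_attr)
        xs.extend([t_on, t_on + ramp, t_off, t_off + ramp])
        ys.extend([0.0, amp, amp, 0.0])
    return np.array(xs), np.array(ys)


def _angle_knots(schedules, params: GaitModelParams, lead_start: float | None,
                 lead_angle: float = 5.0):
    xs, ys = [], []
    dt = 1.0 / params.sample_rate
    first_hs = schedules[0].t_hs
    if lead_start is not None and lead_start < first_hs - 1.5 * dt:
        xs.extend([lead_start, first_hs - dt])
        ys.extend([lead_angle, lead_angle])
    a_hs = params.shank_angle_amplitude
    sta = params.sta_crossing_deg
    for k, sch in enumerate(schedules):
        mid_stance = 0.5 * (sta + sch.phi_to)   # below threshold, above phi_TO
        t_min = sch.t_to + 0.4 * (sch.t_sta - sch.t_to)
        # the first cycle of a stream starts below the STA threshold so the
        # swing-phase threshold crossing cannot fire before the first strike
        hs_angle = lead_angle if (k == 0 and lead_start is not None) else a_hs
        xs.extend([sch.t_hs, sch.t_ho, sch.t_to, t_min, sch.t_sta])
        ys.extend([hs_angle, mid_stance, sch.phi_to, params.swing_min_angle_deg, sta])
    xs.append(schedules[-1].t_end)
    ys.append(a_hs)
    return np.array(xs), np.array(ys)


def _truth_for_side(schedules, side: Side, grid: np.ndarray):
    events: list[GaitEvent] = []
    for sch in schedules:
        events.extend([GaitEvent(EventKind.HS, sch.t_hs, side),
                       GaitEvent(EventKind.FF, sch.t_ff, side),
                       GaitEvent(EventKind.HO, sch.t_ho, side),
                       GaitEvent(EventKind.TO, sch.t_to, side),
                       GaitEvent(EventKind.STA, sch.t_sta, side)])
    bounds, labels = [], []
    for sch in schedules:
        bounds.extend([sch.t_hs, sch.t_ff, sch.t_ho, sch.t_to, sch.t_sta])
        labels.extend([Phase.LR, Phase.ST, Phase.PS, Phase.SW, Phase.TSW])
    idx = np.searchsorted(np.asarray(bounds), grid, side="right") - 1
    phases = np.empty(len(grid), dtype=object)
    for i, j in enumerate(idx):
        phases[i] = Phase.SW if j < 0 else labels[j]
    boundaries = [sch.t_hs for sch in schedules]
    return events, phases, boundaries


def _synthesize_side(schedules, params: GaitModelParams, grid: np.ndarray,
                     rng: np.random.Generator | None, lead_start: float | None):
    amp = params.contact_force_amplitude
    ramp = params.contact_ramp_s
    hx, hy = _contact_knots(schedules, amp, ramp, "t_hs", "t_ho")
    tx, ty = _contact_knots(schedules, amp, ramp, "t_ff", "t_to")
    heel = np.interp(grid, hx, hy, left=0.0, right=0.0)
    toe = np.interp(grid, tx, ty, left=0.0, right=0.0)
    ax, ay = _angle_knots(schedules, params, lead_start)
    angle = np.full(len(grid), ay[-1])
    inside = grid <= ax[-1]
    angle[inside] = PchipInterpolator(ax, ay)(grid[inside])
    if grid[0] < ax[0]:
        angle[grid < ax[0]] = ay[0]
    if rng is not None:
        if params.noise_sd_force > 0:
            heel = np.maximum(heel + rng.normal(0, params.noise_sd_force, len(grid)), 0.0)
            toe = np.maximum(toe + rng.normal(0, params.noise_sd_force, len(grid)), 0.0)
        if params.noise_sd_angle > 0:
            angle = angle + rng.normal(0, params.noise_sd_angle, len(grid))
    return heel, toe, angle


@dataclass
class SyntheticSession:
    """Generated two-leg sensor streams plus ground truth for evaluation."""

    t: np.ndarray
    samples: dict                    # Side -> DataFrame(t, heel, toe, shank_angle)
    truth_events: list[GaitEvent]
    truth_phases: dict               # Side -> array of Phase per sample
    truth_cycles: dict               # Side -> list of heel-strike times
    cycle_speeds: list[float]
    protocol: SpeedProtocol | None
    params: GaitModelParams
    sample_rate: float

    @property
    def n_cycles(self) -> int:
        return len(self.truth_cycles[Side.LEFT])


def generate_cycle(params: GaitModelParams, t0: float, side: Side = Side.LEFT,
                   rng: np.random.Generator | None = None):
    """One labeled gait cycle starting at heel strike ``t0``.

    Returns ``(samples, events, phases)``; pass ``rng`` to add sensor
    noise (omitting it gives the noise-free deterministic signal).
    """
    sch = build_cycle_schedule(params, t0)
    dt = 1.0 / params.sample_rate
    i0, i1 = round(sch.t_hs / dt), round(sch.t_end / dt)
    grid = np.arange(i0, i1 + 1) * dt
    heel, toe, angle = _synthesize_side([sch], params, grid, rng, lead_start=None)
    events, phases, _ = _truth_for_side([sch], side, grid)
    df = pd.DataFrame({"t": grid, "heel": heel, "toe": toe, "shank_angle": angle})
    return df, events, phases


def generate_protocol(protocol: SpeedProtocol, params: GaitModelParams | None = None,
                      seed: int | None = None, lead_in_s: float = 0.5,
                      two_sided: bool = True) -> SyntheticSession:
    """Generate the full speed-ramp session (both legs, half-cycle offset).

    ``params`` is a template whose ``speed_kmh`` is overridden per level;
    ``seed`` overrides the template's seed for the sensor noise streams.
    """
    params = params if params is not None else GaitModelParams()
    if seed is None:
        seed = params.seed
    dt = 1.0 / params.sample_rate
    speeds = protocol.cycle_speeds()

    def side_schedules(t_start: float):
        scheds, t0 = [], _snap(t_start, dt)
        for sp in speeds:
            sch = build_cycle_schedule(replace(params, speed_kmh=sp), t0)
            scheds.append(sch)
            t0 = sch.t_end
        return scheds

    lead_left = max(lead_in_s, 3 * dt)
    left = side_schedules(lead_left)
    t_first = left[0].t_end - left[0].t_hs
    sides = {Side.LEFT: (left, _snap(0.0, dt))}
    if two_sided:
        right = side_schedules(lead_left + t_first / 2.0)
        sides[Side.RIGHT] = (right, _snap(0.0, dt))

    t_final = max(s[-1].t_end for s, _ in sides.values())
    grid = np.arange(round(t_final / dt) + 1) * dt

    rng = np.random.default_rng(seed)
    noisy = params.noise_sd_force > 0 or params.noise_sd_angle > 0
    children = rng.spawn(len(sides)) if noisy else [None] * len(sides)

    samples, phases_by_side, cycles_by_side = {}, {}, {}
    all_events: list[GaitEvent] = []
    for (side, (scheds, grid0)), child in zip(sides.items(), children):
        heel, toe, angle = _synthesize_side(scheds, params, grid, child, lead_start=grid0)
        events, phases, boundaries = _truth_for_side(scheds, side, grid)
        samples[side] = pd.DataFrame({"t": grid, "heel": heel, "toe": toe,
                                      "shank_angle": angle})
        phases_by_side[side] = phases
        cycles_by_side[side] = boundaries
        all_events.extend(events)
    all_events.sort(key=lambda e: e.t)
    return SyntheticSession(t=grid, samples=samples, truth_events=all_events,
                            truth_phases=phases_by_side, truth_cycles=cycles_by_side,
                            cycle_speeds=list(speeds), protocol=protocol,
                            params=params, sample_rate=params.sample_rate)


# ---------------------------------------------------------------------------
# Closed-loop integration
# ---------------------------------------------------------------------------

@dataclass
class CycleRecord:
    """Adaptation-log entry for one gait-cycle index (all 8 channels)."""

    n: int
    speed_kmh: float | None
    t_s: dict          # (Side, Muscle) -> seconds
    phi_to: dict       # Side -> degrees
    tau: dict          # (Side, Muscle) -> seconds, after this cycle's update
    pw: dict           # Side -> microseconds, after this cycle's update


@dataclass
class SessionLog:
    """Everything a closed-loop run produces."""

    stim: pd.DataFrame                 # long: t, side, muscle, amplitude_mA, pulse_width_us
    adaptation: list[CycleRecord]
    detection: dict                    # Side -> DetectionResult
    evaluation: dict                   # EventKind -> MatchStats
    adaptive: AdaptiveState
    saturation_count: int


def closed_loop_run(session: SyntheticSession, channels: dict | None = None,
                    fsm_config: FsmConfig | None = None,
                    adaptive: AdaptiveState | None = None,
                    match_tol: float = 0.05) -> SessionLog:
    """Stream a session through detection, stimulation and adaptation.

    Detection runs per leg on the generated sensor streams; the
    controller synthesizes the eight amplitude traces cycle by cycle with
    the current tau values; after each cycle index (left and right cycles
    paired by index — the legs are half a cycle out of phase) the
    iterative-learning update adjusts tau and the LG pulse widths used
    from the next cycle on.  Detection quality is scored against the
    session's ground truth.
    """
    channels = channels if channels is not None else default_channels()
    fsm_config = fsm_config or FsmConfig(
        sample_rate=session.sample_rate,
        sta_threshold_deg=session.params.sta_crossing_deg)
    adaptive = adaptive or AdaptiveState.default(
        tau_init=next(iter(channels.values())).tau)
    dt = 1.0 / session.sample_rate
    grid = session.t

    det: dict[Side, DetectionResult] = {}
    windows: dict[Side, list[tuple[int, int]]] = {}
    to_times: dict[Side, np.ndarray] = {}
    for side in session.samples:
        d = detect_stream(session.samples[side], fsm_config, side)
        det[side] = d
        edges = [0] + [int(np.searchsorted(grid, b - dt / 2)) for b in
                       d.cycle_boundaries] + [len(grid)]
        windows[side] = list(zip(edges, edges[1:]))
        to_times[side] = np.array(sorted(e.t for e in d.events
                                         if e.kind == EventKind.TO))

    # sync channel parameters with the adaptive state
    for key, cfg in channels.items():
        if key in adaptive.tau:
            cfg.set_tau(adaptive.tau[key])
        if cfg.muscle_id is Muscle.LG and cfg.side in adaptive.pw_lg:
            cfg.pulse_width_us = adaptive.pw_lg[cfg.side]

    n_windows = {side: len(w) for side, w in windows.items()}
    n_cycles = min(len(w) for w in windows.values()) - 1  # first window is lead-in
    n_cycles = max(n_cycles, 0)

    amp_chunks: dict = {key: [] for key in channels}
    pw_chunks: dict = {key: [] for key in channels}
    saturation = 0
    adaptation: list[CycleRecord] = []

    def emit_window(side: Side, w: tuple[int, int]):
        nonlocal saturation
        i0, i1 = w
        sl = slice(i0, i1)
        t_s_here = {}
        for muscle in Muscle:
            key = (side, muscle)
            cfg = channels[key]
            amp, n_sat = generate_channel_trace(
                cfg, grid[sl], det[side].phases[sl], det[side].impulses,
                return_saturation=True)
            saturation += n_sat
            amp_chunks[key].append(amp)
            pw_chunks[key].append(np.full(i1 - i0, cfg.pulse_width_us))
            t_s_here[key] = measure_stimulation_time(amp, cfg.c_min, dt)
        return t_s_here

    # lead-in segment (before the first detected heel strike)
    for side in windows:
        emit_window(side, windows[side][0])

    for n in range(n_cycles):
        t_s: dict = {}
        phi_to: dict = {}
        for side in windows:
            w = windows[side][n + 1]
            t_s.update(emit_window(side, w))
            # toe-off angle feedback, raw from the sensor stream
            lo_t, hi_t = grid[w[0]], grid[w[1] - 1]
            cand = to_times[side][(to_times[side] >= lo_t) & (to_times[side] <= hi_t)]
            if len(cand):
                idx = int(np.clip(np.searchsorted(grid, cand[0]), 0, len(grid) - 1))
                phi_to[side] = float(session.samples[side]["shank_angle"].iloc[idx])
        speed = session.cycle_speeds[n] if n < len(session.cycle_speeds) else None
        metrics = CycleMetrics(n=n, t_s=t_s, phi_to=phi_to)
        record_cycle(adaptive, metrics)
        for key, cfg in channels.items():
            cfg.set_tau(adaptive.tau[key])
            if cfg.muscle_id is Muscle.LG:
                cfg.pulse_width_us = adaptive.pw_lg[cfg.side]
        adaptation.append(CycleRecord(n=n, speed_kmh=speed, t_s=dict(t_s),
                                      phi_to=dict(phi_to), tau=dict(adaptive.tau),
                                      pw=dict(adaptive.pw_lg)))

    # any leftover windows (sides can differ by one cycle): final parameters
    for side in windows:
        for w in windows[side][n_cycles + 1:]:
            emit_window(side, w)

    frames = []
    for (side, muscle), chunks in amp_chunks.items():
        amp = np.concatenate(chunks) if chunks else np.empty(0)
        pw = np.concatenate(pw_chunks[(side, muscle)]) if chunks else np.empty(0)
        frames.append(pd.DataFrame({
            "t": grid[:len(amp)], "side": side.value, "muscle": muscle.value,
            "amplitude_mA": amp, "pulse_width_us": pw}))
    stim = pd.concat(frames, ignore_index=True).sort_values(
        ["t", "side", "muscle"], kind="stable").reset_index(drop=True)

    detected_events = [e for d in det.values() for e in d.events]
    evaluation = evaluate_detection(detected_events, session.truth_events, tol=match_tol)
    return SessionLog(stim=stim, adaptation=adaptation, detection=det,
                      evaluation=evaluation, adaptive=adaptive,
                      saturation_count=saturation)
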