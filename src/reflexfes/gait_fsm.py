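"""Gait-phase detection from insole pressure and shank-angle streams.

Two stages:

1. **Binarization.** Heel and toe force channels are converted to contact
   bits ``S_H``/``S_T`` by hysteresis thresholds expressed as fractions of
   an exponentially decayed running maximum (drift-robust, amplitude-free).
   The shank-angle bit ``S_phi`` is 1 when the sagittal shank angle is at
   or above a configurable threshold angle; it is only consulted during
   swing.  Bit edges are debounced: a new bit value must persist for
   ``debounce_samples`` consecutive samples, and the resulting edge is
   timestamped retroactively at the first sample of the new value.

2. **IF-THEN finite state machine.** Five phases per leg — load response
   (LR), stance (ST), pre-swing (PS), swing (SW), terminal swing (TSW) —
   with four impulse-generating transitions:

   * any contact after no contact      -> LR,  event HS,  impulse I_LR
   * (1,1) -> (0,1) heel lifts         -> PS,  event HO,  impulse I_PS
   * any contact -> (0,0) foot lifts   -> SW,  event TO,  impulse I_SW
   * in SW, S_phi rises 0 -> 1         -> TSW, event STA, impulse I_TSW

   LR ends in ST once both sensors have been in contact for a dwell
   window (event FF).  Unexpected bit patterns keep the current phase.

Cycle boundaries are heel strikes with the heel leading (``S_H=1,
S_T=0``); streams whose every initial contact is forefoot-first fall back
to any-contact boundaries (pathological-gait rule).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .response_core import Side


class Phase(str, enum.Enum):
    LR = "LR"
    ST = "ST"
    PS = "PS"
    SW = "SW"
    TSW = "TSW"


class EventKind(str, enum.Enum):
    HS = "HS"
    FF = "FF"
    HO = "HO"
    TO = "TO"
    STA = "STA"


class ImpulseKind(str, enum.Enum):
    I_LR = "I_LR"
    I_PS = "I_PS"
    I_SW = "I_SW"
    I_TSW = "I_TSW"


@dataclass(frozen=True)
class ContactSample:
    """One sensor sample: time (s), heel/toe force (a.u.), shank angle (deg)."""

    t: float
    heel: float
    toe: float
    shank_angle: float
    side: Side = Side.LEFT


@dataclass(frozen=True)
class BinaryInputs:
    """FSM input bits; ``s_phi`` is meaningful only during swing."""

    s_h: int
    s_t: int
    s_phi: int = 0


@dataclass(frozen=True)
class GaitEvent:
    kind: EventKind
    t: float
    side: Side


@dataclass(frozen=True)
class EventImpulse:
    kind: ImpulseKind
    t: float
    side: Side


@dataclass
class FsmConfig:
    """Binarization and state-machine parameters.

    theta_on / theta_off are hysteresis thresholds as fractions of the
    decayed running force maximum; decay_horizon_s is the e-folding time
    of that maximum (about three gait cycles by default).
    """

    sample_rate: float = 100.0
    theta_on: float = 0.20
    theta_off: float = 0.10
    decay_horizon_s: float = 3.6
    sta_threshold_deg: float = 15.0
    debounce_samples: int = 2
    ff_debounce_s: float = 0.05


class AdaptiveThreshold:
    """Hysteresis binarizer with an exponentially decayed running maximum.

    The running maximum of each force channel decays with time constant
    ``decay_horizon_s`` and is lifted by each new sample, so thresholds
    track slow drift while remaining scale-free.  Optional seeds stand in
    for at least one observed cycle when processing starts mid-stream.
    """

    def __init__(self, config: FsmConfig, seed_heel_max: float = 0.0,
                 seed_toe_max: float = 0.0) -> None:
        self.config = config
        self._max = {"heel": float(seed_heel_max), "toe": float(seed_toe_max)}
        self._bits = {"heel": 0, "toe": 0}
        self._last_t: float | None = None

    def _update_sensor(self, name: str, force: float, dt: float | None) -> int:
        cfg = self.config
        if dt is not None and dt > 0:
            self._max[name] *= math.exp(-dt / cfg.decay_horizon_s)
        self._max[name] = max(self._max[name], force)
        m = self._max[name]
        if self._bits[name] == 0:
            if m > 0 and force > 0 and force >= cfg.theta_on * m:
                self._bits[name] = 1
        else:
            if m <= 0 or force <= cfg.theta_off * m:
                self._bits[name] = 0
        return self._bits[name]

    def update(self, sample: ContactSample) -> BinaryInputs:
        vals = (sample.t, sample.heel, sample.toe, sample.shank_angle)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite sample at t={sample.t!r}")
        if sample.heel < 0 or sample.toe < 0:
            raise ValueError("forces must be non-negative")
        dt = None if self._last_t is None else sample.t - self._last_t
        self._last_t = sample.t
        s_h = self._update_sensor("heel", sample.heel, dt)
        s_t = self._update_sensor("toe", sample.toe, dt)
        s_phi = int(sample.shank_angle >= self.config.sta_threshold_deg)
        return BinaryInputs(s_h=s_h, s_t=s_t, s_phi=s_phi)


def binarize(sample: ContactSample, thresh_state: AdaptiveThreshold) -> BinaryInputs:
    """Convert one sensor sample to FSM bits, updating the running extrema."""
    return thresh_state.update(sample)


def step_fsm(prev_bits: BinaryInputs, prev_phase: Phase, cur_bits: BinaryInputs,
             t: float, side: Side = Side.LEFT):
    """Single stateless FSM transition on already-debounced bits.

    Returns ``(phase, events, impulses)`` with all events stamped at ``t``.
    The time-dwell LR->ST (FF) rule needs edge bookkeeping and lives in
    :class:`GaitPhaseDetector`; this function covers the four printed
    impulse transitions.  Unexpected bit patterns keep the current phase.
    """
    events: list[GaitEvent] = []
    impulses: list[EventImpulse] = []
    phase = prev_phase
    prev_contact = prev_bits.s_h or prev_bits.s_t
    cur_contact = cur_bits.s_h or cur_bits.s_t

    if not prev_contact and cur_contact:
        phase = Phase.LR
        events.append(GaitEvent(EventKind.HS, t, side))
        impulses.append(EventImpulse(ImpulseKind.I_LR, t, side))
    elif prev_contact and not cur_contact:
        phase = Phase.SW
        events.append(GaitEvent(EventKind.TO, t, side))
        impulses.append(EventImpulse(ImpulseKind.I_SW, t, side))
    elif (prev_bits.s_h, prev_bits.s_t) == (1, 1) and (cur_bits.s_h, cur_bits.s_t) == (0, 1):
        phase = Phase.PS
        events.append(GaitEvent(EventKind.HO, t, side))
        impulses.append(EventImpulse(ImpulseKind.I_PS, t, side))
    elif phase is Phase.SW and prev_bits.s_phi == 0 and cur_bits.s_phi == 1 \
            and cur_bits.s_h == 0 and cur_bits.s_t == 0:
        phase = Phase.TSW
        events.append(GaitEvent(EventKind.STA, t, side))
        impulses.append(EventImpulse(ImpulseKind.I_TSW, t, side))
    return phase, events, impulses


class _DebouncedBit:
    """Confirms a bit change after N consecutive samples; remembers the
    time the new value first appeared (the retroactive edge time)."""

    def __init__(self, n_confirm: int, value: int = 0) -> None:
        self.n_confirm = max(1, int(n_confirm))
        self.value = value
        self.edge_t: float | None = None
        self._cand_val: int | None = None
        self._cand_t0 = 0.0
        self._cand_n = 0

    def step(self, raw: int, t: float) -> bool:
        """Feed one raw sample; returns True if the confirmed value changed."""
        if raw == self.value:
            self._cand_val = None
            self._cand_n = 0
            return False
        if raw != self._cand_val:
            self._cand_val = raw
            self._cand_t0 = t
            self._cand_n = 0
        self._cand_n += 1
        if self._cand_n >= self.n_confirm:
            self.value = raw
            self.edge_t = self._cand_t0
            self._cand_val = None
            self._cand_n = 0
            return True
        return False


class GaitPhaseDetector:
    """Streaming per-leg detector: binarize -> debounce -> FSM.

    Feed samples in time order via :meth:`step`; each call returns the
    current phase plus any events and impulses emitted at that sample
    (timestamped at the underlying bit edge, which may precede the call
    time by the debounce window).
    """

    def __init__(self, config: FsmConfig | None = None, side: Side = Side.LEFT,
                 seed_heel_max: float = 0.0, seed_toe_max: float = 0.0) -> None:
        self.config = config or FsmConfig()
        self.side = side
        self.threshold = AdaptiveThreshold(self.config, seed_heel_max, seed_toe_max)
        n = self.config.debounce_samples
        self._bits = {"s_h": _DebouncedBit(n), "s_t": _DebouncedBit(n),
                      "s_phi": _DebouncedBit(n)}
        self.phase: Phase | None = None
        self._both_contact_since: float | None = None
        self._hs_heel_led: list[tuple[float, bool]] = []
        self._initialized = False

    # -- internals ---------------------------------------------------------

    def _confirmed(self) -> BinaryInputs:
        return BinaryInputs(self._bits["s_h"].value, self._bits["s_t"].value,
                            self._bits["s_phi"].value)

    def _init_state(self, raw: BinaryInputs) -> None:
        for name, val in (("s_h", raw.s_h), ("s_t", raw.s_t), ("s_phi", raw.s_phi)):
            self._bits[name].value = val
        if raw.s_h and raw.s_t:
            self.phase = Phase.ST
        elif raw.s_h or raw.s_t:
            self.phase = Phase.LR
        else:
            self.phase = Phase.SW
        self._initialized = True

    # -- public API --------------------------------------------------------

    def step(self, sample: ContactSample):
        """Process one sample; returns ``(phase, events, impulses)``."""
        raw = self.threshold.update(sample)
        if not self._initialized:
            self._init_state(raw)
            return self.phase, [], []

        prev = self._confirmed()
        changed = False
        for name, val in (("s_h", raw.s_h), ("s_t", raw.s_t), ("s_phi", raw.s_phi)):
            changed |= self._bits[name].step(val, sample.t)
        cur = self._confirmed()

        events: list[GaitEvent] = []
        impulses: list[EventImpulse] = []
        side = self.side

        if changed:
            prev_contact = prev.s_h or prev.s_t
            cur_contact = cur.s_h or cur.s_t
            if not prev_contact and cur_contact:
                edges = [self._bits[n].edge_t for n, v in
                         (("s_h", cur.s_h), ("s_t", cur.s_t)) if v]
                t_evt = min(e for e in edges if e is not None)
                self.phase = Phase.LR
                self._both_contact_since = None
                events.append(GaitEvent(EventKind.HS, t_evt, side))
                impulses.append(EventImpulse(ImpulseKind.I_LR, t_evt, side))
                self._hs_heel_led.append((t_evt, cur.s_h == 1 and cur.s_t == 0))
            elif prev_contact and not cur_contact:
                edges = [self._bits[n].edge_t for n, v in
                         (("s_h", prev.s_h), ("s_t", prev.s_t)) if v]
                t_evt = max(e for e in edges if e is not None)
                self.phase = Phase.SW
                self._both_contact_since = None
                events.append(GaitEvent(EventKind.TO, t_evt, side))
                impulses.append(EventImpulse(ImpulseKind.I_SW, t_evt, side))
            elif (prev.s_h, prev.s_t) == (1, 1) and (cur.s_h, cur.s_t) == (0, 1):
                t_evt = self._bits["s_h"].edge_t
                self.phase = Phase.PS
                self._both_contact_since = None
                events.append(GaitEvent(EventKind.HO, t_evt, side))
                impulses.append(EventImpulse(ImpulseKind.I_PS, t_evt, side))
            elif self.phase is Phase.SW and prev.s_phi == 0 and cur.s_phi == 1 \
                    and cur.s_h == 0 and cur.s_t == 0:
                t_evt = self._bits["s_phi"].edge_t
                self.phase = Phase.TSW
                events.append(GaitEvent(EventKind.STA, t_evt, side))
                impulses.append(EventImpulse(ImpulseKind.I_TSW, t_evt, side))
            # any other pattern: keep the current phase (robustness contract)

        # LR -> ST once both sensors have been down for the dwell window
        if self.phase is Phase.LR and cur.s_h == 1 and cur.s_t == 1:
            if self._both_contact_since is None:
                edges = [self._bits["s_h"].edge_t, self._bits["s_t"].edge_t]
                edges = [e for e in edges if e is not None]
                self._both_contact_since = max(edges) if edges else sample.t
            if sample.t - self._both_contact_since >= self.config.ff_debounce_s:
                self.phase = Phase.ST
                events.append(GaitEvent(EventKind.FF, self._both_contact_since, side))
        elif not (cur.s_h == 1 and cur.s_t == 1):
            self._both_contact_since = None

        return self.phase, events, impulses


@dataclass
class DetectionResult:
    """Output of :func:`detect_stream` for one leg."""

    t: np.ndarray
    phases: np.ndarray          # array of Phase, one per sample
    events: list[GaitEvent]
    impulses: list[EventImpulse]
    cycle_boundaries: list[float]   # heel-strike times delimiting gait cycles
    side: Side = Side.LEFT


def _coerce_samples(stream, side: Side) -> list[ContactSample]:
    if isinstance(stream, pd.DataFrame):
        required = {"t", "heel", "toe", "shank_angle"}
        missing = required - set(stream.columns)
        if missing:
            raise ValueError(f"sensor frame missing columns: {sorted(missing)}")
        return [ContactSample(t=float(r.t), heel=float(r.heel), toe=float(r.toe),
                              shank_angle=float(r.shank_angle), side=side)
                for r in stream.itertuples(index=False)]
    return list(stream)


def detect_stream(stream, config: FsmConfig | None = None,
                  side: Side = Side.LEFT) -> DetectionResult:
    """Run the full detector over a sorted sensor stream.

    ``stream`` is a DataFrame with columns ``t, heel, toe, shank_angle``
    or an iterable of :class:`ContactSample`.  Threshold running maxima
    are seeded from the stream's own force maxima (offline processing has
    the whole stream available; online use can seed explicitly via
    :class:`GaitPhaseDetector`).
    """
    config = config or FsmConfig()
    samples = _coerce_samples(stream, side)
    if not samples:
        return DetectionResult(np.empty(0), np.empty(0, dtype=object), [], [], [], side)
    t_arr = np.array([s.t for s in samples])
    if np.any(np.diff(t_arr) <= 0):
        raise ValueError("sample times must be strictly increasing")

    seed_h = max(s.heel for s in samples)
    seed_t = max(s.toe for s in samples)
    det = GaitPhaseDetector(config, side=side, seed_heel_max=seed_h, seed_toe_max=seed_t)

    phases = np.empty(len(samples), dtype=object)
    events: list[GaitEvent] = []
    impulses: list[EventImpulse] = []
    for i, s in enumerate(samples):
        phase, ev, imp = det.step(s)
        phases[i] = phase
        events.extend(ev)
        impulses.extend(imp)
    events.sort(key=lambda e: e.t)
    impulses.sort(key=lambda e: e.t)

    heel_led = [t for t, led in det._hs_heel_led if led]
    boundaries = heel_led if heel_led else [t for t, _ in det._hs_heel_led]
    return DetectionResult(t_arr, phases, events, impulses, boundaries, side)


@dataclass
class MatchStats:
    """Per-event-kind detection quality (recall and latency)."""

    n_truth: int
    n_matched: int
    accuracy_pct: float        # matched / truth * 100; NaN if no truth
    mean_latency_ms: float     # mean(detected - truth) over matches; NaN if none


def _greedy_match(det_times: np.ndarray, truth_times: np.ndarray, tol: float):
    """One-to-one greedy matching in time order; returns latencies (s)."""
    latencies = []
    j = 0
    for tt in truth_times:
        while j < len(det_times) and det_times[j] < tt - tol:
            j += 1
        if j < len(det_times) and abs(det_times[j] - tt) <= tol:
            latencies.append(det_times[j] - tt)
            j += 1
    return latencies


def evaluate_detection(detected: list[GaitEvent], truth: list[GaitEvent],
                       tol: float = 0.05) -> dict[EventKind, MatchStats]:
    """Greedy one-to-one event matching within ``tol`` seconds.

    Events are matched within the same (side, kind) group; results are
    aggregated per kind.  Accuracy is per-event recall (matched / truth,
    in percent) — undefined (NaN) for kinds absent from the truth list.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    kinds = sorted({e.kind for e in truth}, key=lambda k: k.value)
    out: dict[EventKind, MatchStats] = {}
    for kind in kinds:
        n_truth = 0
        latencies: list[float] = []
        for side in Side:
            tt = np.sort([e.t for e in truth if e.kind == kind and e.side == side])
            dt_ = np.sort([e.t for e in detected if e.kind == kind and e.side == side])
            n_truth += len(tt)
            latencies.extend(_greedy_match(dt_, tt, tol))
        n_matched = len(latencies)
        acc = 100.0 * n_matched / n_truth if n_truth else float("nan")
        lat = 1000.0 * float(np.mean(latencies)) if latencies else float("nan")
        out[kind] = MatchStats(n_truth, n_matched, acc, lat)
    return out


def overall_recall_pct(stats: dict[EventKind, MatchStats]) -> float:
    """Pooled recall across event kinds, in percent."""
    n_truth = sum(s.n_truth for s in stats.values())
    n_matched = sum(s.n_matched for s in stats.values())
    return 100.0 * n_matched / n_truth if n_truth else float("nan")
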