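"""Configuration, logging, cycle normalization and session summaries.

All on-disk formats are flat text: YAML for configuration, CSV for
sensor/stimulation/adaptation traces (UTF-8, '.' decimal separator,
times in seconds to six decimals) and JSON-lines for event records, so
runs diff cleanly and golden files stay stable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adaptive_ilc import (DPHI_THRESHOLD, DT_THRESHOLD, L_PW, L_STEP, PW_BOUNDS,
                           TAU_BOUNDS, AdaptiveState)
from .gait_fsm import EventImpulse, EventKind, FsmConfig, GaitEvent, ImpulseKind, Phase
from .reflexive_controller import (ConfigurationError, DEFAULT_CALIBRATION,
                                   MuscleChannelConfig)
from .response_core import Muscle, Side
from .synthetic_gait import (GaitModelParams, SessionLog, SpeedProtocol,
                             SyntheticSession)


class ConfigError(ValueError):
    """Raised for malformed or incomplete session configuration."""


@dataclass
class IlcSettings:
    """Iterative-learning constants; defaults are the printed values."""

    l_step: float = L_STEP
    l_pw: float = L_PW
    dt_threshold: float = DT_THRESHOLD
    dphi_threshold: float = DPHI_THRESHOLD
    tau_min: float = TAU_BOUNDS[0]
    tau_max: float = TAU_BOUNDS[1]
    pw_min: float = PW_BOUNDS[0]
    pw_max: float = PW_BOUNDS[1]
    tau_init: float = 0.1
    pw_init: float = 300.0
    flip_tau_sign: bool = False


@dataclass
class SessionConfig:
    """Everything a run needs: sample rate, FSM thresholds, ILC constants,
    per-channel calibration, speed protocol and the noise seed."""

    sample_rate: float = 100.0
    fsm: FsmConfig = field(default_factory=FsmConfig)
    ilc: IlcSettings = field(default_factory=IlcSettings)
    gait: GaitModelParams = field(default_factory=GaitModelParams)
    protocol: SpeedProtocol = field(default_factory=SpeedProtocol)
    calibration: dict = field(default_factory=dict)   # side -> muscle -> fields
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.calibration:
            self.calibration = {
                side.value: {
                    muscle.value: {"c_min": cmin, "c_max": cmax,
                                   "pulse_width_us": 300.0, "stim_frequency_hz": 25.0}
                    for muscle, (cmin, cmax) in DEFAULT_CALIBRATION.items()}
                for side in Side}

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "sample_rate": self.sample_rate,
            "seed": self.seed,
            "fsm": dataclasses.asdict(self.fsm),
            "ilc": dataclasses.asdict(self.ilc),
            "gait": dataclasses.asdict(self.gait),
            "protocol": dataclasses.asdict(self.protocol),
            "calibration": self.calibration,
        }
        d["gait"]["phase_fractions"] = {
            p.value: v for p, v in self.gait.phase_fractions.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        try:
            gait = dict(d.get("gait", {}))
            if "phase_fractions" in gait:
                gait["phase_fractions"] = {
                    Phase(k): v for k, v in gait["phase_fractions"].items()}
            return cls(
                sample_rate=d.get("sample_rate", 100.0),
                seed=d.get("seed", 0),
                fsm=FsmConfig(**d.get("fsm", {})),
                ilc=IlcSettings(**d.get("ilc", {})),
                gait=GaitModelParams(**gait),
                protocol=SpeedProtocol(**d.get("protocol", {})),
                calibration=d.get("calibration", {}),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid session config: {exc}") from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(raw)

    # -- builders ----------------------------------------------------------

    def build_channels(self) -> dict:
        """Instantiate the 8-channel configuration from the calibration map."""
        channels = {}
        for side in Side:
            per_side = self.calibration.get(side.value)
            if per_side is None:
                raise ConfigurationError(f"calibration missing side {side.value!r}")
            for muscle in Muscle:
                entry = per_side.get(muscle.value)
                if entry is None:
                    raise ConfigurationError(
                        f"calibration missing {side.value}.{muscle.value}")
                if not {"c_min", "c_max"} <= set(entry):
                    raise ConfigurationError(
                        f"calibration {side.value}.{muscle.value} needs c_min and c_max")
                channels[(side, muscle)] = MuscleChannelConfig(
                    muscle_id=muscle, side=side,
                    c_min=float(entry["c_min"]), c_max=float(entry["c_max"]),
                    pulse_width_us=float(entry.get("pulse_width_us", 300.0)),
                    stim_frequency_hz=float(entry.get("stim_frequency_hz", 25.0)),
                    tau=float(entry.get("tau_init", self.ilc.tau_init)))
        return channels

    def build_adaptive_state(self) -> AdaptiveState:
        ilc = self.ilc
        return AdaptiveState.default(
            tau_init=ilc.tau_init, pw_init=ilc.pw_init,
            l_step=ilc.l_step, l_pw=ilc.l_pw,
            dt_threshold=ilc.dt_threshold, dphi_threshold=ilc.dphi_threshold,
            tau_bounds=(ilc.tau_min, ilc.tau_max),
            pw_bounds=(ilc.pw_min, ilc.pw_max),
            flip_tau_sign=ilc.flip_tau_sign)


# ---------------------------------------------------------------------------
# Gait-cycle time normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedCycle:
    """One cycle resampled onto the 0..100 % grid (101 samples)."""

    percent: np.ndarray
    values: np.ndarray
    cycle_index: int = 0

    def __post_init__(self) -> None:
        if len(self.percent) != 101 or len(self.values) != 101:
            raise ValueError("a normalized cycle has exactly 101 samples")


def time_normalize(values, times=None, cycle_index: int = 0) -> NormalizedCycle:
    """Resample one cycle trace onto 0–100 % of the gait cycle (101 samples).

    Linear interpolation; with ``times`` omitted the samples are assumed
    uniformly spaced over the cycle.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("cycle trace needs at least 2 samples")
    if times is None:
        times = np.arange(len(values), dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) != len(values):
        raise ValueError("times and values must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    grid = np.linspace(times[0], times[-1], 101)
    return NormalizedCycle(percent=np.arange(101), values=np.interp(grid, times, values),
                           cycle_index=cycle_index)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_session(log: SessionLog, protocol: SpeedProtocol | None = None) -> dict:
    """Deterministic descriptive summary of a closed-loop run.

    Returns ``{"channels": DataFrame, "levels": DataFrame}``: per-channel
    mean stimulation time, tau trajectory endpoints, change and burst
    counts; and (when the speed protocol is known) one row per visited
    speed level.  This summarizes synthetic runs only — it does not
    reproduce any human-subject statistics.
    """
    records = log.adaptation
    chan_rows = []
    for side in Side:
        for muscle in Muscle:
            key = (side, muscle)
            t_s = [r.t_s[key] for r in records if key in r.t_s]
            taus = [r.tau[key] for r in records if key in r.tau]
            n_changes = int(np.count_nonzero(np.abs(np.diff(taus)) > 1e-15)) if len(taus) > 1 else 0
            sub = log.stim[(log.stim["side"] == side.value)
                           & (log.stim["muscle"] == muscle.value)]
            active = (sub["amplitude_mA"].to_numpy() > 0).astype(int)
            bursts = int(np.count_nonzero(np.diff(active) == 1) + (active[:1] == 1).sum()) \
                if len(active) else 0
            row = {"side": side.value, "muscle": muscle.value,
                   "n_cycles": len(t_s),
                   "mean_t_s": float(np.mean(t_s)) if t_s else float("nan"),
                   "tau_first": taus[0] if taus else float("nan"),
                   "tau_final": taus[-1] if taus else float("nan"),
                   "n_tau_changes": n_changes,
                   "n_bursts": bursts}
            if muscle is Muscle.LG:
                pws = [r.pw[side] for r in records if side in r.pw]
                row["pw_final_us"] = pws[-1] if pws else float("nan")
            chan_rows.append(row)
    channels = pd.DataFrame(chan_rows)

    level_rows = []
    if protocol is not None and records:
        cpl = protocol.cycles_per_level
        levels = protocol.levels()
        for i, speed in enumerate(levels):
            rs = [r for r in records if i * cpl <= r.n < (i + 1) * cpl]
            if not rs:
                continue
            all_ts = [v for r in rs for v in r.t_s.values()]
            all_phi = [v for r in rs for v in r.phi_to.values()]
            level_rows.append({
                "level_index": i, "speed_kmh": speed, "n_cycles": len(rs),
                "mean_t_s": float(np.mean(all_ts)) if all_ts else float("nan"),
                "mean_phi_to": float(np.mean(all_phi)) if all_phi else float("nan")})
    levels_df = pd.DataFrame(level_rows)
    return {"channels": channels, "levels": levels_df}


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6f"


def write_sensors_csv(session: SyntheticSession, path) -> None:
    frames = []
    for side, df in session.samples.items():
        d = df.copy()
        d["side"] = side.value
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=_FLOAT_FMT)


def read_sensors_csv(path) -> dict:
    df = pd.read_csv(path)
    required = {"t", "heel", "toe", "shank_angle", "side"}
    if not required <= set(df.columns):
        raise ConfigError(f"sensor CSV needs columns {sorted(required)}")
    return {Side(s): g.drop(columns="side").reset_index(drop=True)
            for s, g in df.groupby("side")}


def write_events_jsonl(events, path) -> None:
    with open(path, "w") as fh:
        for e in sorted(events, key=lambda e: (e.t, e.kind.value, e.side.value)):
            fh.write(json.dumps({"t": round(e.t, 6), "kind": e.kind.value,
                                 "side": e.side.value}) + "\n")


def read_events_jsonl(path) -> list[GaitEvent]:
    events = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        kind = d["kind"]
        if kind in ImpulseKind._value2member_map_:
            continue  # tolerate mixed event/impulse logs
        events.append(GaitEvent(EventKind(kind), float(d["t"]), Side(d["side"])))
    return events


def write_impulses_jsonl(impulses, path) -> None:
    with open(path, "w") as fh:
        for e in sorted(impulses, key=lambda e: (e.t, e.kind.value, e.side.value)):
            fh.write(json.dumps({"t": round(e.t, 6), "kind": e.kind.value,
                                 "side": e.side.value}) + "\n")


def write_phases_csv(detections: dict, path) -> None:
    frames = []
    for side, det in detections.items():
        frames.append(pd.DataFrame({"t": det.t, "side": side.value,
                                    "phase": [p.value for p in det.phases]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=_FLOAT_FMT)


def write_stim_csv(stim: pd.DataFrame, path) -> None:
    stim.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_adaptation_csv(adaptation, path) -> None:
    """Flatten the per-cycle adaptation log: one row per cycle per channel."""
    rows = []
    for rec in adaptation:
        for side in Side:
            for muscle in Muscle:
                key = (side, muscle)
                if key not in rec.t_s:
                    continue
                rows.append({
                    "cycle": rec.n,
                    "speed_kmh": rec.speed_kmh,
                    "side": side.value, "muscle": muscle.value,
                    "t_s": rec.t_s[key],
                    "phi_TO": rec.phi_to.get(side, float("nan")),
                    "tau": rec.tau[key],
                    "pw": rec.pw[side] if muscle is Muscle.LG else float("nan")})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_evaluation_json(stats: dict, path) -> None:
    out = {kind.value: {"n_truth": s.n_truth, "n_matched": s.n_matched,
                        "accuracy_pct": None if np.isnan(s.accuracy_pct) else round(s.accuracy_pct, 3),
                        "mean_latency_ms": None if np.isnan(s.mean_latency_ms) else round(s.mean_latency_ms, 3)}
           for kind, s in stats.items()}
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
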