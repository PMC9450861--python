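"""State gates, channel amplitudes, and equivalence with a brute-force
convolution oracle."""

import numpy as np
import pytest

from reflexfes import (BRANCHES, ConfigurationError, EventImpulse, ImpulseKind,
                       Muscle, MuscleChannelConfig, Phase, ReflexiveController, Side,
                       activation_duration, channel_amplitude, default_channels,
                       detect_stream, generate_channel_trace, impulse_response,
                       peak_time, state_gate)

ALL_PHASES = list(Phase)


def _cfg(muscle=Muscle.TA, tau=0.1, c_min=10.0, c_max=25.0, **kw):
    return MuscleChannelConfig(muscle_id=muscle, side=Side.LEFT, c_min=c_min,
                               c_max=c_max, tau=tau, **kw)


class TestStateGate:
    @pytest.mark.parametrize("muscle,branch,on_phases", [
        (Muscle.TA, "SW", {Phase.SW, Phase.TSW}),
        (Muscle.BF, "SW", {Phase.SW, Phase.TSW}),
        (Muscle.LG, "LR", {Phase.LR}),
        (Muscle.LG, "PS", {Phase.PS}),
        (Muscle.RF, "LR", {Phase.LR}),
        (Muscle.RF, "TSW", {Phase.TSW}),
    ])
    def test_gate_truth_table(self, muscle, branch, on_phases):
        for phase in ALL_PHASES:
            assert state_gate(muscle, branch, phase) == int(phase in on_phases)

    def test_unknown_branch_rejected(self):
        with pytest.raises(ValueError):
            state_gate(Muscle.TA, "LR", Phase.SW)

    def test_two_branch_gates_are_mutually_exclusive(self):
        for muscle in (Muscle.LG, Muscle.RF):
            b1, b2 = BRANCHES[muscle]
            for phase in ALL_PHASES:
                assert not (phase in b1.gate_phases and phase in b2.gate_phases)


class TestChannelAmplitude:
    def test_gate_off_outputs_zero(self):
        cfg = _cfg()
        imp = EventImpulse(ImpulseKind.I_SW, 0.0, Side.LEFT)
        assert channel_amplitude(cfg, imp, Phase.ST, 0.05) == 0.0

    def test_envelope_starts_at_c_min(self):
        cfg = _cfg()
        imp = EventImpulse(ImpulseKind.I_SW, 1.0, Side.LEFT)
        assert channel_amplitude(cfg, imp, Phase.SW, 1.0) == pytest.approx(cfg.c_min)

    def test_envelope_peaks_at_c_max(self):
        cfg = _cfg(tau=0.2)
        imp = EventImpulse(ImpulseKind.I_SW, 1.0, Side.LEFT)
        t_pk = 1.0 + peak_time(0.2)
        assert channel_amplitude(cfg, imp, Phase.SW, t_pk) == pytest.approx(cfg.c_max)

    def test_gate_on_without_impulse_rests_at_c_min(self):
        cfg = _cfg()
        assert channel_amplitude(cfg, None, Phase.SW, 3.0) == pytest.approx(cfg.c_min)

    def test_invalid_calibration_rejected(self):
        with pytest.raises(ConfigurationError):
            _cfg(c_min=25.0, c_max=10.0)
        with pytest.raises(ConfigurationError):
            _cfg(muscle=Muscle.LG, pulse_width_us=600.0)


class TestController:
    def test_missing_channel_is_configuration_error(self):
        channels = default_channels()
        channels.pop((Side.LEFT, Muscle.TA))
        with pytest.raises(ConfigurationError):
            ReflexiveController(channels)

    def test_tick_emits_eight_commands_with_bounded_amplitudes(self):
        ctl = ReflexiveController(default_channels())
        phases = {Side.LEFT: Phase.SW, Side.RIGHT: Phase.ST}
        imp = EventImpulse(ImpulseKind.I_SW, 0.0, Side.LEFT)
        for t in np.arange(0.0, 0.3, 0.01):
            cmds = ctl.tick(t, phases, [imp] if t == 0.0 else [])
            assert len(cmds) == 8
            for c in cmds:
                cfg = ctl.channels[(c.side, c.muscle_id)]
                assert 0.0 <= c.amplitude_ma <= cfg.c_max + 1e-12

    def test_streaming_matches_vectorized_trace(self, small_session):
        det = detect_stream(small_session.samples[Side.LEFT])
        channels = default_channels()
        ctl = ReflexiveController(channels)
        imp_iter = iter(sorted(det.impulses, key=lambda i: i.t))
        pending = next(imp_iter, None)
        streamed = {m: [] for m in Muscle}
        for t, phase in zip(det.t, det.phases):
            new = []
            while pending is not None and pending.t <= t:
                new.append(pending)
                pending = next(imp_iter, None)
            cmds = ctl.tick(float(t), {Side.LEFT: phase}, new)
            for c in cmds:
                if c.side is Side.LEFT:
                    streamed[c.muscle_id].append(c.amplitude_ma)
        for muscle in Muscle:
            vec = generate_channel_trace(channels[(Side.LEFT, muscle)], det.t,
                                         det.phases, det.impulses)
            assert np.max(np.abs(np.array(streamed[muscle]) - vec)) < 1e-9

    def test_lg_and_rf_fire_two_bursts_per_cycle(self, small_session):
        det = detect_stream(small_session.samples[Side.LEFT])
        channels = default_channels()
        bounds = det.cycle_boundaries
        for muscle, expected in ((Muscle.LG, 2), (Muscle.RF, 2),
                                 (Muscle.TA, 1), (Muscle.BF, 1)):
            amp = generate_channel_trace(channels[(Side.LEFT, muscle)], det.t,
                                         det.phases, det.impulses)
            a, b = bounds[3], bounds[4]  # one interior cycle, (a, b] windows
            mask = (det.t > a) & (det.t <= b)
            active = (amp[mask] > 0).astype(int)
            rising = int(np.count_nonzero(np.diff(active) == 1) + (active[0] == 1))
            assert rising == expected

    def test_no_impulses_yield_gated_c_min(self):
        cfg = _cfg()
        t = np.arange(0, 1, 0.01)
        phases = np.array([Phase.SW] * 50 + [Phase.ST] * 50, dtype=object)
        amp = generate_channel_trace(cfg, t, phases, [])
        assert np.allclose(amp[:50], cfg.c_min) and np.all(amp[50:] == 0.0)

    def test_new_impulse_restarts_envelope(self):
        cfg = _cfg(tau=0.2)
        t0, t1 = 0.0, 0.1  # second impulse arrives mid-envelope
        imps = [EventImpulse(ImpulseKind.I_SW, t0, Side.LEFT),
                EventImpulse(ImpulseKind.I_SW, t1, Side.LEFT)]
        t = np.arange(0.0, 0.6, 0.005)
        phases = np.array([Phase.SW] * len(t), dtype=object)
        amp = generate_channel_trace(cfg, t, phases, imps)
        assert np.all(amp <= cfg.c_max + 1e-12)
        # right after the restart the envelope is back near its origin
        i = int(round(t1 / 0.005))
        assert amp[i] == pytest.approx(cfg.c_min)
        # and peaks at C_max at t1 + peak_time
        j = int(round((t1 + peak_time(0.2)) / 0.005))
        assert amp[j] == pytest.approx(cfg.c_max, abs=0.05)


class TestConvolutionOracle:
    def _oracle(self, cfg, t, phases, impulses):
        """Brute-force discrete convolution of the impulse train with the
        sampled truncated envelope, then gating and clamping."""
        dt = t[1] - t[0]
        amp = np.zeros_like(t)
        for br in BRANCHES[cfg.muscle_id]:
            gate = np.array([p in br.gate_phases for p in phases], dtype=float)
            train = np.zeros_like(t)
            for imp in impulses:
                if imp.kind == br.trigger:
                    train[int(round((imp.t - t[0]) / dt))] = 1.0
            env = impulse_response(cfg.transfer[br.name], np.arange(len(t)) * dt)
            conv = np.convolve(train, env)[:len(t)]
            amp += gate * (conv * cfg.delta_c + cfg.c_min)
        return np.clip(amp, 0.0, cfg.c_max)

    @pytest.mark.parametrize("muscle", list(Muscle))
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_controller_equals_convolution(self, muscle, seed):
        rng = np.random.default_rng(seed)
        dt = 0.01
        n_cycles, cycle_len = 10, 1.0
        t = np.arange(0, n_cycles * cycle_len, dt)
        tau = float(rng.uniform(0.05, 0.35))  # envelope shorter than one cycle
        cfg = _cfg(muscle=muscle, tau=tau, c_min=8.0, c_max=30.0)
        # random phase schedule: each cycle split into the five phases
        phases = np.empty(len(t), dtype=object)
        impulses = []
        for c in range(n_cycles):
            cuts = np.sort(rng.choice(np.arange(1, 99), size=4, replace=False))
            for block, phase in zip(np.split(np.arange(100), cuts), list(Phase)):
                phases[c * 100 + block] = phase
            # one jittered impulse per kind per cycle; same-kind spacing stays
            # above the envelope duration, where restart == superposition
            for kind in [ImpulseKind.I_LR, ImpulseKind.I_PS, ImpulseKind.I_SW,
                         ImpulseKind.I_TSW]:
                j = int(rng.integers(0, 13))
                impulses.append(EventImpulse(kind, t[c * 100 + j], Side.LEFT))
        vec = generate_channel_trace(cfg, t, phases, impulses)
        oracle = self._oracle(cfg, t, phases, impulses)
        assert np.max(np.abs(vec - oracle)) < 1e-9
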