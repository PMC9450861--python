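# Methods

This note documents the models, numerical choices and known limitations of
`reflexfes`.  It is written for users who want to understand what the
toolkit computes and what passing its tests does and does not demonstrate.

## Stimulation envelope

Every stimulation burst is shaped by the impulse response of a second-order
low-pass Bessel-type filter,

    H(t) = g · (1/τ) · e^(−1.5 t/τ) · sin(1.5 t/τ),

with time coefficient τ (seconds) and gain g.  With the normalizing gain
g = τ·√2·e^(π/4) the peak equals 1, so the envelope maps linearly onto each
muscle's calibrated current range [C_min, C_max].  Closed forms used
throughout: the peak sits at t = πτ/6 (from tan(1.5t/τ) = 1) and the first
post-peak zero at t = 2πτ/3, making the rise time exactly one fourth of the
burst duration; the associated cut-off frequency is f_c = 1/(2πτ).

Two deliberate choices:

* **Truncation.**  The sinusoid makes the raw expression negative after
  2πτ/3.  Negative stimulation amplitude is meaningless, so H is truncated
  to zero there: each burst is a single non-negative lobe.
* **Literal coefficients.**  The damping and frequency terms (1.5/τ and
  3/(2τ)) are taken as given; no attempt is made to re-derive them from a
  canonical Bessel pole layout, since only the time-domain envelope is used.

H is evaluated lazily per sample at the session sample rate; there is no
precomputed lookup table.

## Gait-phase detection

**Binarization.**  The heel/toe force channels use hysteresis thresholds at
20 % (on) and 10 % (off) of an exponentially decayed running maximum
(e-folding time 3.6 s ≈ three gait cycles).  Relative thresholds make
detection invariant under monotone rescaling of the force signals and
robust to slow drift; the running maximum can be seeded explicitly when a
stream starts mid-gait (offline, it is seeded from the stream's own
maxima).  The shank-angle bit S_φ is a plain threshold at 15° forward
rotation by default (configurable; it must match the generator's
terminal-swing crossing angle when evaluating on synthetic data).

**Debouncing.**  A bit must hold its new value for 2 consecutive samples to
count as an edge (FSR chatter suppression).  Edges are timestamped
*retroactively* at the first sample of the new value, so debouncing delays
emission but not the recorded event time; on clean data the detection
latency is at most one sample period.

**State machine.**  The four impulse-generating transitions operate on the
contact bits exactly as stated in the module docstring; LR→ST (the FF
event) additionally requires both sensors in contact for a 50 ms dwell
window, since no bit transition distinguishes it.  Unexpected bit patterns
keep the current phase rather than raising, because a wearable detector
must keep running through sensor glitches.  The STA transition is
single-shot per swing: it only fires out of SW, and the phase moves to TSW.
Legs are processed as fully independent state machines.

**Cycle boundaries** are heel strikes with the heel leading (S_H=1, S_T=0
at the strike).  If a stream contains no heel-led strike at all
(forefoot-first pathological contact), all initial-contact events are used
instead.

**Evaluation** reports per-event recall: detected and ground-truth events
of the same kind and side are greedily matched one-to-one within a
tolerance (50 ms by default), accuracy = matched/truth × 100 per kind, and
latency is the mean signed detected−truth difference over matches.  A
per-sample (phase-trace) accuracy definition would be an alternative; the
per-event definition is the one implemented and reported.

## Reflexive controller

Each of the 8 channels owns one or two branches (trigger impulse + phase
gate); the branch tables are in `reflexive_controller.BRANCHES`.  Choices:

* **Restart, not superposition.**  A new qualifying impulse resets the
  branch clock.  The branch gates are disjoint phases, so overlapping
  envelopes could only arise from repeated same-kind impulses (e.g. sensor
  chatter); restarting guarantees the amplitude never exceeds C_max.
  Outputs are clamped to [0, C_max] regardless and clamped samples counted.
* **TA triggering.**  TA's envelope is triggered by I_SW, consistent with
  its swing-phase gate; likewise BF.  LG is triggered by I_LR and I_PS on
  separate branches, RF by I_LR and I_TSW.
* **Commands are amplitude samples** at the session sample rate, not
  biphasic pulse trains; pulse-level waveform synthesis, electrode models
  and stimulator safety interlocks are out of scope.  Stimulation frequency
  is a constant per-channel setting (default 25 Hz) carried through the
  config but not otherwise used.
* Non-LG channels keep a constant pulse width (default 300 μs); only LG's
  pulse width is adapted.

Default calibration currents (TA 10–25 mA, LG 12–28 mA, BF/RF 15–35 mA) are
typical for healthy adults and stand in for a per-participant measurement
session; real use supplies them via the YAML config.

## Iterative-learning adaptation

The update laws, steps (L = 0.01 s, L_PW = 20 μs), dead zones (0.04 s, 2°)
and clamps (τ ∈ [0.01, 1] s, PW ∈ [250, 500] μs) are implemented exactly as
stated, with strict inequalities: a deviation of exactly ±threshold
produces no update.  Further choices:

* **Warm-up.**  No updates until the ring buffer holds five complete
  cycles; the current cycle is compared first and enters the buffer after,
  so the buffer is strictly the previous five cycles.
* **t_s semantics.**  The stimulation time is the *delivered* duration:
  total time within the cycle with amplitude strictly above C_min (gate
  open and envelope positive), summed across branches.  When the phase gate
  is longer than the envelope, t_s saturates at the envelope duration
  2πτ/3 and stops tracking gait tempo; when the gate truncates the burst,
  t_s tracks the phase duration.
* **Update direction.**  As printed, a shorter-than-average t_s increases
  τ.  For gate-truncated bursts this lengthens the envelope as phases
  shorten, which is arguably the de-stabilizing direction; the config flag
  `flip_tau_sign` (default off) inverts it without changing anything else.
* **φ_TO** uses the raw (unfiltered) shank-angle sample at the detected
  toe-off.
* Initial values τ = 0.1 s and PW = 300 μs for all channels, configurable.

## Synthetic gait generator

The generator emulates: periodic stance/swing contact plateaus (heel down
from HS to HO, toe down from FF to TO), a smooth shank-angle trajectory
built from monotone piecewise-cubic (PCHIP) segments that attains φ_TO at
toe-off, dips during swing and rises through the terminal-swing threshold
exactly at the scheduled STA instant, additive Gaussian sensor noise, a
half-cycle offset between legs, and the up-then-down speed ramp with every
visited level contributing its configured cycle count (11 levels × 15
cycles = 165 by default, each level counted each time it is visited).

Defaults, chosen once as representative values: phase fractions LR 10 %,
ST 30 %, PS 10 %, SW 37 %, TSW 13 % (standard gait-cycle conventions);
cycle duration linear in belt speed, 1.4 s at 1.0 km/h to 1.0 s at
2.0 km/h; contact-force plateau 100 a.u. with noise SD 2 a.u.; shank angle
20° at heel strike, −10° swing minimum, noise SD 0.5°; sampling at 100 Hz.
The toe-off angle ramps from 10° at 1.0 km/h to 14° at 2.0 km/h — kept
below the 15° STA threshold by construction, because a swing-onset angle at
or above the threshold would fire the terminal-swing transition at toe-off
instead of at the scheduled crossing.

Two consistency-critical details: all scheduled event times are snapped to
the sample grid, and contact transitions ramp within 5 ms (less than one
sample period), so the detector's ≤1-sample-latency contract is exact
rather than alignment-dependent.  The first cycle of a stream starts with
the shank angle below the STA threshold so the detector (which boots in
swing) cannot fire a spurious terminal-swing transition before the first
heel strike.

**What the generator does not emulate** — and hence what passing tests do
not show: musculoskeletal dynamics and joint kinematics (no hip/knee/ankle
plant; stimulation has no effect on the simulated gait), muscle fatigue,
FSR nonlinearity and saturation, IMU orientation-fusion error, spike
artifacts (available as an option, off by default via the noise model), and
inter-leg coordination constraints.  Detection accuracy of 100 % on this
generator is a clean-signal upper bound, not a claim about human data; the
human-subject joint-kinematics comparisons that motivate such controllers
require real participants and are out of scope.

## Closed-loop integration

Detection runs per leg over the whole stream; the controller synthesizes
amplitude traces cycle by cycle with the τ values current at that cycle;
after each cycle index the ILC update runs and the new parameters take
effect from the next cycle.  Left and right cycles are paired by index for
the update (the legs are half a cycle out of phase, so the pairing is
accurate to half a cycle); the adaptation log holds one record per cycle
index with all eight channels.  On constant-speed clean sessions all
deviations sit inside the dead zones and parameters provably stay constant
— the toolkit's speed ramp changes phase durations by less than the 0.04 s
dead zone per level, so τ adaptation on clean synthetic data is quiescent
by design, and forced-deviation sequences are used to exercise the update
law itself.

## Problem sizes

The default test and acceptance runs use the full 165-cycle two-leg session
(~200 s of gait at 100 Hz, ≈20 000 samples per leg) for detection checks,
10-cycle instances for controller-oracle equivalence (tolerance 1e−9 mA),
and 200/50-cycle forced sequences for the saturation checks; these sizes
complete in seconds while covering every speed level of the protocol.
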