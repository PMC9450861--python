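"""Stimulation envelope model.

The reflexive controller shapes every stimulation burst with the impulse
response of a second-order low-pass Bessel-type filter,

    H(t) = g * (1/tau) * exp(-1.5 t / tau) * sin(1.5 t / tau),

where ``tau`` (seconds) sets the burst time scale and the gain ``g``
normalizes the peak to 1 so the envelope maps linearly onto a muscle's
calibrated current range [C_min, C_max].

The sinusoidal factor makes the raw expression go negative after its
first post-peak zero crossing at t = 2*pi*tau/3.  Stimulation amplitude
below C_min is meaningless, so the envelope is truncated to zero beyond
that crossing and every burst is a single non-negative lobe.

Closed-form timing quantities used throughout the package:

* peak time            t_peak = pi*tau/6      (argmax of H)
* activation duration  t_act  = 2*pi*tau/3    (first post-peak zero)
* t_peak / t_act       = 1/4 for every tau
* cut-off frequency    f_c = 1 / (2*pi*tau)
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

#: Admissible range for the time coefficient tau, in seconds.
TAU_BOUNDS = (0.01, 1.0)


class Muscle(str, enum.Enum):
    """The four stimulated muscles per leg."""

    TA = "TA"  #: tibialis anterior (ankle dorsiflexion)
    LG = "LG"  #: lateral gastrocnemius (ankle plantarflexion / push-off)
    BF = "BF"  #: biceps femoris (knee flexion, hip extension)
    RF = "RF"  #: rectus femoris (knee extension, hip flexion)


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


def _validate_tau(tau: float) -> float:
    tau = float(tau)
    if not math.isfinite(tau) or not (TAU_BOUNDS[0] <= tau <= TAU_BOUNDS[1]):
        raise ValueError(
            f"tau must lie in [{TAU_BOUNDS[0]}, {TAU_BOUNDS[1]}] s, got {tau!r}"
        )
    return tau


def normalizing_gain(tau: float) -> float:
    """Gain ``g`` that makes ``max_t H(t) = 1``.

    At the peak, ``1.5 t/tau = pi/4``, so ``H(t_peak) = g/(tau*sqrt(2)) *
    exp(-pi/4)``; the normalizing gain is therefore ``tau*sqrt(2)*exp(pi/4)``
    (linear in tau).
    """
    tau = _validate_tau(tau)
    return tau * math.sqrt(2.0) * math.exp(math.pi / 4.0)


def peak_time(tau: float) -> float:
    """Time-to-peak of the envelope, ``pi*tau/6`` seconds."""
    return math.pi * _validate_tau(tau) / 6.0


def activation_duration(tau: float) -> float:
    """Duration of the single stimulation lobe, ``2*pi*tau/3`` seconds.

    This is the first zero crossing after the peak, beyond which the
    envelope is truncated to zero.  ``peak_time / activation_duration``
    is exactly 1/4 for every tau.
    """
    return 2.0 * math.pi * _validate_tau(tau) / 3.0


def cutoff_frequency(tau: float) -> float:
    """Filter cut-off frequency ``f_c = 1/(2*pi*tau)`` in hertz."""
    tau = float(tau)
    if not math.isfinite(tau) or tau <= 0:
        raise ValueError(f"tau must be a positive finite number, got {tau!r}")
    return 1.0 / (2.0 * math.pi * tau)


@dataclass
class TransferFunctionParams:
    """Parameters of one muscle branch's impulse-response envelope.

    Attributes
    ----------
    tau:
        Time coefficient in seconds, within :data:`TAU_BOUNDS`.
    g:
        Dimensionless gain; with ``g = normalizing_gain(tau)`` the peak
        of H equals 1.
    muscle_id, side, trigger:
        Optional bookkeeping: which channel this envelope belongs to and
        which gait-event impulse kind it is convolved with.
    """

    tau: float
    g: float
    muscle_id: Muscle | None = None
    side: Side | None = None
    trigger: object | None = None

    def __post_init__(self) -> None:
        _validate_tau(self.tau)
        if not math.isfinite(self.g) or self.g <= 0:
            raise ValueError(f"gain g must be positive, got {self.g!r}")

    @classmethod
    def normalized(cls, tau: float, **kwargs) -> "TransferFunctionParams":
        """Build parameters with the peak-normalizing gain for ``tau``."""
        return cls(tau=tau, g=normalizing_gain(tau), **kwargs)


def impulse_response(params: TransferFunctionParams, t):
    """Evaluate the truncated envelope H at time(s) ``t`` (seconds, >= 0).

    Returns a dimensionless amplitude fraction in [0, 1] for normalized
    gain: zero at t = 0, peaking at ``peak_time(tau)``, and zero for all
    t beyond ``activation_duration(tau)``.  Accepts scalars or arrays.
    """
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("t must be finite")
    if np.any(arr < 0):
        raise ValueError("t must be non-negative")
    x = 1.5 * arr / params.tau
    h = (params.g / params.tau) * np.exp(-x) * np.sin(x)
    h = np.where(arr <= activation_duration(params.tau), np.maximum(h, 0.0), 0.0)
    if arr.ndim == 0:
        return float(h)
    return h
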