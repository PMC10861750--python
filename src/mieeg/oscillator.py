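"""Van der Pol model of a small oscillating neuronal assembly.

A cortical assembly engaged in primary processing of a sensory stream is
modelled as the self-excited oscillator

    Y'' - (lambda - Y^2) Y' + p^2 Y = g * u(t)

where ``lambda`` is the bifurcation parameter, ``p`` the angular frequency
in rad/s and ``u(t)`` an additive external input scaled by the coupling
gain ``g``. For lambda <= 0 the origin is attracting and the assembly is
silent; for lambda > 0 it settles on a limit cycle of amplitude 2*sqrt(lambda)
(amplitude 2 at lambda = 1) at frequency close to p/2pi. A same-frequency
input captures the oscillator phase — the entrainment that represents
information transfer into the assembly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from ._kernels import vdp_rk4
from .timeseries import TimeSeries, check_compatible

__all__ = [
    "OscillatorParams",
    "OscillatorState",
    "vdp_derivatives",
    "simulate_oscillator",
    "measure_amplitude",
    "phase_sync_index",
    "dominant_frequency",
]

#: default initial state; slightly off the (unstable, for lambda>0) origin
DEFAULT_INIT = (0.1, 0.0)

#: trajectory magnitude considered a numerical blow-up
DEFAULT_BOUND = 1e6


@dataclass(frozen=True)
class OscillatorParams:
    """Constants of the assembly oscillator.

    lam : bifurcation parameter (dimensionless).
    p : angular frequency in rad/s, > 0.
    forcing_gain : coupling gain of the additive input, >= 0.
    """

    lam: float = 1.0
    p: float = 2 * math.pi * 10.0
    forcing_gain: float = 1.0

    def __post_init__(self):
        if not self.p > 0:
            raise ValueError("p must be > 0")
        if self.forcing_gain < 0:
            raise ValueError("forcing_gain must be >= 0")


@dataclass(frozen=True)
class OscillatorState:
    """Output Y and its time derivative."""

    y: float
    ydot: float


def vdp_derivatives(
    state: OscillatorState,
    params: OscillatorParams,
    forcing_value: float = 0.0,
) -> tuple[float, float]:
    """Right-hand side (dY/dt, dY'/dt) of the forced oscillator."""
    y, ydot = float(state.y), float(state.ydot)
    if not (math.isfinite(y) and math.isfinite(ydot)):
        raise FloatingPointError(
            "non-finite oscillator state: numerical blow-up"
        )
    acc = ((params.lam - y * y) * ydot - params.p**2 * y
           + params.forcing_gain * float(forcing_value))
    return (ydot, acc)


def simulate_oscillator(
    params: OscillatorParams,
    duration: float,
    dt: float = 1e-3,
    init: OscillatorState | tuple[float, float] | None = None,
    forcing: TimeSeries | None = None,
    bound: float = DEFAULT_BOUND,
) -> TimeSeries:
    """Fixed-step RK4 trajectory of Y(t).

    The forcing series, when given, must be sampled at 1/dt and is applied
    by zero-order hold. The step must resolve at least 10 steps per period
    of p. A trajectory exceeding `bound` raises, naming dt.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > 2 * math.pi / (10.0 * params.p):
        raise ValueError(
            f"dt={dt} too coarse: need >= 10 steps per period of "
            f"p={params.p} rad/s"
        )
    n = int(round(duration / dt)) + 1
    if n < 2:
        raise ValueError("duration must cover at least one step")
    if init is None:
        init = DEFAULT_INIT
    if isinstance(init, OscillatorState):
        init = (init.y, init.ydot)
    if forcing is None:
        f = np.zeros((n, 1))
    else:
        if not np.isclose(forcing.sampling_rate, 1.0 / dt):
            raise ValueError(
                "forcing must be sampled at 1/dt "
                f"({forcing.sampling_rate} Hz vs {1.0 / dt} Hz)"
            )
        if len(forcing) < n:
            raise ValueError("forcing shorter than the simulated duration")
        f = forcing.samples[:n, None]
    y0 = np.full(1, float(init[0]))
    yd0 = np.full(1, float(init[1]))
    out, blow = vdp_rk4(
        float(params.lam), float(params.p), float(params.forcing_gain),
        y0, yd0, np.ascontiguousarray(f, dtype=float), float(dt),
        float(bound),
    )
    if blow >= 0:
        raise FloatingPointError(
            f"oscillator trajectory exceeded |Y|={bound:g} at step {blow} "
            f"(t={blow * dt:.4f} s); dt={dt} may be too coarse"
        )
    return TimeSeries(out[:, 0], 1.0 / dt, t0=0.0)


def measure_amplitude(ts: TimeSeries, discard_fraction: float = 0.5) -> float:
    """Steady-state amplitude: half the peak-to-peak range of the tail."""
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    tail = ts.samples[int(len(ts) * discard_fraction):]
    if tail.size < 2:
        raise ValueError("retained segment empty after discard")
    return float(tail.max() - tail.min()) / 2.0


def phase_sync_index(ts: TimeSeries, reference: TimeSeries) -> float:
    """Phase-locking value between two oscillatory series, in [0, 1].

    Instantaneous phases come from the analytic signal; 1 means the phase
    difference is constant over the whole window (perfect locking).
    """
    check_compatible(ts, reference)
    a = np.angle(hilbert(ts.samples - ts.samples.mean()))
    b = np.angle(hilbert(reference.samples - reference.samples.mean()))
    return float(np.abs(np.mean(np.exp(1j * (a - b)))))


def dominant_frequency(ts: TimeSeries, discard_fraction: float = 0.0) -> float:
    """Frequency (Hz) of the largest non-DC spectral peak of the tail."""
    tail = ts.samples[int(len(ts) * discard_fraction):]
    if tail.size < 4:
        raise ValueError("series too short for a spectrum")
    spec = np.abs(np.fft.rfft(tail - tail.mean()))
    freqs = np.fft.rfftfreq(tail.size, ts.dt)
    return float(freqs[int(np.argmax(spec))])
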