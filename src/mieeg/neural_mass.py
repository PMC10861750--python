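"""Four-population neural mass model of the brain's advanced processing.

Pyramidal cells (1) interact with excitatory interneurons (2), slow
inhibitory interneurons (3) and fast inhibitory interneurons (4); the fast
inhibitory population additionally inhibits itself and owns an auxiliary
second-order input branch (primed state y4', x4') driven by an external
input u4 through excitatory synaptic kinetics. External drive u1 enters the
excitatory interneuron branch scaled by 1/C12. Each population is a
second-order linear synapse (gain G, rate constant w) wrapped around a
firing-rate sigmoid centred on zero, and the model output — the simulated
EEG — is the summed membrane potential of the pyramidal population,

    v1(t) = C12*y2 - C13*y3 - C14*y4.

Default constants are the physiologically grounded Wendling-family values
(G2=3.25 mV, w2=100 /s excitatory; G3=22 mV, w3=50 /s slow inhibitory;
G4=10 mV, w4=500 /s fast inhibitory; C21=135 and fractions thereof), with
sigmoid saturation e0=2.5 /s and steepness r=0.56 /mV. Because the sigmoid
is centred on zero its output is a firing-rate *deviation* and may be
negative; it is not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.special import expit

from . import _kernels
from .timeseries import TimeSeries, check_compatible

__all__ = [
    "NMMParams",
    "STATE_LABELS",
    "VR_CONNECTIVITY_OVERRIDES",
    "sigmoid",
    "nmm_derivatives",
    "simulate_nmm",
    "default_params",
]

#: state vector layout used everywhere (primed = fast-inhibitory self branch)
STATE_LABELS = ("y1", "x1", "y2", "x2", "y3", "x3", "y4", "x4", "y4p", "x4p")

#: VR induction maps to a 20% stronger excitatory->pyramidal coupling
VR_CONNECTIVITY_OVERRIDES = {"C12": 108.0 * 1.2}

DEFAULT_BOUND = 1e6


@dataclass(frozen=True)
class NMMParams:
    """Connectivity constants, synaptic gains/rates and sigmoid parameters.

    C_ij is the synaptic constant from population j to i (dimensionless,
    >= 0), G_i the synaptic gain (mV), w_i the reciprocal time constant
    (1/s), e0 the sigmoid saturation (1/s) and r its steepness (1/mV).
    """

    C12: float = 108.0
    C21: float = 135.0
    C13: float = 33.75
    C31: float = 33.75
    C14: float = 13.5
    C41: float = 40.5
    C43: float = 13.5
    C44: float = 13.5
    G2: float = 3.25
    G3: float = 22.0
    G4: float = 10.0
    w2: float = 100.0
    w3: float = 50.0
    w4: float = 500.0
    e0: float = 2.5
    r: float = 0.56

    def __post_init__(self):
        for name in ("w2", "w3", "w4", "e0", "r"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for f in fields(self):
            if f.name.startswith("C") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def replace(self, **overrides) -> "NMMParams":
        return replace(self, **overrides)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def default_params(condition_label: str = "normal") -> NMMParams:
    """Documented defaults per condition; 'vr' applies the connectivity
    overrides on top of 'normal' and differs in nothing else."""
    if condition_label == "normal":
        return NMMParams()
    if condition_label == "vr":
        return NMMParams().replace(**VR_CONNECTIVITY_OVERRIDES)
    raise ValueError(
        f"unknown condition label {condition_label!r}; use 'normal' or 'vr'"
    )


def sigmoid(v, e0: float = 2.5, r: float = 0.56):
    """Firing-rate sigmoid 2*e0/(1+exp(-r*v)) - e0.

    Odd, strictly increasing, range (-e0, +e0), exactly 0 at v = 0.
    """
    return 2.0 * e0 * expit(r * np.asarray(v, dtype=float)) - e0


def nmm_derivatives(
    state: np.ndarray,
    params: NMMParams,
    u1: float = 0.0,
    u4: float = 0.0,
) -> np.ndarray:
    """Readable reference evaluation of the ten coupled equations.

    `state` follows :data:`STATE_LABELS`. The compiled kernel used by
    :func:`simulate_nmm` is pinned against this function in the tests.
    """
    s = np.asarray(state, dtype=float)
    if s.shape != (10,):
        raise ValueError("state must have exactly 10 components")
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("non-finite NMM state")
    if params.C12 == 0 and u1 != 0:
        raise ZeroDivisionError(
            "C12 = 0 with nonzero u1: the excitatory branch divides u1 by C12"
        )
    y1, x1, y2, x2, y3, x3, y4, x4, y4p, x4p = s
    p = params
    v1 = p.C12 * y2 - p.C13 * y3 - p.C14 * y4
    v2 = p.C21 * y1
    v3 = p.C31 * y1
    v4 = p.C41 * y1 - p.C43 * y3 - p.C44 * y4 + y4p
    z1, z2, z3, z4 = (sigmoid(v, p.e0, p.r) for v in (v1, v2, v3, v4))
    u1_term = u1 / p.C12 if u1 != 0 else 0.0
    return np.array([
        x1,
        p.G2 * p.w2 * z1 - 2 * p.w2 * x1 - p.w2**2 * y1,
        x2,
        p.G2 * p.w2 * (z2 + u1_term) - 2 * p.w2 * x2 - p.w2**2 * y2,
        x3,
        p.G3 * p.w3 * z3 - 2 * p.w3 * x3 - p.w3**2 * y3,
        x4,
        p.G4 * p.w4 * z4 - 2 * p.w4 * x4 - p.w4**2 * y4,
        x4p,
        p.G2 * p.w2 * u4 - 2 * p.w2 * x4p - p.w2**2 * y4p,
    ])


def _run_kernel(params, U1, U4, dt, state0, record_states, bound):
    """Dispatch (T, n) input blocks to the compiled RK4 kernel."""
    p = params
    v1, states, blow = _kernels.nmm_rk4(
        p.C12, p.C21, p.C13, p.C31, p.C14, p.C41, p.C43, p.C44,
        p.G2, p.G3, p.G4, p.w2, p.w3, p.w4, p.e0, p.r,
        np.ascontiguousarray(U1, dtype=float),
        np.ascontiguousarray(U4, dtype=float),
        float(dt), float(bound),
        np.ascontiguousarray(state0, dtype=float), record_states,
    )
    if blow >= 0:
        raise FloatingPointError(
            f"NMM trajectory exceeded {bound:g} at step {blow} "
            f"(t={blow * dt:.4f} s); dt={dt} may be too coarse"
        )
    return v1, states


def simulate_nmm(
    params: NMMParams,
    u1: TimeSeries,
    u4: TimeSeries,
    init: np.ndarray | None = None,
    record_states: bool = False,
    bound: float = DEFAULT_BOUND,
):
    """RK4 trajectory of the model; returns the simulated EEG v1(t).

    u1 and u4 must share sampling rate and length; inputs are zero-order
    held over each step. With ``record_states`` the full (T, 10) state
    history is returned alongside v1.
    """
    check_compatible(u1, u4)
    dt = u1.dt
    wmax = max(params.w2, params.w3, params.w4)
    if dt * wmax > 0.5:
        raise ValueError(
            f"dt={dt} too coarse for w={wmax} 1/s (need dt*w <= 0.5)"
        )
    if params.C12 == 0 and np.any(u1.samples != 0):
        raise ZeroDivisionError(
            "C12 = 0 with nonzero u1: the excitatory branch divides u1 by C12"
        )
    if init is None:
        init = np.zeros(10)
    init = np.asarray(init, dtype=float).reshape(10, 1)
    v1, states = _run_kernel(
        params, u1.samples[:, None], u4.samples[:, None], dt, init,
        record_states, bound,
    )
    out = TimeSeries(v1[:, 0], u1.sampling_rate, t0=u1.t0)
    if record_states:
        return out, states[:, :, 0]
    return out
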