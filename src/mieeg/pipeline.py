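"""The movement-intention generation cascade and synthetic trial ensembles.

Two sensory streams are processed in parallel: positive external visual
information U_ev(t) and negative internal pain irritation U_ip(t). Each
drives a van der Pol assembly oscillator (primary processing); the
entrained outputs are RMS-normalized, scaled by their salience weights and
combined as u1 = u_ev - u_ip, the drive of the pyramidal/excitatory loop of
the neural mass model (advanced processing). Fast inhibitory interneurons
receive an independent white Gaussian input u4 (mean 0, variance 5). The
model output v1(t) is the simulated single-channel (Cz-equivalent) EEG.

Conditions
----------
normal : spontaneous activity only — both streams are uniformly distributed
    random signals.
vr : VR induction — a sinusoidal stimulus (default 10 Hz, amplitude 0.5)
    is superimposed on the visual stream from the intention onset (default
    2 s before movement) until the end of the movement phase, and the
    excitatory->pyramidal coupling C12 is strengthened by 20%.

The trial protocol mirrors the experiment it emulates: 5 sessions of 10
trials; each trial is 5 s still, up to 4 s movement and 4.5 s rest at
1,000 Hz, so a 10-trial session spans 135 s. Trials are aligned so that
t = 0 is the movement onset; a 2-s burn-in precedes every trial and is
discarded before any feature computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .neural_mass import (NMMParams, VR_CONNECTIVITY_OVERRIDES,
                          default_params, _run_kernel)
from .timeseries import TimeSeries, check_compatible

__all__ = [
    "ConditionSpec",
    "ProtocolSpec",
    "TrialEnsemble",
    "normal_condition",
    "vr_condition",
    "build_inputs",
    "gaussian_input",
    "combine_primary",
    "simulate_trial",
    "generate_dataset",
]

#: half-width of the uniformly distributed random model input
UNIFORM_HALFWIDTH = 0.5

#: variance of the white Gaussian input to the fast inhibitory interneurons
U4_VARIANCE = 5.0

#: natural frequency (Hz) of the assembly oscillators (alpha band)
ASSEMBLY_FREQ_HZ = 10.0

#: salience scale mapping unit-RMS primary outputs onto the NMM input range
#: (the excitatory branch divides u1 by C12=108, so ~100 yields unit drive)
DEFAULT_SALIENCE = 100.0

#: burn-in discarded before the still phase of every trial (seconds)
BURN_IN = 2.0


@dataclass(frozen=True)
class ConditionSpec:
    """Generative configuration of one experimental condition.

    `connectivity_overrides` is what distinguishes the conditions (empty
    for normal); `nmm_base` optionally re-bases any model constant for
    both conditions alike and is applied first.
    """

    label: str
    stim_freq: float = ASSEMBLY_FREQ_HZ
    stim_amplitude: float = 0.0
    stim_onset: float = -2.0
    connectivity_overrides: dict = field(default_factory=dict)
    visual_weight: float = DEFAULT_SALIENCE
    pain_weight: float = DEFAULT_SALIENCE
    nmm_base: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in ("normal", "vr"):
            raise ValueError(f"unknown condition label {self.label!r}")
        if self.stim_amplitude < 0:
            raise ValueError("stim_amplitude must be >= 0")
        if self.label == "normal":
            if self.stim_amplitude != 0:
                raise ValueError("normal condition must have zero stimulus")
            if self.connectivity_overrides:
                raise ValueError(
                    "normal condition must have no connectivity overrides"
                )

    def nmm_params(self) -> NMMParams:
        base = default_params("normal").replace(**self.nmm_base)
        return base.replace(**self.connectivity_overrides)


def normal_condition(**overrides) -> ConditionSpec:
    return ConditionSpec(label="normal", **overrides)


def vr_condition(**overrides) -> ConditionSpec:
    kw = dict(
        stim_amplitude=UNIFORM_HALFWIDTH,
        connectivity_overrides=dict(VR_CONNECTIVITY_OVERRIDES),
    )
    kw.update(overrides)
    return ConditionSpec(label="vr", **kw)


@dataclass(frozen=True)
class ProtocolSpec:
    """Trial/session timing of the acquisition protocol."""

    n_sessions: int = 5
    trials_per_session: int = 10
    pre_still: float = 5.0
    movement: float = 4.0
    rest: float = 4.5
    sampling_rate: float = 1000.0
    epoch_window: tuple[float, float] = (-5.0, 2.0)

    def __post_init__(self):
        if self.n_sessions < 1 or self.trials_per_session < 1:
            raise ValueError("session and trial counts must be >= 1")
        if not (self.epoch_window[0] < 0 < self.epoch_window[1]):
            raise ValueError("epoch_window must straddle the movement onset")
        for name in ("pre_still", "movement", "rest", "sampling_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def n_trials(self) -> int:
        return self.n_sessions * self.trials_per_session

    @property
    def trial_duration(self) -> float:
        return self.pre_still + self.movement + self.rest


@dataclass
class TrialEnsemble:
    """One simulated dataset: aligned trials of one condition."""

    trials: list[TimeSeries]
    condition: ConditionSpec
    protocol: ProtocolSpec
    seed: int

    def __post_init__(self):
        if not self.trials:
            raise ValueError("ensemble must hold at least one trial")
        first = self.trials[0]
        for t in self.trials[1:]:
            check_compatible(first, t)
        if len(self.trials) != self.protocol.n_trials:
            raise ValueError(
                f"trial count {len(self.trials)} != sessions x trials "
                f"{self.protocol.n_trials}"
            )

    def __len__(self) -> int:
        return len(self.trials)

    def as_array(self) -> np.ndarray:
        return np.stack([t.samples for t in self.trials])


def _trial_rng(seed: int, trial_index: int) -> np.random.Generator:
    # per-trial streams derived deterministically from the master seed
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(trial_index)])
    )


def gaussian_input(
    n: int,
    seed: int | np.random.Generator = 0,
    variance: float = U4_VARIANCE,
) -> np.ndarray:
    """White Gaussian model input, mean 0, given variance."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return rng.normal(0.0, math.sqrt(variance), int(n))


def _input_grid(proto: ProtocolSpec, burn_in: float):
    fs = proto.sampling_rate
    t0 = -(burn_in + proto.pre_still)
    n = int(round((burn_in + proto.trial_duration) * fs))
    t = t0 + np.arange(n) / fs
    return t, fs, t0


def build_inputs(
    cond: ConditionSpec,
    proto: ProtocolSpec,
    trial_index: int = 0,
    seed: int = 0,
    burn_in: float = BURN_IN,
):
    """Raw per-trial model inputs (U_ev, U_ip, u4), seeded reproducibly.

    U_ev is uniform noise on [-a, a]; under VR the sinusoidal stimulus is
    superimposed from the stimulus onset until the end of the movement
    phase. U_ip is an independent uniform stream, u4 white Gaussian noise
    with variance 5. The same (seed, trial_index) always yields bit-identical
    outputs.
    """
    t, fs, t0 = _input_grid(proto, burn_in)
    rng = _trial_rng(seed, trial_index)
    a = UNIFORM_HALFWIDTH
    u_ev = rng.uniform(-a, a, t.size)
    u_ip = rng.uniform(-a, a, t.size)
    u4 = gaussian_input(t.size, rng)
    if cond.stim_amplitude > 0:
        on = (t >= cond.stim_onset) & (t < proto.movement)
        u_ev[on] += cond.stim_amplitude * np.sin(
            2 * np.pi * cond.stim_freq * (t[on] - cond.stim_onset)
        )
    mk = lambda x: TimeSeries(x, fs, t0)  # noqa: E731
    return mk(u_ev), mk(u_ip), mk(u4)


def combine_primary(u_ev: TimeSeries, u_ip: TimeSeries) -> TimeSeries:
    """Net pyramidal drive u1(t) = u_ev(t) - u_ip(t)."""
    check_compatible(u_ev, u_ip)
    return u_ev.copy_with(u_ev.samples - u_ip.samples)


def _oscillator_block(forcing: np.ndarray, dt: float, p: float,
                      lam: float = 1.0) -> np.ndarray:
    """Entrain one assembly oscillator per column; unit-RMS outputs.

    The coupling gain is p^2 so that order-one inputs act on the scale of
    the restoring force and phase capture completes well within the
    intention window (see docs/methods.md).
    """
    n = forcing.shape[1]
    y0 = np.full(n, 0.1)
    yd0 = np.zeros(n)
    out, blow = _kernels.vdp_rk4(
        float(lam), float(p), float(p * p), y0, yd0,
        np.ascontiguousarray(forcing, dtype=float), float(dt), 1e6,
    )
    if blow >= 0:
        raise FloatingPointError(
            f"primary oscillator blew up at step {blow} (dt={dt})"
        )
    rms = np.sqrt(np.mean(out**2, axis=0))
    rms[rms == 0] = 1.0
    return out / rms


def _simulate_block(cond, proto, trial_indices, seed, burn_in=BURN_IN):
    """Vectorized cascade for a block of trials; returns (T_keep, n), t0."""
    t, fs, _ = _input_grid(proto, burn_in)
    dt = 1.0 / fs
    n = len(trial_indices)
    U_ev = np.empty((t.size, n))
    U_ip = np.empty((t.size, n))
    U4 = np.empty((t.size, n))
    for j, idx in enumerate(trial_indices):
        ev, ip, u4 = build_inputs(cond, proto, idx, seed, burn_in)
        U_ev[:, j] = ev.samples
        U_ip[:, j] = ip.samples
        U4[:, j] = u4.samples
    p = 2 * np.pi * ASSEMBLY_FREQ_HZ
    u_ev = cond.visual_weight * _oscillator_block(U_ev, dt, p)
    u_ip = cond.pain_weight * _oscillator_block(U_ip, dt, p)
    u1 = u_ev - u_ip
    state0 = np.zeros((10, n))
    v1, _ = _run_kernel(cond.nmm_params(), u1, U4, dt, state0, False, 1e6)
    keep = int(round(burn_in * fs))
    return v1[keep:], -proto.pre_still


def simulate_trial(
    cond: ConditionSpec,
    proto: ProtocolSpec,
    trial_index: int = 0,
    seed: int = 0,
    burn_in: float = BURN_IN,
) -> TimeSeries:
    """One simulated EEG trial, aligned so t = 0 is the movement onset."""
    block, t0 = _simulate_block(cond, proto, [trial_index], seed, burn_in)
    return TimeSeries(block[:, 0], proto.sampling_rate, t0)


def generate_dataset(
    cond: ConditionSpec,
    proto: ProtocolSpec,
    seed: int = 0,
    burn_in: float = BURN_IN,
) -> TrialEnsemble:
    """Full n_sessions x trials_per_session ensemble for one condition."""
    idx = list(range(proto.n_trials))
    block, t0 = _simulate_block(cond, proto, idx, seed, burn_in)
    trials = [
        TimeSeries(block[:, j], proto.sampling_rate, t0)
        for j in range(len(idx))
    ]
    return TrialEnsemble(trials, cond, proto, int(seed))
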