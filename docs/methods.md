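# Methods

This note documents the model equations, parameter choices, numerical
conventions and known limitations of `mieeg`. Everything stated here is
either a definition or is computed by the test suite / acceptance script;
no empirical claim beyond those computations is made.

## 1. Primary processing: assembly oscillators

A neuronal assembly engaged in primary sensory processing is the forced
van der Pol oscillator

    Ÿ − (λ − Y²)Ẏ + p²Y = g·u(t)

* `λ` (dimensionless) — bifurcation parameter. λ ≤ 0: the origin is
  attracting and the assembly is silent; λ > 0: limit cycle. The
  steady-state amplitude follows from the rescaling Y = √λ·Z, which maps
  the equation onto the standard oscillator Z̈ − λ(1−Z²)Ż + p²Z = 0 with
  unit-amplitude-parameter limit cycle |Z| ≈ 2; hence |Y| ≈ **2√λ**
  (exactly 2 at the default λ = 1). At p = 2π·10 rad/s the effective
  nonlinearity parameter λ/p is ≪ 1, so the cycle is quasi-sinusoidal and
  the dominant frequency is p/2π to well within one FFT bin of a 5-s
  window. The suite asserts the 2√λ law at 5% over λ ∈ [0.25, 1].
* `p` (rad/s) — angular frequency; default 2π·10 (α band, the rhythm of
  the sensorimotor assemblies modelled here).
* `g` — additive input gain. In the standalone oscillator API the default
  is 1. **In the cascade the oscillators use g = p².** Rationale: the
  restoring term has magnitude p²·|Y| ≈ 4000·2 at 10 Hz, so an order-one
  input coupled with g = 1 would shift the oscillator phase at a rate of
  ~2·10⁻³ rad/s — phase capture would take hundreds of seconds, and no
  stimulus starting 2 s before movement could ever entrain the assembly
  within the intention window. g = p² makes the forcing commensurate with
  the restoring force; capture then completes in well under a second, and
  the entrainment property (phase-locking value > 0.9 over the tail of a
  20-period run, from any initial phase) holds.

Integration is fixed-step classical Runge-Kutta (RK4) at dt = 1 ms
(matching the 1,000 Hz acquisition rate), forcing applied by zero-order
hold (all four stages of step k use input sample k). The step must
resolve ≥ 10 steps per period. A trajectory-magnitude guard (default 10⁶)
raises instead of propagating overflow, naming the step and dt. The
default initial state (0.1, 0) sits slightly off the origin, which is
unstable for λ > 0.

Steady-state measurements discard the first half of a run by default
(`discard_fraction = 0.5`); amplitude is half the peak-to-peak range of
the retained tail. Phase synchrony is the phase-locking value of
analytic-signal (Hilbert) instantaneous phases, 1 = perfect locking.

## 2. Advanced processing: four-population neural mass model

State variables `y_i, x_i` (i = 1 pyramidal, 2 excitatory, 3 slow
inhibitory, 4 fast inhibitory) plus the primed pair `y₄′, x₄′` for the
auxiliary input branch of the fast-inhibitory population — ten equations:

    v₁ = C₁₂y₂ − C₁₃y₃ − C₁₄y₄            ẋ₁ = G₂w₂·z(v₁) − 2w₂x₁ − w₂²y₁
    v₂ = C₂₁y₁                             ẋ₂ = G₂w₂·(z(v₂) + u₁/C₁₂) − 2w₂x₂ − w₂²y₂
    v₃ = C₃₁y₁                             ẋ₃ = G₃w₃·z(v₃) − 2w₃x₃ − w₃²y₃
    v₄ = C₄₁y₁ − C₄₃y₃ − C₄₄y₄ + y₄′       ẋ₄ = G₄w₄·z(v₄) − 2w₄x₄ − w₄²y₄
                                           ẋ₄′ = G₂w₂·u₄ − 2w₂x₄′ − w₂²y₄′

with `z(v) = 2e₀/(1+e^(−rv)) − e₀`. Two printed idiosyncrasies of this
model family are implemented verbatim, not "corrected": the external
drive enters the excitatory branch **divided by C₁₂**, and the primed
branch uses the **excitatory** kinetics (G₂, w₂) although it feeds the
fast-inhibitory population. The sigmoid is centred on zero, so firing-rate
deviations may be negative; they are not clipped.

Defaults (the physiologically grounded constants of the
Wendling-model family, all overridable through the config):

| parameter | value | unit | meaning |
|---|---|---|---|
| G₂, w₂ | 3.25, 100 | mV, s⁻¹ | excitatory synaptic gain / rate |
| G₃, w₃ | 22, 50 | mV, s⁻¹ | slow inhibitory |
| G₄, w₄ | 10, 500 | mV, s⁻¹ | fast inhibitory |
| C₂₁ | 135 | — | pyramidal→excitatory |
| C₁₂ | 108 | — | excitatory→pyramidal |
| C₃₁ = C₁₃ | 33.75 | — | pyramidal↔slow inhibitory |
| C₄₁ | 40.5 | — | pyramidal→fast inhibitory |
| C₄₃, C₁₄ | 13.5 | — | slow→fast inhibitory, fast→pyramidal |
| C₄₄ | 13.5 | — | fast-inhibitory self-inhibition |
| e₀, r | 2.5, 0.56 | s⁻¹, mV⁻¹ | sigmoid saturation / steepness |

Output units: `v₁` is reported in model units (mV-scale by construction
of the G's); a display gain to μV is a presentation choice left to the
user.

Numerics: RK4 at dt = 1 ms, zero initial state, zero-order-hold inputs.
The rate precondition is `dt·max(w) ≤ 0.5` **with equality allowed**,
because the defaults give exactly 0.5 (w₄ = 500 s⁻¹ at 1 kHz); RK4's
stability region extends far beyond this product. The all-zero state with
zero input is an exact fixed point — z(0) = 0 in floating point — and the
suite verifies bit-exact zero over 10⁵ steps. Integrator fidelity is
checked against the closed-form synaptic impulse response
`G·w·t·e^(−wt)` per isolated branch (< 1% RMS); the Dirac impulse is
realized exactly as the state injection x(0) = G·w rather than as a
1-sample rectangular pulse, whose width (1 ms) would smear the w = 500
branch (time constant 2 ms) by far more than the tolerance being tested.

## 3. The cascade and the synthetic datasets

Per trial: (1) draw `U_ev`, `U_ip` uniform on [−0.5, 0.5] and `u₄`
Gaussian (0, variance 5), all at 1,000 Hz; (2) under VR, superimpose
`0.5·sin(2π·10·(t − t_on))` on `U_ev` from `t_on = −2 s` (the intention
window) until the end of the movement phase; (3) drive one assembly
oscillator per stream (λ = 1, p = 2π·10, g = p²); (4) normalize each
oscillator output to unit RMS and scale by its salience weight;
(5) combine `u₁ = u_ev − u_ip`; (6) integrate the neural mass model with
the condition's connectivity; (7) drop the 2-s burn-in and align t = 0 to
movement onset.

Design choices where the architecture left the value open:

* **Salience weights** default 100 for both streams. The excitatory
  branch divides `u₁` by C₁₂ = 108, so unit-RMS primary outputs weighted
  by ~100 reach the sigmoid stage at ~unit RMS — the drive scale at which
  this model family operates. With weight 1 the cascade input would be
  ~10⁻² of the sigmoid's dynamic range and the primary stage would be
  invisible in `v₁`.
* The weights multiply the **normalized oscillator outputs**, not the raw
  inputs: scaling a forcing input is either erased by the RMS
  normalization or, at the magnitudes needed, qualitatively changes the
  nonlinear oscillator; one well-defined application point keeps the
  weights interpretable as salience.
* **VR connectivity override**: C₁₂ +20% — attention enhancement mapped
  to a stronger excitatory→pyramidal coupling; fully configurable.
* **Trial timeline**: 5 s still + 4 s movement + 4.5 s rest, so one
  10-trial session spans 135 s. The rest duration is a configuration
  default, not a protocol constant.
* **Seeding**: each trial's generator derives from
  `SeedSequence([master_seed, trial_index])`; identical (seed, index) is
  bit-identical, and both conditions share the master seed so condition
  comparisons are noise-paired.

### What the generator does and does not emulate

It emulates: the acquisition protocol (sessions × trials, timing,
sampling rate), the stated input statistics (uniform drive; Gaussian
variance-5 fast-inhibitory input), an event-locked VR stimulus, and
condition-specific connectivity. It does **not** emulate: artifacts (no
EMG/ocular/line noise — artifact removal is deliberately out of scope),
multichannel scalp topography (single Cz-equivalent channel), or the
cortical mechanism of genuine ERD. In the model the VR effect arises from
*entrainment*: after stimulus onset the visual-channel oscillator becomes
phase-coherent, the circulating coherent component compresses the
sigmoid loop gain, and broadband power collapses around the stimulus line
(spectral sharpening). Consequently the ERD *trough* (most negative
baseline-relative dB in band) deepens robustly under VR in both α and β,
while the α band *average* can rise because the coherent 10-Hz line lies
inside it — unlike real ERD, where no exogenous line exists. Likewise the
simulated "MRCP" is the phase-locked low-frequency tail of the evoked
response, not a readiness potential. Passing the directional tests
therefore shows that the implemented cascade reproduces the *direction*
of the condition contrast (deeper ERD trough, more negative low-frequency
minimum, higher detectability under VR); it does not validate the model
against human EEG.

The verification suite runs the contrast at 30-trial ensembles × 10
master seeds — the package's chosen problem size for a stable
directional readout (the full protocol's 50 trials per dataset are
exercised separately).

## 4. Feature pipeline

* **Epochs**: [−5, +2] s around movement onset, half-open sample ranges,
  t = 0 mapped to the onset sample by floor; resting baseline [−5, −2] s
  (for short diagnostic windows the baseline shrinks to the first half of
  the pre-onset segment).
* **Filtering**: zero-phase (forward-backward) Butterworth, order 4,
  applied as second-order sections. Zero phase avoids latency bias in
  onset/peak-time estimates. The 0.1 Hz corner of the MRCP band has a
  seconds-long edge transient; epochs are baseline-mean corrected after
  filtering.
* **ERD percentage**: E = mean of squared samples per sub-epoch; E_b =
  mean over the m baseline epochs; ERD = (E − E_b)/E_b × 100.
* **ERSP**: Hanning-window short-time Fourier transform, window 1 s,
  hop 50 ms by default. Frames are labelled by their **centre** time.
  Power is averaged **across trials before** the logarithm; the map is
  `10·log₁₀(P/P_baseline)` with a per-frequency baseline mean. (Averaging
  log power per trial instead would carry the χ²₂ bias of ≈ −2.5 dB per
  single-window bin and make the white-noise self-baseline nonzero.) The
  hop is a config key: the acquisition description "1-s epochs with a
  200-ms overlap" is readable as hop = 800 ms or hop = 200 ms; neither is
  asserted, and the finer 50 ms default gives onset statistics their
  nominal resolution.
* **ERD onset**: earliest in-band (8–30 Hz) frame at or below −20 dB
  within [−2, 2] s; "not detected" is an explicit `None`/NaN sentinel,
  never 0. Note the physics of the window: with a Hanning window of
  length T, a total suppression starting at t₀ is only detected at the
  −20 dB level once ≲ 1% of the window's weighted energy predates t₀,
  i.e. within ≈ 0.2·T of t₀ — with the default 1-s window the onset
  cannot be localized better than ~200 ms regardless of hop. The
  onset-recovery tests therefore use a 0.1-s analysis window, where
  recovery within one 50-ms hop is attainable and verified.
* **ERD peak**: most negative in-band, in-window value. **Frequency power
  curve**: time-mean of the map over post-baseline frames;
  **characteristic frequency**: in-band argmin (ties → lowest frequency),
  guaranteed inside the requested band (α 8–13, β 14–25 Hz).
* **MRCP**: trials filtered 0.1–10 Hz, baseline-mean subtracted,
  averaged; peak = minimum of the average in [−3, +1] s, first sample on
  ties.
* **Baseline power**: trial-mean of the mean squared 8–25 Hz signal over
  the baseline window.

## 5. Comparison statistics

Paired two-sided t tests at the 95% level (a zero-variance difference is
flagged degenerate; identical samples report t = 0, p = 1). Normality via
Shapiro-Wilk with bias-corrected sample skewness and **excess** kurtosis
(normal = 0). Q-Q pairs are matched empirical quantiles on the plotting
positions (i+0.5)/n of the smaller sample. Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP); each ratio is computed only when requested so
that a one-class count table can still yield its defined metric.

`detectability_score` replaces a trained deep classifier — whose value
lies in weights learned on real recordings — with a stratified k-fold
cross-validated linear discriminant over per-segment features (log α and
β band power, mean low-frequency amplitude), movement as the positive
class, deterministic given the seed. Any object with fit/predict can be
substituted, so a stronger classifier can be plugged in unchanged.

## 6. Orchestration and IO

Delimited text is the canonical format (full float precision, so
write→read round trips are bit-identical; CSV parsing uses round-trip
float conversion). EDF is read-only convenience via `mne`, channel
selected by label. The full run simulates both conditions with the same
master seed, extracts one feature row per session (pairing the condition
comparison across sessions), writes the feature tables, the comparison
report, the resolved configuration and a seed manifest. Unknown
configuration keys are rejected by name. Integration kernels are
numba-compiled; results are independent of compilation (the pure-Python
reference derivative implementation is pinned against the kernel in the
tests).

## 7. Limitations

* Single channel; no volume conduction, no electrode montage.
* The VR contrast direction is built into the condition defaults
  (stimulus + stronger C₁₂); the package demonstrates mechanism and
  pipeline correctness, not a fitted model of any subject.
* The α-band average rises under VR because the stimulus line is inside
  the band (see §3); trough-depth statistics are the meaningful ERD
  readout in this generator.
* No artifact model, hence no test of artifact-removal robustness.
* Parameter units are model units end to end; absolute μV calibration of
  `v₁` is not attempted.
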