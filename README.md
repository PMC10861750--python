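# mieeg — movement-intention EEG: generative model and feature analysis

`mieeg` is a research tool for studying how lower-limb **movement
intention** expresses itself in single-channel (Cz) EEG, and whether
**virtual-reality (VR) induction** makes that intention easier to detect.
It implements a two-stage generative model of intention-related EEG,
simulates complete experimental datasets under a *normal* and a *VR*
condition, extracts the standard pre-movement EEG features — event-related
desynchronization (ERD/ERSP) and the movement-related cortical potential
(MRCP) — and quantifies the difference between conditions with paired
statistics and a cross-validated detectability score. It is aimed at
BCI/neurorehabilitation researchers who want a fully reproducible,
desk-scale testbed for intention-detection pipelines.

## The model

**Primary processing.** A small neuronal assembly receiving one sensory
stream (external visual information `U_ev`, or internal pain irritation
`U_ip`) is a van der Pol oscillator

```
Ÿ − (λ − Y²)Ẏ + p²Y = g·u(t)
```

with bifurcation parameter λ, angular frequency `p` (default 2π·10 rad/s,
the α band) and additive input `u(t)`. For λ ≤ 0 the assembly is silent;
for λ > 0 it holds a limit cycle of amplitude `2√λ` (amplitude 2 at λ = 1).
A same-frequency input captures the oscillator's phase — entrainment is
how information enters the assembly.

**Advanced processing.** The entrained outputs are combined,
`u₁ = u_ev − u_ip`, and drive a four-population neural mass model —
pyramidal cells (1), excitatory interneurons (2), slow (3) and fast (4)
inhibitory interneurons, with fast-inhibitory self-inhibition and an
auxiliary input branch receiving white Gaussian noise `u₄` (mean 0,
variance 5). Each population is a second-order synapse
`ẍ = G·w·z − 2w·ẋ − w²·y` wrapped around the zero-centred firing-rate
sigmoid `z(v) = 2e₀/(1+e^(−rv)) − e₀` (e₀ = 2.5 s⁻¹, r = 0.56 mV⁻¹).
The simulated EEG is the pyramidal membrane potential
`v₁ = C₁₂y₂ − C₁₃y₃ − C₁₄y₄`.

**Conditions.** *Normal*: both streams are uniformly distributed random
signals. *VR*: a sinusoidal stimulus (10 Hz, amplitude 0.5) is
superimposed on the visual stream from 2 s before movement onset, and the
excitatory→pyramidal coupling C₁₂ is strengthened by 20%. Trials follow
the acquisition protocol (5 sessions × 10 trials; 5 s still, 4 s
movement, 4.5 s rest; 1,000 Hz sampling).

See `docs/methods.md` for parameter tables, numerical choices and the
generator's known limitations.

## Worked example

```python
from mieeg.pipeline import (ProtocolSpec, generate_dataset,
                            normal_condition, vr_condition)
from mieeg.features import detection_features, epoch_signal, feature_table
from mieeg.stats import detectability_score

proto = ProtocolSpec(n_sessions=3, trials_per_session=10)
epochs = {}
for cond in (normal_condition(), vr_condition()):
    ens = generate_dataset(cond, proto, seed=0)
    epochs[cond.label] = epoch_signal(ens)   # [-5, +2] s around onset
print(feature_table(epochs).round(3).to_string())

for label, ep in epochs.items():
    score = detectability_score(detection_features(ep, ep.baseline),
                                detection_features(ep, (-1.0, 2.0)), seed=0)
    print(label, {k: round(v, 3) for k, v in score.items()})
```

prints

```
         erd_onset_time  erd_peak  char_freq_alpha  char_freq_beta  alpha_peak_power  beta_peak_power  mrcp_peak  mrcp_peak_time  baseline_power
dataset
normal              NaN    -6.348             13.0            14.0            -3.289           -3.055     -1.745           0.004          17.231
vr                  NaN   -11.694              8.0            21.0            -4.585           -8.037     -3.334          -1.572           7.961

normal {'sensitivity': 0.767, 'specificity': 0.833, 'accuracy': 0.8}
vr {'sensitivity': 0.667, 'specificity': 1.0, 'accuracy': 0.833}
```

Reading the numbers: under VR the ERD peak is deeper (−11.7 vs −6.3 dB),
the characteristic-frequency powers in the α and β bands are more strongly
attenuated, and the MRCP minimum is more negative (−3.3 vs −1.7, and
pre-movement at −1.57 s instead of post-onset) — VR induction sharpens the
movement-locked features, and the rest-vs-movement detectability is
higher. `erd_onset_time` is NaN because the simulated suppression never
crosses the −20 dB onset threshold used for real recordings. Feature
values are in model units; ERSP values are dB relative to the resting
baseline (−5 to −2 s).

## Command line

```bash
mieeg simulate --condition vr --sessions 5 --trials 10 --seed 1 --out vr_run/
mieeg features --in vr_run/ --out vr_features.csv
mieeg compare --a normal_features.csv --b vr_features.csv --out report.json
mieeg run --seed 1 --out full_run/          # everything end to end
```

All outputs are delimited text/JSON; every run directory contains the
resolved configuration and seed manifest, and any output is a pure
function of (config, seed).

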