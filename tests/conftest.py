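"""Shared fixtures: deterministic hypothesis profile, a minimal EDF writer
and the (expensive, session-scoped) normal-vs-VR simulation experiment."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def write_minimal_edf(path, signals, labels, fs):
    """Hand-rolled single-record EDF file for reader tests (synthetic).

    Physical range is fixed at +/-1000 uV against the full 16-bit digital
    range, so round-tripped values agree to ~0.03 uV.
    """
    ns = len(signals)
    spr = len(signals[0])
    dur = spr / fs
    hdr = "".join([
        "0".ljust(8), "X".ljust(80), "X".ljust(80),
        "01.01.24", "00.00.00", str(256 * (1 + ns)).ljust(8), "".ljust(44),
        "1".ljust(8), str(dur).ljust(8), str(ns).ljust(4),
    ])
    hdr += "".join(label.ljust(16) for label in labels)
    hdr += "".join("unknown".ljust(80) for _ in range(ns))
    hdr += "".join("uV".ljust(8) for _ in range(ns))
    hdr += "".join("-1000".ljust(8) for _ in range(ns))
    hdr += "".join("1000".ljust(8) for _ in range(ns))
    hdr += "".join("-32768".ljust(8) for _ in range(ns))
    hdr += "".join("32767".ljust(8) for _ in range(ns))
    hdr += "".join("".ljust(80) for _ in range(ns))
    hdr += "".join(str(spr).ljust(8) for _ in range(ns))
    hdr += "".join("".ljust(32) for _ in range(ns))
    with open(path, "wb") as fh:
        fh.write(hdr.encode("ascii"))
        for s in signals:
            fh.write(np.round(np.asarray(s) / 1000 * 32767)
                     .astype("<i2").tobytes())
    return path


@pytest.fixture()
def edf_writer():
    return write_minimal_edf


#: seeds of the multi-seed condition experiment (fixed, not tuned)
DIRECTIONAL_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def directional_experiment():
    """Per-seed normal-vs-VR metrics over 30-trial ensembles.

    Returns {label: {seed: {...}}} with ERD peak (8-30 Hz), alpha-band
    trough depth, MRCP peak and rest-vs-move detectability for each of 10
    master seeds under the default condition specs.
    """
    from mieeg.features import (ALPHA_BAND, detection_features, epoch_signal,
                                erd_peak, mrcp_extract, stft_ersp)
    from mieeg.pipeline import (ProtocolSpec, generate_dataset,
                                normal_condition, vr_condition)
    from mieeg.stats import detectability_score

    proto = ProtocolSpec(n_sessions=3, trials_per_session=10)
    out = {"normal": {}, "vr": {}}
    for seed in DIRECTIONAL_SEEDS:
        for cond in (normal_condition(), vr_condition()):
            ens = generate_dataset(cond, proto, seed=seed)
            ep = epoch_signal(ens)
            tf = stft_ersp(ep)
            _, mrcp_peak_val, _ = mrcp_extract(ep)
            rest = detection_features(ep, ep.baseline)
            move = detection_features(ep, (-1.0, 2.0))
            out[cond.label][seed] = {
                "erd_peak": erd_peak(tf),
                "alpha_trough": erd_peak(tf, search=(0.0, 2.0),
                                         band=ALPHA_BAND),
                "mrcp_peak": mrcp_peak_val,
                "detectability": detectability_score(rest, move, seed=seed),
            }
    return out
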