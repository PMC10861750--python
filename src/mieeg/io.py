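"""Readers, writers, configuration and the end-to-end run orchestration.

Delimited text is the canonical interchange format (auditable and
diff-able): a TimeSeries is a CSV with a ``time,value`` header, times in
seconds with '.' decimals, values printed with full float precision so a
write/read round trip is bit-identical. EDF recordings can be read for
interoperability with real acquisitions (channel selected by label, e.g.
"Cz"); EDF support is read-only and needs the optional `mne` dependency.

Every run writes the fully resolved configuration and a seed manifest next
to its outputs, making any artifact a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import detection_features, feature_table
from .pipeline import (ConditionSpec, ProtocolSpec, TrialEnsemble,
                       generate_dataset)
from .stats import compare_feature_tables, detectability_score
from .timeseries import TimeSeries

__all__ = [
    "ConfigError", "StageError", "DEFAULT_CONFIG", "load_config",
    "read_timeseries", "write_timeseries", "write_ensemble",
    "read_ensemble", "run_full",
]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


_CONDITION_DEFAULTS = {
    "stim_freq": 10.0,
    "stim_amplitude": 0.0,
    "stim_onset": -2.0,
    "connectivity_overrides": {},
    "visual_weight": 100.0,
    "pain_weight": 100.0,
}

DEFAULT_CONFIG = {
    "sim": {"seed": 0, "burn_in": 2.0},
    "oscillator": {"lambda": 1.0, "p_hz": 10.0, "forcing_gain": 1.0},
    "nmm": {},
    "condition": {
        "normal": dict(_CONDITION_DEFAULTS),
        "vr": {**_CONDITION_DEFAULTS,
               "stim_amplitude": 0.5,
               "connectivity_overrides": {"C12": 129.6}},
    },
    "protocol": {
        "sessions": 5, "trials": 10, "pre_still": 5.0, "movement": 4.0,
        "rest": 4.5, "sampling_rate": 1000.0, "epoch_window": [-5.0, 2.0],
    },
    "features": {"stft_window": 1.0, "stft_hop": 0.05, "fmax": 45.0},
    "compare": {"folds": 10},
}

#: sections whose keys are validated against NMMParams fields instead of
#: the defaults tree
_NMM_KEYED = {"nmm", "connectivity_overrides"}


def _nmm_field_names():
    from .neural_mass import NMMParams
    return {f.name for f in dataclasses.fields(NMMParams)}


def _merge(defaults, override, path=""):
    if not isinstance(override, dict):
        raise ConfigError(f"config section '{path or '<root>'}' must be a map")
    merged = {}
    for key, dval in defaults.items():
        if key in override:
            oval = override[key]
            if isinstance(dval, dict):
                if key in _NMM_KEYED:
                    bad = set(oval) - _nmm_field_names()
                    if bad:
                        raise ConfigError(
                            f"unknown model parameter(s) {sorted(bad)} "
                            f"under '{path}{key}'"
                        )
                    merged[key] = dict(oval)
                else:
                    merged[key] = _merge(dval, oval, f"{path}{key}.")
            else:
                merged[key] = oval
        else:
            merged[key] = {k: v for k, v in dval.items()} \
                if isinstance(dval, dict) else dval
            if isinstance(dval, dict) and key not in _NMM_KEYED:
                merged[key] = _merge(dval, {}, f"{path}{key}.")
    unknown = set(override) - set(defaults)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} under "
            f"'{path or '<root>'}'"
        )
    return merged


def load_config(path: str | Path | None = None, overrides: dict | None = None):
    """Resolve a run configuration against the defaults.

    Unknown keys are rejected with the offending key named. `overrides`
    (same nested structure) are applied after the file.
    """
    cfg = _merge(DEFAULT_CONFIG, {})
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def condition_from_config(cfg: dict, label: str) -> ConditionSpec:
    c = dict(cfg["condition"][label])
    c["connectivity_overrides"] = dict(c.get("connectivity_overrides", {}))
    return ConditionSpec(label=label, nmm_base=dict(cfg.get("nmm", {})), **c)


def protocol_from_config(cfg: dict) -> ProtocolSpec:
    p = cfg["protocol"]
    return ProtocolSpec(
        n_sessions=int(p["sessions"]),
        trials_per_session=int(p["trials"]),
        pre_still=float(p["pre_still"]),
        movement=float(p["movement"]),
        rest=float(p["rest"]),
        sampling_rate=float(p["sampling_rate"]),
        epoch_window=tuple(p["epoch_window"]),
    )


def write_timeseries(ts: TimeSeries, path: str | Path,
                     name: str = "value") -> None:
    """CSV with header ``time,<name>``; full float precision."""
    data = np.column_stack([ts.times, ts.samples])
    np.savetxt(path, data, delimiter=",", header=f"time,{name}",
               comments="", fmt="%.17g")


def read_timeseries(path: str | Path, format: str | None = None,
                    channel: str | None = None) -> TimeSeries:
    """Read a series from delimited text or EDF.

    CSV needs a ``time`` column plus one value column (or `channel` naming
    one of several). EDF requires `channel`; an unknown label raises with
    the available labels listed.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "csv":
        # round_trip parsing keeps write->read bit-identical
        df = pd.read_csv(path, float_precision="round_trip")
        if "time" not in df.columns:
            raise ValueError(f"{path}: missing 'time' column")
        if len(df) < 2:
            raise ValueError(f"{path}: empty or single-sample series")
        value_cols = [c for c in df.columns if c != "time"]
        if channel is not None:
            if channel not in value_cols:
                raise ValueError(
                    f"{path}: channel {channel!r} not found; available: "
                    f"{value_cols}"
                )
            col = channel
        elif len(value_cols) == 1:
            col = value_cols[0]
        else:
            raise ValueError(
                f"{path}: several channels {value_cols}; pass channel="
            )
        t = df["time"].to_numpy(dtype=float)
        fs = 1.0 / float(np.median(np.diff(t)))
        return TimeSeries(df[col].to_numpy(dtype=float), fs, t0=float(t[0]))
    if format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError(
                "EDF reading needs the optional dependency mne "
                "(pip install mieeg[edf])"
            ) from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        if channel is None:
            raise ValueError("EDF reading requires a channel label")
        if channel not in raw.ch_names:
            raise ValueError(
                f"{path}: channel {channel!r} not found; available: "
                f"{raw.ch_names}"
            )
        data = raw.get_data(picks=[channel])[0]
        return TimeSeries(data, float(raw.info["sfreq"]), t0=0.0)
    raise ValueError(f"unknown format {format!r} (use 'csv' or 'edf')")


def write_tfmap(tfmap, prefix: str | Path) -> dict:
    """Time-frequency map as a dB matrix file plus two axis files.

    Writes `<prefix>_values.csv` (freqs x times), `<prefix>_times.csv`
    and `<prefix>_freqs.csv`.
    """
    prefix = Path(prefix)
    paths = {
        "values": prefix.with_name(prefix.name + "_values.csv"),
        "times": prefix.with_name(prefix.name + "_times.csv"),
        "freqs": prefix.with_name(prefix.name + "_freqs.csv"),
    }
    np.savetxt(paths["values"], tfmap.values, delimiter=",", fmt="%.17g")
    np.savetxt(paths["times"], tfmap.times, delimiter=",", fmt="%.17g")
    np.savetxt(paths["freqs"], tfmap.freqs, delimiter=",", fmt="%.17g")
    return {k: str(v) for k, v in paths.items()}


def write_ensemble(ens: TrialEnsemble, out_dir: str | Path) -> Path:
    """One CSV per trial plus a JSON manifest (condition, protocol, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for i, ts in enumerate(ens.trials):
        fname = f"trial_{i:03d}.csv"
        write_timeseries(ts, out / fname, name="v1")
        files.append(fname)
    manifest = {
        "mieeg_version": __version__,
        "seed": ens.seed,
        "condition": dataclasses.asdict(ens.condition),
        "protocol": dataclasses.asdict(ens.protocol),
        "trials": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def read_ensemble(in_dir: str | Path) -> TrialEnsemble:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    cond_kw = dict(manifest["condition"])
    label = cond_kw.pop("label")
    cond = ConditionSpec(label=label, **cond_kw)
    proto_kw = dict(manifest["protocol"])
    proto_kw["epoch_window"] = tuple(proto_kw["epoch_window"])
    proto = ProtocolSpec(**proto_kw)
    trials = [read_timeseries(in_dir / f) for f in manifest["trials"]]
    return TrialEnsemble(trials, cond, proto, int(manifest["seed"]))


def _session_epochs(ens: TrialEnsemble):
    """Split an ensemble into per-session epoch ensembles."""
    from .features import epoch_signal
    proto = ens.protocol
    k = proto.trials_per_session
    out = {}
    for s in range(proto.n_sessions):
        sub = TrialEnsemble(
            ens.trials[s * k:(s + 1) * k], ens.condition,
            ProtocolSpec(**{**dataclasses.asdict(proto), "n_sessions": 1}),
            ens.seed,
        )
        out[f"session_{s}"] = epoch_signal(sub, window=proto.epoch_window)
    return out


def session_feature_table(ens: TrialEnsemble, cfg: dict) -> pd.DataFrame:
    f = cfg["features"]
    return feature_table(
        _session_epochs(ens),
        stft_window=float(f["stft_window"]), stft_hop=float(f["stft_hop"]),
    )


def run_full(config: dict | str | Path | None = None,
             out_dir: str | Path = "mieeg_run",
             seed: int | None = None) -> dict:
    """Simulate both conditions, extract features, compare; write reports.

    Feature rows are computed per session so that the condition comparison
    is paired across the five sessions. Both conditions share the master
    seed, which pairs their trial-level noise realizations. Returns the
    paths of everything written. Idempotent for fixed (config, seed).
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if seed is not None:
        config = {**config, "sim": {**config["sim"], "seed": int(seed)}}
    master = int(config["sim"]["seed"])
    burn_in = float(config["sim"]["burn_in"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proto = protocol_from_config(config)

    tables, ensembles = {}, {}
    for label in ("normal", "vr"):
        try:
            cond = condition_from_config(config, label)
            ensembles[label] = generate_dataset(cond, proto, seed=master,
                                                burn_in=burn_in)
        except Exception as exc:
            raise StageError(f"stage simulate[{label}]: {exc}") from exc
        try:
            tables[label] = session_feature_table(ensembles[label], config)
        except Exception as exc:
            raise StageError(f"stage features[{label}]: {exc}") from exc

    try:
        report = compare_feature_tables(tables["normal"], tables["vr"],
                                        "normal", "vr")
        from .features import epoch_signal
        det = {}
        for label, ens in ensembles.items():
            ep = epoch_signal(ens, window=proto.epoch_window)
            rest = detection_features(ep, ep.baseline)
            move = detection_features(ep, (-1.0, proto.epoch_window[1]))
            det[label] = detectability_score(
                rest, move, folds=int(config["compare"]["folds"]),
                seed=master,
            )
        report["detectability"] = det
    except Exception as exc:
        raise StageError(f"stage compare: {exc}") from exc

    paths = {}
    for label, df in tables.items():
        p = out / f"features_{label}.csv"
        df.to_csv(p)
        paths[f"features_{label}"] = str(p)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    paths["report"] = str(out / "report.json")
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump(config, sort_keys=True))
    paths["resolved_config"] = str(out / "resolved_config.yaml")
    manifest = {
        "mieeg_version": __version__,
        "seed": master,
        "conditions": ["normal", "vr"],
        "n_trials_per_condition": proto.n_trials,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = str(out / "manifest.json")
    return paths
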