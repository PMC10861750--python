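"""Uniformly sampled time series, the carrier between all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : array-like, shape (n,)
        Signal values, in model units unless stated otherwise.
    sampling_rate : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds. Throughout the package t = 0
        is the movement onset, so trial-aligned signals carry negative t0.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("TimeSeries samples must be one-dimensional")
        if self.samples.size < 1:
            raise ValueError("TimeSeries must hold at least one sample")
        self.sampling_rate = float(self.sampling_rate)
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        self.t0 = float(self.t0)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate

    def copy_with(self, samples: np.ndarray) -> "TimeSeries":
        """New series on the same time grid with different values."""
        return TimeSeries(samples, self.sampling_rate, self.t0)


def check_compatible(a: TimeSeries, b: TimeSeries) -> None:
    """Raise unless two series share length and sampling rate."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not np.isclose(a.sampling_rate, b.sampling_rate):
        raise ValueError(
            f"sampling-rate mismatch: {a.sampling_rate} vs {b.sampling_rate}"
        )
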