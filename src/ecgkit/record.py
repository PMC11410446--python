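"""Core ECG record container.

An :class:`ECGRecord` is a uniformly sampled single-lead voltage trace in
millivolts with an attached sampling rate. Sample indices are 0-based
everywhere in this package and all time intervals are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ECGRecord"]


@dataclass(frozen=True)
class ECGRecord:
    """A sampled single-lead ECG.

    Parameters
    ----------
    samples : ndarray of float
        Voltage samples in mV, ordered in time.
    fs : float
        Sampling rate in Hz; must be positive.
    record_id : str
        Identifier (e.g. a database record name or a simulation tag).
    lead : str
        Lead name; free-form, defaults to ``"I"``.
    """

    samples: np.ndarray
    fs: float
    record_id: str = "record"
    lead: str = "I"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size < 2:
            raise ValueError("an ECG record needs at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must all be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        samples.setflags(write=False)
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (0-based index / fs)."""
        return np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray) -> "ECGRecord":
        """Return a copy of this record carrying new samples."""
        return replace(self, samples=np.asarray(samples, dtype=float))
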