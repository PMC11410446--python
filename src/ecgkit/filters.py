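"""Filter design and application for ECG preprocessing.

The preprocessing chain this package implements combines four linear stages:
a long FIR high-pass that removes baseline wander, a Butterworth band-pass
that emphasises the QRS band, a Butterworth band-stop, and an FIR band-stop
notch for mains (power-line) interference. Filters are described by a
:class:`TransferFunction` — a rational function in either the analog ``s``
domain or the digital ``z`` domain — so the same evaluation and cascade
machinery serves designed digital filters and analog-style reference
functions alike.

Design happens directly in the digital domain via :mod:`scipy.signal`;
analog transfer functions can be discretised with
:func:`bilinear_discretize` before being applied to sampled data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .record import ECGRecord

__all__ = [
    "TransferFunction",
    "design_butterworth",
    "design_fir",
    "cascade",
    "evaluate_response",
    "apply_filter",
    "bilinear_discretize",
    "write_coefficients",
    "read_coefficients",
]


@dataclass(frozen=True)
class TransferFunction:
    """Rational filter description b(x)/a(x), coefficients in descending power.

    ``domain`` is ``"s"`` for analog (evaluated at ``s = j*2*pi*f``) or
    ``"z"`` for digital (evaluated at ``z = exp(j*2*pi*f/fs)``); digital
    transfer functions must carry their sampling rate ``fs``.
    """

    num: np.ndarray
    den: np.ndarray
    domain: str = "z"
    fs: float | None = None

    def __post_init__(self) -> None:
        num = np.atleast_1d(np.asarray(self.num, dtype=float))
        den = np.atleast_1d(np.asarray(self.den, dtype=float))
        if den.size == 0 or not np.any(den):
            raise ValueError("denominator must be nonempty and nonzero")
        # strip leading zeros so degree and stability checks are meaningful
        den = np.trim_zeros(den, "f")
        if den.size == 0:
            raise ValueError("denominator leading coefficient must be nonzero")
        if num.size == 0:
            num = np.zeros(1)
        if self.domain not in ("s", "z"):
            raise ValueError(f"domain must be 's' or 'z', got {self.domain!r}")
        if self.domain == "z":
            if self.fs is None or self.fs <= 0:
                raise ValueError("digital transfer functions require fs > 0")
        num.setflags(write=False)
        den.setflags(write=False)
        object.__setattr__(self, "num", num)
        object.__setattr__(self, "den", den)

    @property
    def order(self) -> int:
        """Maximum polynomial degree of numerator and denominator."""
        return max(self.num.size, self.den.size) - 1

    @property
    def is_fir(self) -> bool:
        return self.den.size == 1

    def is_stable(self) -> bool:
        """Analog: all poles in the open left half plane; digital: inside the
        unit circle. Constant denominators (FIR) are always stable."""
        if self.den.size == 1:
            return True
        poles = np.roots(self.den)
        if self.domain == "s":
            return bool(np.all(poles.real < 0))
        return bool(np.all(np.abs(poles) < 1.0))

    def response(self, frequencies: Iterable[float]) -> np.ndarray:
        return evaluate_response(self, frequencies)


def unity(domain: str = "z", fs: float | None = None) -> TransferFunction:
    """The identity filter H = 1."""
    return TransferFunction(np.array([1.0]), np.array([1.0]), domain, fs)


def design_butterworth(
    kind: str,
    f_low: float,
    f_high: float,
    order: int,
    fs: float,
) -> TransferFunction:
    """Design a digital Butterworth band-pass or band-stop filter.

    Parameters
    ----------
    kind : {"pass", "stop"}
        Band-pass or band-stop response.
    f_low, f_high : float
        Band edges in Hz, ``0 < f_low < f_high < fs/2``.
    order : int
        Butterworth design order per edge; the resulting digital transfer
        function has polynomial degree ``2 * order``.
    fs : float
        Sampling rate in Hz.
    """
    if kind not in ("pass", "stop"):
        raise ValueError(f"kind must be 'pass' or 'stop', got {kind!r}")
    if order < 1:
        raise ValueError("order must be >= 1")
    if not (0 < f_low < f_high):
        raise ValueError(f"need 0 < f_low < f_high, got ({f_low}, {f_high})")
    if f_high >= fs / 2:
        raise ValueError(
            f"upper cutoff {f_high} Hz must lie below Nyquist {fs / 2} Hz"
        )
    btype = "bandpass" if kind == "pass" else "bandstop"
    b, a = signal.butter(order, [f_low, f_high], btype=btype, fs=fs)
    return TransferFunction(b, a, "z", fs)


def design_fir(
    kind: str,
    cutoff: float | Sequence[float],
    order: int,
    fs: float,
) -> TransferFunction:
    """Design a linear-phase FIR high-pass or band-stop filter (Hamming window).

    ``order`` is the filter order; the coefficient count is ``order + 1``.
    High-pass and band-stop responses need unity gain at Nyquist, which
    requires an even order (odd tap count).
    """
    if kind not in ("highpass", "bandstop"):
        raise ValueError(f"kind must be 'highpass' or 'bandstop', got {kind!r}")
    if order < 2:
        raise ValueError("order must be >= 2")
    if order % 2 != 0:
        raise ValueError(
            f"{kind} FIR filters require an even order (got {order})"
        )
    cut = np.atleast_1d(np.asarray(cutoff, dtype=float))
    if np.any(cut <= 0) or np.any(cut >= fs / 2):
        raise ValueError(f"cutoffs {cut} must lie strictly inside (0, fs/2)")
    if kind == "highpass":
        if cut.size != 1:
            raise ValueError("highpass takes exactly one cutoff")
        taps = signal.firwin(order + 1, cut[0], pass_zero=False, fs=fs)
        # mean-correct so DC is rejected exactly: baseline removal must null
        # the signal mean even when the order cannot realise the cutoff
        taps = taps - np.sum(taps) / taps.size
    else:
        if cut.size != 2 or cut[0] >= cut[1]:
            raise ValueError("bandstop takes two increasing cutoffs")
        taps = signal.firwin(order + 1, cut, pass_zero=True, fs=fs)
    return TransferFunction(taps, np.array([1.0]), "z", fs)


def cascade(a: TransferFunction, b: TransferFunction) -> TransferFunction:
    """Series combination: numerators and denominators multiply, degrees add."""
    if a.domain != b.domain:
        raise ValueError(f"cannot cascade {a.domain}-domain with {b.domain}-domain")
    if a.domain == "z" and a.fs != b.fs:
        raise ValueError(f"sampling rates differ: {a.fs} vs {b.fs}")
    return TransferFunction(
        np.polymul(a.num, b.num), np.polymul(a.den, b.den), a.domain, a.fs
    )


def evaluate_response(
    tf: TransferFunction, frequencies: Iterable[float]
) -> np.ndarray:
    """Complex frequency response of ``tf`` at the given frequencies (Hz).

    Analog transfer functions are evaluated at ``s = j*2*pi*f`` (f >= 0);
    digital ones at ``z = exp(j*2*pi*f/fs)`` for ``f < fs/2``. Frequencies
    at which the denominator vanishes are reported in the raised error.
    """
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if tf.domain == "s":
        if np.any(freqs < 0):
            raise ValueError("analog evaluation requires frequencies >= 0")
        x = 1j * 2 * np.pi * freqs
    else:
        assert tf.fs is not None
        if np.any(freqs >= tf.fs / 2) or np.any(freqs < 0):
            raise ValueError(
                f"digital evaluation requires 0 <= f < fs/2 = {tf.fs / 2} Hz"
            )
        x = np.exp(1j * 2 * np.pi * freqs / tf.fs)
    den_val = np.polyval(tf.den, x)
    # flag only true poles on the contour: Horner's round-off accumulates to
    # ~eps * sum|a_k|, so anything a few times above that is a real value
    noise_floor = 4 * np.finfo(float).eps * float(np.sum(np.abs(tf.den))) + 1e-300
    bad = np.abs(den_val) < noise_floor
    if np.any(bad):
        raise ZeroDivisionError(
            "denominator vanishes at frequencies (Hz): "
            f"{freqs[bad].tolist()}"
        )
    return np.polyval(tf.num, x) / den_val


def apply_filter(
    tf: TransferFunction, record: ECGRecord, zero_phase: bool = False
) -> ECGRecord:
    """Filter a record through a digital transfer function.

    Forward-only filtering (the default) preserves causality but delays the
    output by the filter's group delay; ``zero_phase=True`` applies
    forward-backward filtering, which cancels the phase response and keeps
    peaks aligned with the input at the cost of non-causality.
    """
    if tf.domain != "z":
        raise ValueError("analog transfer function: discretize with "
                         "bilinear_discretize before applying to samples")
    if tf.fs != record.fs:
        raise ValueError(f"filter fs {tf.fs} != record fs {record.fs}")
    if not tf.is_stable():
        raise ValueError("refusing to apply an unstable filter")
    if zero_phase:
        # filtfilt needs padding shorter than the signal
        padlen = min(3 * (max(tf.num.size, tf.den.size) - 1), record.n_samples - 1)
        y = signal.filtfilt(tf.num, tf.den, record.samples, padlen=max(padlen, 0))
    else:
        y = signal.lfilter(tf.num, tf.den, record.samples)
    return record.with_samples(y)


def bilinear_discretize(tf: TransferFunction, fs: float) -> TransferFunction:
    """Map an analog transfer function to the z domain with Tustin's method."""
    if tf.domain != "s":
        raise ValueError("bilinear_discretize expects an analog transfer function")
    bz, az = signal.bilinear(tf.num, tf.den, fs)
    return TransferFunction(bz, az, "z", fs)


def nominal_delay_samples(tf: TransferFunction) -> int:
    """Nominal group delay of a forward-applied filter, in samples.

    Linear-phase FIR filters delay by half their order; for IIR filters this
    returns 0 (no single nominal delay exists).
    """
    if tf.is_fir:
        return (tf.num.size - 1) // 2
    return 0


def write_coefficients(path: str | Path, tf: TransferFunction) -> None:
    """Export coefficients as CSV: one per line, numerator then denominator."""
    lines = ["section,coefficient"]
    lines += [f"num,{float(c)!r}" for c in tf.num]
    lines += [f"den,{float(c)!r}" for c in tf.den]
    meta = f"# domain={tf.domain}" + (f" fs={tf.fs!r}" if tf.fs else "")
    Path(path).write_text(meta + "\n" + "\n".join(lines) + "\n")


def read_coefficients(path: str | Path) -> TransferFunction:
    """Read a coefficient CSV written by :func:`write_coefficients`."""
    text = Path(path).read_text().strip().splitlines()
    domain, fs = "z", None
    num: list[float] = []
    den: list[float] = []
    for line in text:
        line = line.strip()
        if line.startswith("#"):
            for tok in line.lstrip("# ").split():
                key, _, val = tok.partition("=")
                if key == "domain":
                    domain = val
                elif key == "fs":
                    fs = float(val)
            continue
        if not line or line.startswith("section"):
            continue
        section, _, val = line.partition(",")
        (num if section == "num" else den).append(float(val))
    if not den:
        warnings.warn("coefficient file has no denominator section; assuming FIR")
        den = [1.0]
    return TransferFunction(np.array(num), np.array(den), domain, fs)
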