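"""QRS peak detection.

Two detectors are provided. The primary detector computes the Hilbert
envelope of the (band-pass filtered) ECG — the magnitude of the analytic
signal x(t) + i*H[x](t), where H is the Hilbert transform that shifts
positive frequency components by -90 degrees and negative ones by +90 —
and picks envelope maxima against an adaptive running-amplitude threshold.
The envelope dominates |x| pointwise, which makes R peaks stand out even
when the raw R deflection is biphasic after filtering.

The second detector is the classic band-pass / derivative / squaring /
moving-window-integration chain with dual adaptive thresholds and
search-back, kept in its textbook form as an independent comparator.

All indices refer to 0-based samples of the original record; intervals are
in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .filters import apply_filter, design_butterworth
from .record import ECGRecord

__all__ = [
    "QRSAnnotation",
    "hilbert_envelope",
    "detect_r_peaks",
    "hilbert_detect",
    "locate_qs",
    "rr_intervals",
    "pan_tompkins",
]


@dataclass(frozen=True)
class QRSAnnotation:
    """Detected Q/R/S sample indices with QRS and RR intervals (seconds).

    Per beat Q < R < S; QRS intervals lie in (0, 0.25) s; RR intervals are
    one fewer than R peaks and all exceed the 0.2 s refractory bound.
    """

    r_indices: np.ndarray
    q_indices: np.ndarray
    s_indices: np.ndarray
    qrs_intervals: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r_indices, dtype=int)
        q = np.asarray(self.q_indices, dtype=int)
        s = np.asarray(self.s_indices, dtype=int)
        qrs = np.asarray(self.qrs_intervals, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        if not (r.size == q.size == s.size == qrs.size):
            raise ValueError("per-beat arrays must have equal length")
        if r.size and not np.all((q < r) & (r < s)):
            raise ValueError("each beat must satisfy Q < R < S")
        if qrs.size and not np.all((qrs > 0) & (qrs < 0.25)):
            raise ValueError("QRS intervals must lie in (0, 0.25) s")
        if rr.size != max(r.size - 1, 0):
            raise ValueError("RR count must be R count - 1")
        if rr.size and not np.all(rr > 0.2):
            raise ValueError("RR intervals must exceed the 0.2 s refractory bound")
        for name, arr in (("r_indices", r), ("q_indices", q), ("s_indices", s),
                          ("qrs_intervals", qrs), ("rr", rr)):
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    @property
    def n_beats(self) -> int:
        return int(self.r_indices.size)

    @property
    def mean_qrs(self) -> float:
        return float(np.mean(self.qrs_intervals)) if self.n_beats else float("nan")

    @property
    def mean_heart_rate(self) -> float:
        """Mean heart rate in bpm, 60 / mean(RR)."""
        return 60.0 / float(np.mean(self.rr)) if self.rr.size else float("nan")


def hilbert_envelope(record_or_samples) -> np.ndarray:
    """Envelope |x + i*H[x]| of a signal; same length as the input.

    The analytic signal is built in the frequency domain by zeroing
    negative frequencies, which is the O(n log n) equivalent of the
    principal-value convolution definition of the Hilbert transform.
    """
    x = (record_or_samples.samples
         if isinstance(record_or_samples, ECGRecord)
         else np.asarray(record_or_samples, dtype=float))
    if x.size < 8:
        raise ValueError("need at least 8 samples for a meaningful envelope")
    return np.abs(signal.hilbert(x))


def detect_r_peaks(
    envelope: np.ndarray,
    fs: float,
    threshold_fraction: float = 0.5,
    refractory: float = 0.2,
) -> np.ndarray:
    """Pick R peaks from a nonnegative envelope.

    Candidate local maxima at least ``refractory`` seconds apart are
    accepted when they exceed ``threshold_fraction`` times a running
    amplitude estimate; the estimate is updated as an exponentially
    weighted average (weight 0.125 per accepted peak), the standard
    adaptation speed for beat-amplitude tracking.
    """
    env = np.asarray(envelope, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelope must be nonnegative")
    if not np.any(env):
        return np.array([], dtype=int)
    min_dist = max(int(round(refractory * fs)), 1)
    candidates, _ = signal.find_peaks(env, distance=min_dist)
    if candidates.size == 0:
        return np.array([], dtype=int)

    # initialise the amplitude estimate from the first two seconds
    head = env[: max(int(2 * fs), min_dist)]
    running = float(np.max(head)) if head.size else float(np.max(env))
    accepted: list[int] = []
    for c in candidates:
        if accepted and (c - accepted[-1]) < min_dist:
            continue
        if env[c] >= threshold_fraction * running:
            accepted.append(int(c))
            running = 0.875 * running + 0.125 * float(env[c])
    return np.asarray(accepted, dtype=int)


def hilbert_detect(
    record: ECGRecord,
    band: tuple[float, float] = (5.0, 15.0),
    order: int = 2,
    threshold_fraction: float = 0.5,
    refractory: float = 0.2,
    snap_window: float = 0.05,
) -> np.ndarray:
    """Band-pass + Hilbert-envelope R detection on a raw record.

    The record is band-pass filtered (zero phase, so indices stay aligned
    with the input), enveloped, thresholded, and each detection snapped to
    the nearest raw-signal maximum within ``snap_window`` seconds.
    """
    bp = design_butterworth("pass", band[0], band[1], order=order, fs=record.fs)
    filtered = apply_filter(bp, record, zero_phase=True)
    env = hilbert_envelope(filtered)
    peaks = detect_r_peaks(env, record.fs, threshold_fraction, refractory)
    if peaks.size == 0:
        return peaks
    w = max(int(round(snap_window * record.fs)), 1)
    snapped = []
    for p in peaks:
        lo, hi = max(p - w, 0), min(p + w + 1, record.n_samples)
        snapped.append(lo + int(np.argmax(record.samples[lo:hi])))
    snapped = np.asarray(sorted(set(snapped)), dtype=int)
    # snapping can merge neighbours; re-enforce the refractory spacing
    keep = [0]
    min_dist = max(int(round(refractory * record.fs)), 1)
    for i in range(1, snapped.size):
        if snapped[i] - snapped[keep[-1]] >= min_dist:
            keep.append(i)
    return snapped[keep]


def locate_qs(
    record: ECGRecord,
    r_indices: np.ndarray,
    search_window: float = 0.06,
) -> QRSAnnotation:
    """Locate Q and S troughs around each R peak and build the annotation.

    Q is the signal minimum in (R - window, R), S the minimum in
    (R, R + window); the QRS interval is (S - Q)/fs. Beats whose search
    window would cross the record edge are dropped with a warning, as are
    beats whose trough spacing falls outside the physiologic (0, 0.25) s
    range.
    """
    r_indices = np.asarray(r_indices, dtype=int)
    if np.any(np.diff(r_indices) <= 0):
        raise ValueError("R indices must be strictly increasing")
    w = max(int(round(search_window * record.fs)), 1)
    x = record.samples
    r_kept, q_kept, s_kept, qrs = [], [], [], []
    dropped = 0
    for r in r_indices:
        if r - w < 0 or r + w >= record.n_samples:
            dropped += 1
            continue
        q = r - w + int(np.argmin(x[r - w: r]))
        s = r + 1 + int(np.argmin(x[r + 1: r + w + 1]))
        width = (s - q) / record.fs
        if not (0 < width < 0.25):
            dropped += 1
            continue
        r_kept.append(int(r))
        q_kept.append(q)
        s_kept.append(s)
        qrs.append(width)
    if dropped:
        warnings.warn(f"dropped {dropped} beat(s) at record edges or with "
                      "non-physiologic trough spacing")
    r_arr = np.asarray(r_kept, dtype=int)
    return QRSAnnotation(
        r_indices=r_arr,
        q_indices=np.asarray(q_kept, dtype=int),
        s_indices=np.asarray(s_kept, dtype=int),
        qrs_intervals=np.asarray(qrs, dtype=float),
        rr=rr_intervals(r_arr, record.fs),
    )


def rr_intervals(r_indices: np.ndarray, fs: float) -> np.ndarray:
    """Successive R-to-R intervals in seconds; empty for fewer than 2 peaks."""
    r = np.asarray(r_indices, dtype=int)
    if r.size < 2:
        return np.array([], dtype=float)
    if np.any(np.diff(r) <= 0):
        raise ValueError("R indices must be strictly increasing")
    return np.diff(r) / fs


def pan_tompkins(
    record: ECGRecord,
    band: tuple[float, float] = (5.0, 15.0),
    integration_window: float = 0.150,
    refractory: float = 0.2,
) -> np.ndarray:
    """Classic QRS detection chain, kept as an independent comparator.

    Band-pass (5-15 Hz) -> five-point derivative -> squaring -> moving
    window integration (150 ms) -> dual adaptive thresholds with
    search-back. Returned indices refer to the original record: the
    band-pass runs zero-phase and the derivative/integration delays are
    compensated, with each detection snapped to the local raw maximum.
    """
    if record.fs < 100:
        raise ValueError("pan_tompkins requires fs >= 100 Hz")
    if record.duration < 2.0:
        raise ValueError("record must be at least 2 s long")
    fs = record.fs
    bp = design_butterworth("pass", band[0], band[1], order=2, fs=fs)
    filt = apply_filter(bp, record, zero_phase=True).samples

    # five-point derivative, centered (2-sample delay folded out)
    kernel = np.array([1, 2, 0, -2, -1]) * (fs / 8.0)
    deriv = np.convolve(filt, kernel[::-1], mode="same")
    squared = deriv ** 2
    n_int = max(int(round(integration_window * fs)), 1)
    integrated = np.convolve(squared, np.ones(n_int) / n_int, mode="same")

    min_dist = max(int(round(refractory * fs)), 1)
    candidates, _ = signal.find_peaks(integrated, distance=min_dist)
    if candidates.size == 0:
        return np.array([], dtype=int)

    # dual adaptive thresholds on the integrated signal
    spki = float(np.max(integrated[: int(2 * fs)])) * 0.5
    npki = float(np.mean(integrated[: int(2 * fs)])) * 0.5
    accepted: list[int] = []
    rr_history: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    for c in candidates:
        peak = float(integrated[c])
        if peak > threshold1():
            accepted.append(int(c))
            spki = 0.125 * peak + 0.875 * spki
            if len(accepted) >= 2:
                rr_history.append((accepted[-1] - accepted[-2]) / fs)
                rr_history[:] = rr_history[-8:]
        else:
            npki = 0.125 * peak + 0.875 * npki
        # search-back: if the gap since the last beat exceeds 1.66 x the
        # running RR average, re-scan with the lower threshold
        if accepted and rr_history:
            rr_avg = float(np.mean(rr_history))
            if (c - accepted[-1]) / fs > 1.66 * rr_avg:
                gap = candidates[(candidates > accepted[-1]) & (candidates < c)]
                for g in gap:
                    if integrated[g] > 0.5 * threshold1():
                        accepted.append(int(g))
                        spki = 0.25 * float(integrated[g]) + 0.75 * spki
                        accepted.sort()
                        break

    if not accepted:
        return np.array([], dtype=int)
    # snap each integration peak to the raw-signal maximum nearby
    w = max(int(round(0.075 * fs)), 1)
    snapped = []
    for p in accepted:
        lo, hi = max(p - w, 0), min(p + w + 1, record.n_samples)
        snapped.append(lo + int(np.argmax(record.samples[lo:hi])))
    snapped = sorted(set(snapped))
    out = [snapped[0]]
    for s in snapped[1:]:
        if s - out[-1] >= min_dist:
            out.append(s)
    return np.asarray(out, dtype=int)
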