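"""Time-domain and Poincaré heart-rate-variability statistics.

All inputs are RR-interval sequences in seconds; reported dispersions are
in milliseconds.

Two RMSSD conventions are supported. The conventional definition divides
the sum of squared successive differences by the number of differences
(M - 1 for M intervals). A variant divides by the interval count M itself,
which this package also implements because some published analyses define
it that way; reports always name the convention used. The variant is
strictly smaller whenever any successive difference is nonzero.

NN50 counts successive differences exceeding 50 ms — the standard reading;
counting raw intervals above 50 ms would flag essentially every
physiologic beat and is deliberately not what this function does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HRVSummary", "hrv_summary", "poincare", "rmssd"]


@dataclass(frozen=True)
class HRVSummary:
    """Time-domain HRV descriptors plus Poincaré axes.

    sdnn, rmssd, sd1, sd2 in ms; nn50 a count; mean_heart_rate in bpm.
    ``rmssd_convention`` records which denominator produced ``rmssd``.
    """

    sdnn: float
    rmssd: float
    nn50: int
    mean_heart_rate: float
    sd1: float
    sd2: float
    rmssd_convention: str = "interval-count"


def _validate_rr(rr) -> np.ndarray:
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise ValueError("need at least 3 RR intervals")
    if np.any(rr <= 0) or not np.all(np.isfinite(rr)):
        raise ValueError("RR intervals must be positive and finite")
    return rr


def rmssd(rr, convention: str = "interval-count") -> float:
    """Root mean square of successive RR differences, in ms.

    ``convention="standard"`` divides by the number of differences (M - 1);
    ``convention="interval-count"`` divides by the interval count M.
    """
    rr = _validate_rr(rr)
    diffs_ms = np.diff(rr) * 1000.0
    ss = float(np.sum(diffs_ms ** 2))
    if convention == "standard":
        return float(np.sqrt(ss / diffs_ms.size))
    if convention == "interval-count":
        return float(np.sqrt(ss / rr.size))
    raise ValueError(f"unknown RMSSD convention {convention!r}")


def hrv_summary(rr, rmssd_convention: str = "interval-count") -> HRVSummary:
    """Compute SDNN, RMSSD, NN50, mean heart rate and Poincaré SD1/SD2.

    SDNN is the population standard deviation of the RR intervals (ms);
    NN50 counts absolute successive differences above 50 ms; mean heart
    rate is 60 / mean(RR) bpm.
    """
    rr = _validate_rr(rr)
    sdnn = float(np.std(rr)) * 1000.0
    diffs_ms = np.diff(rr) * 1000.0
    nn50 = int(np.sum(np.abs(diffs_ms) > 50.0))
    hr = 60.0 / float(np.mean(rr))
    sd1, sd2, _ = poincare(rr)
    return HRVSummary(
        sdnn=sdnn,
        rmssd=rmssd(rr, rmssd_convention),
        nn50=nn50,
        mean_heart_rate=hr,
        sd1=sd1,
        sd2=sd2,
        rmssd_convention=rmssd_convention,
    )


def poincare(rr) -> tuple[float, float, np.ndarray]:
    """Poincaré descriptors and scatter points (RR_n, RR_{n+1}).

    SD1 is the dispersion perpendicular to the identity line, measured
    about the line itself: the root mean square of
    (RR_{n+1} - RR_n)/sqrt(2). This makes SD1 identically equal to the
    conventional RMSSD divided by sqrt(2). SD2 is the centered standard
    deviation of (RR_n + RR_{n+1})/sqrt(2), the spread along the identity
    line. Both in ms; points in seconds, count = len(RR) - 1.
    """
    rr = _validate_rr(rr)
    x, y = rr[:-1], rr[1:]
    points = np.column_stack([x, y])
    d = (y - x) / np.sqrt(2.0)
    s = (y + x) / np.sqrt(2.0)
    sd1 = float(np.sqrt(np.mean(d ** 2))) * 1000.0
    sd2 = float(np.std(s)) * 1000.0
    return sd1, sd2, points
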