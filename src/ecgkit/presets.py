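"""Reference transfer functions and the standard two-stage cascade.

The smoothing front end this package reduces is a two-stage Butterworth
cascade: a band-pass stage that emphasises the QRS band followed by a
band-stop stage, giving a 16th-degree IIR prototype. This module builds
that prototype at any sampling rate, and also carries a set of analog-style
reference transfer functions (a degree-4 band-pass, a degree-16 band-stop,
a degree-1 reduced-order filter, and two long FIR tap vectors) that the
test suite uses as evaluation fixtures for the response machinery. The
reference functions are fixtures only — designed digital filters, not these
printed coefficient lists, drive the actual pipeline.
"""

from __future__ import annotations

import numpy as np

from .filters import TransferFunction, cascade, design_butterworth

__all__ = [
    "bandpass_4th_analog",
    "bandstop_16th_analog",
    "reduced_order_reference",
    "lowpass_32nd_analog",
    "fir60_taps",
    "sixteen_order_cascade",
]


def bandpass_4th_analog() -> TransferFunction:
    """Degree-4 analog band-pass reference (first cascade stage)."""
    num = [0.2066, 0.0, -0.4131, 0.0, 0.2066]
    den = [1.0, 0.5488, 0.4535, 0.1763, 0.1958]
    return TransferFunction(np.array(num), np.array(den), "s")


def bandstop_16th_analog() -> TransferFunction:
    """Degree-16 analog band-stop reference (second cascade stage)."""
    num = [0.3201, 4.517, 30.45, 130.0, 393.2, 892.9, 1574.0, 2196.0, 2452.0,
           2196.0, 1574.0, 892.9, 393.2, 130.0, 30.45, 4.517, 0.3201]
    den = [1.0, 12.12, 70.25, 258.1, 672.2, 1316.0, 2004.0, 2419.0, 2340.0,
           1819.0, 113.0, 559.4, 214.8, 62.0, 12.7, 1.649, 0.102]
    return TransferFunction(np.array(num), np.array(den), "s")


def reduced_order_reference() -> TransferFunction:
    """The reference reduced-order filter (3s + 14)/41: degree 1, all
    coefficients nonnegative."""
    return TransferFunction(np.array([3.0, 14.0]), np.array([41.0]), "s")


def lowpass_32nd_analog() -> TransferFunction:
    """Analog low-pass reference associated with the classic band-pass
    integer-coefficient detector chain.

    As transcribed, this function has a double pole at s = +1 and is
    therefore unstable; it exists purely as a parsing/evaluation fixture and
    must never be applied to data.
    """
    num = np.zeros(13)
    num[0], num[6], num[12] = 0.03125, -0.0625, 0.03125
    den = np.array([1.0, -2.0, 1.0])
    return TransferFunction(num, den, "s")


# 61 coefficients of a 60th-order symmetric (linear-phase) FIR reference.
# Transcribed descending from degree 60 to the constant term.
_FIR60 = [
    -4.168e-19, 0.0004528, -0.0008864, 0.001208, -0.00127, 0.0009014,
    -5.451e-18, -0.001371, 0.002909, -0.004086, 0.004272, -0.002955,
    3.791e-17, 0.004159, -0.008473, 0.01146, -0.01158, 0.00778,
    -2.215e-17, -0.01052, 0.02122, -0.02865, 0.02921, -0.02005,
    2.962e-17, 0.02986, -0.06616, 0.1037, -0.1364, 0.1587,
    0.8331,
    0.1587, -0.1364, 0.1037, -0.06616, 0.02986, 2.962e-17,
    -0.02005, 0.02921, -0.02865, 0.02122, -0.01052, -2.215e-17,
    0.00778, -0.01158, 0.01146, -0.008473, 0.004159, 3.791e-17,
    -0.002955, 0.004272, -0.004086, 0.002909, -0.001371, -5.451e-18,
    0.0009014, -0.00127, 0.001208, -0.0008864, 0.0004528, -4.168e-19,
]


def fir60_taps() -> np.ndarray:
    """Tap vector of the 60th-order FIR reference filter (symmetric)."""
    return np.array(_FIR60)


def sixteen_order_cascade(
    fs: float = 360.0,
    pass_band: tuple[float, float] = (5.0, 15.0),
    stop_band: tuple[float, float] = (49.0, 51.0),
) -> TransferFunction:
    """Build the standard two-stage digital Butterworth cascade of degree 16.

    Stage one is an order-2 band-pass over the QRS emphasis band (degree 4);
    stage two an order-6 band-stop around the mains frequency (degree 12).
    Their series combination is the 16th-degree IIR prototype that the
    minimax order-reduction stage condenses to degree 1.
    """
    bp = design_butterworth("pass", *pass_band, order=2, fs=fs)
    bs = design_butterworth("stop", *stop_band, order=6, fs=fs)
    return cascade(bp, bs)
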