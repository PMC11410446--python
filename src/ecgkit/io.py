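"""Reading and writing ECG records and peak annotations.

Two record formats are supported:

* **WFDB** (PhysioNet ``.hea`` header + ``.dat`` signal), restricted to the
  two storage formats that cover the MIT-BIH arrhythmia database: format
  212 (two 12-bit two's-complement samples packed into 3 bytes) and format
  16 (16-bit little-endian). Raw ADC units are converted to physical mV as
  ``(raw - baseline) / gain`` using the per-signal header fields. Other
  storage formats are rejected loudly rather than guessed at.
* **CSV**: a ``sample_mv`` header followed by one value per line; the
  sampling rate comes either from a ``# fs=<Hz>`` comment line or from an
  explicit argument (missing both is an error).

Annotations round-trip through a CSV with columns
``r_index,q_index,s_index,qrs_interval_s,rr_to_next_s`` (intervals written
with 9 significant digits, comfortably beyond the 1e-6 s contract; the
last beat's ``rr_to_next_s`` is empty).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .detection import QRSAnnotation
from .record import ECGRecord

__all__ = [
    "read_record",
    "write_record_csv",
    "read_annotation",
    "write_annotation",
    "decode_format212",
]


def read_record(
    path: str | Path,
    format: str = "csv",
    channel: int = 0,
    fs: float | None = None,
) -> ECGRecord:
    """Read a record from a WFDB header or a CSV file.

    For ``format="wfdb"``, ``path`` is the ``.hea`` file (or its stem) and
    ``channel`` selects the signal. For ``format="csv"`` the sampling rate
    must come from the file's ``# fs=`` line or the ``fs`` argument.
    """
    path = Path(path)
    if format == "wfdb":
        return _read_wfdb(path, channel)
    if format == "csv":
        return _read_csv(path, fs)
    raise ValueError(f"unknown record format {format!r} (use 'wfdb' or 'csv')")


# ---------------------------------------------------------------------------
# WFDB


def _read_wfdb(path: Path, channel: int) -> ECGRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"header file {hea} not found")
    lines = [ln.strip() for ln in hea.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    record_name = rec_fields[0].split("/")[0]
    n_sig = int(rec_fields[1])
    rec_fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    if not 0 <= channel < n_sig:
        raise ValueError(f"channel {channel} out of range for {n_sig} signals")
    sig_lines = lines[1: 1 + n_sig]

    specs = [_parse_signal_line(ln) for ln in sig_lines]
    fname = specs[channel]["file"]
    fmt = specs[channel]["format"]
    same_file = [i for i, s in enumerate(specs) if s["file"] == fname]
    if any(specs[i]["format"] != fmt for i in same_file):
        raise ValueError("mixed storage formats within one signal file")
    dat = hea.parent / fname
    if not dat.exists():
        raise FileNotFoundError(f"signal file {dat} not found")
    raw_bytes = dat.read_bytes()

    n_in_file = len(same_file)
    if fmt == 212:
        flat = decode_format212(raw_bytes)
    elif fmt == 16:
        flat = np.frombuffer(raw_bytes, dtype="<i2").astype(int)
    else:
        raise ValueError(
            f"unsupported WFDB storage format {fmt}; only 212 and 16 are read"
        )
    usable = (flat.size // n_in_file) * n_in_file
    frames = flat[:usable].reshape(-1, n_in_file)
    col = same_file.index(channel)
    raw = frames[:, col]
    if n_samp:
        raw = raw[:n_samp]

    spec = specs[channel]
    physical = (raw - spec["baseline"]) / spec["gain"]
    return ECGRecord(
        physical, rec_fs, record_id=record_name,
        lead=spec["description"] or f"ch{channel}",
    )


_GAIN_RE = re.compile(r"^(?P<gain>[-+0-9.eE]+)(?:\((?P<baseline>[-+0-9]+)\))?"
                      r"(?:/(?P<units>\S+))?$")


def _parse_signal_line(line: str) -> dict:
    """Parse one header signal line: filename format[xN] gain(baseline)/units
    [adc_res adc_zero init checksum blocksize description]."""
    parts = line.split(None)
    if len(parts) < 2:
        raise ValueError(f"malformed signal line: {line!r}")
    fname = parts[0]
    fmt_field = parts[1]
    m = re.match(r"^(\d+)", fmt_field)
    if not m:
        raise ValueError(f"malformed format field {fmt_field!r}")
    fmt = int(m.group(1))
    gain, baseline, adc_zero = 200.0, None, 0
    if len(parts) > 2:
        g = _GAIN_RE.match(parts[2])
        if not g:
            raise ValueError(f"malformed gain field {parts[2]!r}")
        gain = float(g.group("gain")) or 200.0
        if g.group("baseline") is not None:
            baseline = int(g.group("baseline"))
    if len(parts) > 4:
        try:
            adc_zero = int(parts[4])
        except ValueError:
            adc_zero = 0
    description = " ".join(parts[8:]) if len(parts) > 8 else ""
    return {
        "file": fname,
        "format": fmt,
        "gain": gain,
        "baseline": baseline if baseline is not None else adc_zero,
        "description": description,
    }


def decode_format212(raw: bytes) -> np.ndarray:
    """Unpack WFDB format-212 bytes into 12-bit two's-complement samples.

    Each 3-byte group holds two samples: the first is the 12 low bits of
    the little-endian pair (byte0, byte1); the second takes the high
    nibble of byte1 as its top 4 bits over byte2. A trailing partial group
    is an error naming the byte offset.
    """
    n = len(raw)
    if n % 3 != 0:
        raise ValueError(
            f"format-212 stream truncated: {n} bytes is not a multiple of 3 "
            f"(stray data begins at byte offset {n - n % 3})"
        )
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3).astype(int)
    first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
    second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
    out = np.empty(2 * b.shape[0], dtype=int)
    out[0::2] = first
    out[1::2] = second
    out[out > 2047] -= 4096  # sign-extend 12-bit two's complement
    return out


# ---------------------------------------------------------------------------
# CSV records

_FS_RE = re.compile(r"#\s*fs\s*=\s*([0-9.eE+-]+)")


def _read_csv(path: Path, fs: float | None) -> ECGRecord:
    if not path.exists():
        raise FileNotFoundError(str(path))
    samples: list[float] = []
    file_fs: float | None = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _FS_RE.match(line)
            if m:
                file_fs = float(m.group(1))
            continue
        if line == "sample_mv":
            continue
        samples.append(float(line))
    fs = file_fs if file_fs is not None else fs
    if fs is None:
        raise ValueError(
            f"{path}: no sampling rate — add a '# fs=<Hz>' line or pass fs"
        )
    return ECGRecord(np.asarray(samples), fs, record_id=path.stem)


def write_record_csv(path: str | Path, record: ECGRecord) -> None:
    """Write a record in the CSV dialect read back by :func:`read_record`."""
    lines = [f"# fs={float(record.fs)!r}", "sample_mv"]
    lines += [f"{float(v)!r}" for v in record.samples]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Annotations

_ANNOT_HEADER = "r_index,q_index,s_index,qrs_interval_s,rr_to_next_s"


def write_annotation(path: str | Path, annotation: QRSAnnotation) -> None:
    """Write an annotation CSV; lossless for indices, 1e-9 for intervals."""
    lines = [_ANNOT_HEADER]
    for i in range(annotation.n_beats):
        rr = (f"{annotation.rr[i]:.9g}" if i < annotation.rr.size else "")
        lines.append(
            f"{annotation.r_indices[i]},{annotation.q_indices[i]},"
            f"{annotation.s_indices[i]},{annotation.qrs_intervals[i]:.9g},{rr}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path) -> QRSAnnotation:
    """Read an annotation CSV written by :func:`write_annotation`."""
    lines = Path(path).read_text().strip().splitlines()
    if not lines or lines[0] != _ANNOT_HEADER:
        raise ValueError(f"{path}: missing annotation header")
    r, q, s, qrs, rr = [], [], [], [], []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        fr, fq, fs_, fqrs, frr = ln.split(",")
        r.append(int(fr))
        q.append(int(fq))
        s.append(int(fs_))
        qrs.append(float(fqrs))
        if frr:
            rr.append(float(frr))
    return QRSAnnotation(
        r_indices=np.asarray(r, dtype=int),
        q_indices=np.asarray(q, dtype=int),
        s_indices=np.asarray(s, dtype=int),
        qrs_intervals=np.asarray(qrs, dtype=float),
        rr=np.asarray(rr, dtype=float),
    )
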