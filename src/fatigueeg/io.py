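"""Reading and writing recordings: EDF (16-bit) and a plain CSV dialect.

CSV dialect: header row ``time_s,<ch1>,<ch2>,...``; one row per sample;
a sidecar ``<path>.meta`` plain-text file with ``key=value`` lines carrying
``subject_id``, ``state`` and ``rate``.

EDF reading goes through :func:`mne.io.read_raw_edf`.  Writing uses a
minimal EDF header + 16-bit record serialiser of our own (physical range
set per channel from the data), which the mne reader round-trips within
the format's quantization step.
"""

from __future__ import annotations

import math
import os

import numpy as np
import pandas as pd

from .errors import FormatError
from .recording import Recording

__all__ = ["read_recording", "write_recording"]


def write_recording(rec: Recording, path: str, format: str | None = None) -> None:
    """Write a recording to ``path`` as ``edf`` or ``csv`` (inferred from suffix)."""
    fmt = format or _infer_format(path)
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "edf":
        _write_edf(rec, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def read_recording(
    path: str,
    format: str | None = None,
    subject_id: str | None = None,
    state: str | None = None,
) -> Recording:
    """Read a recording written by :func:`write_recording`.

    ``subject_id`` and ``state`` override (or, for EDF without a sidecar,
    supply) the metadata.
    """
    fmt = format or _infer_format(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if fmt == "csv":
        return _read_csv(path, subject_id, state)
    if fmt == "edf":
        return _read_edf(path, subject_id, state)
    raise FormatError(f"unknown format {fmt!r}")


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    return ext if ext in ("csv", "edf") else ""


# ---------------------------------------------------------------- CSV dialect

def _meta_path(path: str) -> str:
    return path + ".meta"


def _write_meta(rec: Recording, path: str) -> None:
    with open(_meta_path(path), "w") as fh:
        fh.write(f"subject_id={rec.subject_id}\n")
        fh.write(f"state={rec.state}\n")
        fh.write(f"rate={rec.rate}\n")


def _read_meta(path: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    mp = _meta_path(path)
    if os.path.exists(mp):
        with open(mp) as fh:
            for line in fh:
                line = line.strip()
                if line and "=" in line:
                    k, v = line.split("=", 1)
                    meta[k.strip()] = v.strip()
    return meta


def _write_csv(rec: Recording, path: str) -> None:
    t = np.arange(rec.n_samples) / rec.rate
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.insert(0, "time_s", t)
    df.to_csv(path, index=False, float_format="%.6f")
    _write_meta(rec, path)


def _read_csv(path: str, subject_id: str | None, state: str | None) -> Recording:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"malformed CSV {path}: {exc}") from exc
    if df.columns[0] != "time_s":
        raise FormatError(f"{path}: first column must be 'time_s', got {df.columns[0]!r}")
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or non-numeric rows (NaN after parsing)")
    meta = _read_meta(path)
    t = df["time_s"].to_numpy()
    if "rate" in meta:
        rate = float(meta["rate"])
    elif len(t) >= 2:
        rate = 1.0 / (t[1] - t[0])
    else:
        raise FormatError(f"{path}: cannot determine sampling rate (field 'rate')")
    return Recording(
        data=df.iloc[:, 1:].to_numpy().T,
        rate=rate,
        channel_names=list(df.columns[1:]),
        subject_id=subject_id or meta.get("subject_id", "unknown"),
        state=state or meta.get("state", "normal"),
    )


# ------------------------------------------------------------------- EDF 16-bit

def _ascii(s: str, n: int) -> bytes:
    b = s.encode("ascii", "replace")
    if len(b) > n:
        b = b[:n]
    return b.ljust(n)


def _write_edf(rec: Recording, path: str) -> None:
    rate_i = rec.rate
    if abs(rate_i - round(rate_i)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    sr = int(round(rate_i))
    ns = rec.n_channels
    n_rec = math.ceil(rec.n_samples / sr)
    data = rec.data
    pad = n_rec * sr - rec.n_samples
    if pad:  # EDF records have fixed length; zero-pad the final second
        data = np.hstack([data, np.zeros((ns, pad))])
    # per-channel physical range, symmetric, never degenerate
    pmax = np.maximum(np.ceil(np.abs(data).max(axis=1)), 1.0)
    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(rec.subject_id, 80),
            _ascii(f"state={rec.state}", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 * (ns + 1)), 8),
            _ascii("", 44),
            _ascii(str(n_rec), 8),
            _ascii("1", 8),
            _ascii(str(ns), 4),
        ]
    )
    header += b"".join(_ascii(nm, 16) for nm in rec.channel_names)
    header += b"".join(_ascii("", 80) for _ in range(ns))  # transducer
    header += b"".join(_ascii("uV", 8) for _ in range(ns))
    header += b"".join(_ascii(str(-int(p)), 8) for p in pmax)
    header += b"".join(_ascii(str(int(p)), 8) for p in pmax)
    header += b"".join(_ascii("-32768", 8) for _ in range(ns))
    header += b"".join(_ascii("32767", 8) for _ in range(ns))
    header += b"".join(_ascii("", 80) for _ in range(ns))  # prefiltering
    header += b"".join(_ascii(str(sr), 8) for _ in range(ns))
    header += b"".join(_ascii("", 32) for _ in range(ns))  # reserved
    scale = 65535.0 / (2.0 * pmax)  # digital units per microvolt
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            seg = data[:, r * sr : (r + 1) * sr]
            dig = np.round((seg + pmax[:, None]) * scale[:, None] - 32768.0)
            fh.write(np.clip(dig, -32768, 32767).astype("<i2").tobytes())
    _write_meta(rec, path)


def _read_edf(path: str, subject_id: str | None, state: str | None) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types for bad headers
        raise FormatError(f"malformed EDF {path}: {exc}") from exc
    meta = _read_meta(path)
    return Recording(
        data=raw.get_data() * 1e6,  # mne returns volts; recordings are microvolt
        rate=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=subject_id or meta.get("subject_id", "unknown"),
        state=state or meta.get("state", "normal"),
    )
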