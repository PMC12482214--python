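"""EDF/EDF+ and TUH-style annotation I/O.

Reading goes through :func:`mne.io.read_raw_edf`.  Writing uses a minimal
16-bit EDF+ writer implemented here (fixed-layout header, one data-record
per second, a TAL annotation channel carrying the seizure events): the
format is simple enough that a compact writer keeps the package's round
trips exact and dependency-light.

The TUH-style label dialect is a CSV with header
``channel,start_time,stop_time,label`` and one row per channel-event; rows
sharing (start, stop, label) are merged into a single annotation listing
all their channels.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .record import EEGRecord, SeizureAnnotation

__all__ = ["read_edf", "write_edf", "read_tuh_labels", "write_tuh_labels"]

_ANN_LABEL = "EDF Annotations"


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _fmt_float(x: float, width: int = 8) -> str:
    for prec in range(6, -1, -1):
        s = f"{x:.{prec}f}"
        if len(s) <= width:
            return s
    raise ValueError(f"value {x} does not fit in {width} EDF header bytes")


def write_edf(record: EEGRecord, path) -> None:
    """Write a record as 16-bit EDF+C with its annotations.

    Samples are scaled per channel to the full digital range, so the
    round-trip error is at most one quantisation step.  The record is
    zero-padded to a whole number of seconds (EDF stores fixed-length
    one-second data records); the sampling rate must be an integer.
    """
    if not np.all(np.isfinite(record.data)):
        raise ValueError("record contains non-finite samples")
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samples = record.data.shape
    n_records = int(np.ceil(n_samples / fs))
    data = np.zeros((n_ch, n_records * fs))
    data[:, :n_samples] = record.data

    # Symmetric digital range: an even step count makes 0 uV exactly
    # representable, so constant-zero channels round-trip bit-exactly.
    dig_min, dig_max = -32767, 32767
    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = (
        np.round((data - phys_min[:, None]) * scale[:, None]).astype(np.int32) + dig_min
    ).astype("<i2")

    # Annotation TALs: a timekeeping TAL per record; seizure events in record 0.
    tals = []
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        if r == 0:
            for a in record.annotations:
                tal += (
                    f"+{a.onset:.4f}\x15{a.offset - a.onset:.4f}\x14{a.label}\x14\x00"
                ).encode("utf-8")
        tals.append(tal)
    ann_samples = max(60, (max(len(t) for t in tals) + 1) // 2 + 1)

    ns = n_ch + 1
    pid = record.patient_id.replace(" ", "_") or "X"
    header = b"".join(
        [
            _fixed("0", 8),
            _fixed(f"{pid} X X X", 80),
            _fixed("Startdate 01-JAN-2000 X X X", 80),
            _fixed("01.01.00", 8),
            _fixed("00.00.00", 8),
            _fixed(str(256 * (ns + 1)), 8),
            _fixed("EDF+C", 44),
            _fixed(str(n_records), 8),
            _fixed("1", 8),
            _fixed(str(ns), 4),
        ]
    )
    labels = list(record.channel_labels) + [_ANN_LABEL]
    transducers = ["AgAgCl electrode"] * n_ch + [""]
    dims = ["uV"] * n_ch + [""]
    pmin = [_fmt_float(v) for v in phys_min] + ["-1"]
    pmax = [_fmt_float(v) for v in phys_max] + ["1"]
    dmin = [str(dig_min)] * n_ch + [str(dig_min)]
    dmax = [str(dig_max)] * n_ch + [str(dig_max)]
    prefilter = [""] * ns
    spr = [str(fs)] * n_ch + [str(ann_samples)]
    for values, width in [
        (labels, 16),
        (transducers, 80),
        (dims, 8),
        (pmin, 8),
        (pmax, 8),
        (dmin, 8),
        (dmax, 8),
        (prefilter, 80),
        (spr, 8),
        ([""] * ns, 32),
    ]:
        header += b"".join(_fixed(str(v), width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
            tal = tals[r]
            fh.write(tal + b"\x00" * (2 * ann_samples - len(tal)))


def _peek_sample_rates(path) -> list[float]:
    """Per-signal sampling rates from the EDF header (annotations excluded)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        ns = int(head[252:256].decode())
        rec_dur = float(head[244:252].decode())
        sig = fh.read(256 * ns)
    labels = [sig[16 * i : 16 * (i + 1)].decode().strip() for i in range(ns)]
    off = ns * (16 + 80 + 8 * 5 + 80)
    spr = [int(sig[off + 8 * i : off + 8 * (i + 1)].decode()) for i in range(ns)]
    return [s / rec_dur for lab, s in zip(labels, spr) if lab != _ANN_LABEL]


def read_edf(path, strict_fs: bool = True) -> EEGRecord:
    """Read EDF/EDF+ into an :class:`EEGRecord` (microvolts).

    With ``strict_fs`` (default) a file whose channels carry different
    sampling rates is rejected; otherwise the reader falls back to mne's
    resampling-to-a-common-rate behaviour.
    """
    import mne

    path = Path(path)
    rates = _peek_sample_rates(path)
    if strict_fs and len(set(rates)) > 1:
        raise ValueError(
            f"channels carry mixed sampling rates {sorted(set(rates))}; "
            "pass strict_fs=False to resample to a common rate"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    annotations = []
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        if duration <= 0:
            continue
        annotations.append(SeizureAnnotation(float(onset), float(onset + duration), str(desc)))
    pid = ""
    if raw.info.get("subject_info"):
        pid = str(raw.info["subject_info"].get("his_id") or "")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return EEGRecord(
            data=data,
            fs=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
            patient_id=pid,
            annotations=annotations,
        )


def read_tuh_labels(path, record: EEGRecord, attach: bool = True) -> list[SeizureAnnotation]:
    """Read a TUH-style per-channel label CSV and merge into annotations.

    Rows with identical (start, stop, label) collapse to one annotation
    carrying the union of their channels.  Rows naming unknown channels or
    with ``stop <= start`` are skipped with a warning; out-of-range times
    are clipped to the record with a warning.
    """
    df = pd.read_csv(path, comment="#")
    required = {"channel", "start_time", "stop_time", "label"}
    if df.empty and not required.issubset(df.columns):
        return []
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label file missing columns: {sorted(missing)}")

    merged: dict[tuple[float, float, str], list[str]] = {}
    for row in df.itertuples(index=False):
        ch = str(row.channel)
        if ch not in record.channel_labels:
            warnings.warn(f"unknown channel {ch!r}: row skipped", stacklevel=2)
            continue
        start, stop = float(row.start_time), float(row.stop_time)
        if stop <= start:
            warnings.warn(f"row with stop {stop} <= start {start} rejected", stacklevel=2)
            continue
        clipped = (max(start, 0.0), min(stop, record.duration))
        if clipped != (start, stop):
            warnings.warn("annotation clipped to record extent", stacklevel=2)
            start, stop = clipped
        merged.setdefault((start, stop, str(row.label)), []).append(ch)

    annotations = [
        SeizureAnnotation(onset, offset, label, channels)
        for (onset, offset, label), channels in sorted(merged.items())
    ]
    if attach:
        record.annotations.extend(annotations)
    return annotations


def write_tuh_labels(record: EEGRecord, path) -> None:
    """Write annotations as TUH-style per-channel CSV rows."""
    rows = []
    for a in record.annotations:
        for ch in a.channels or record.channel_labels:
            rows.append({"channel": ch, "start_time": a.onset, "stop_time": a.offset, "label": a.label})
    pd.DataFrame(rows, columns=["channel", "start_time", "stop_time", "label"]).to_csv(
        path, index=False
    )
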