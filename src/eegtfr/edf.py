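"""EDF input/output.

Reading goes through MNE's EDF reader so channel labels, sampling rate
and physical units of real clinical files are honoured.  Writing covers
the plain continuous-EEG case only (integral sampling rate, 1-second
data records, 16-bit samples) — enough to round-trip synthetic cohorts
through the real-data code path.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from pathlib import Path

import numpy as np

from .records import EEGRecording


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path) -> Path:
    """Write a recording as a 16-bit EDF file with 1-second data records.

    The sampling rate must be a positive integer; a trailing partial
    second of data is dropped (with a warning) because EDF records have
    fixed duration.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError(f"EDF writer requires an integral sampling rate, got {fs}")
    spr = int(round(fs))  # samples per record per channel
    n_rec = rec.n_times // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    if n_rec * spr != rec.n_times:
        warnings.warn("trailing partial second dropped when writing EDF")
    data = rec.samples[:, : n_rec * spr]
    nch = rec.n_channels

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_max = 32767
    scale = dig_max / phys_max
    digital = np.round(data * scale[:, None]).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad(f"X X X {rec.subject_id}", 80),
        _pad(f"Startdate 01-JAN-2000 X X X label={rec.label or 'NA'}", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (1 + nch)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(nch), 4),
    ])
    fields = [
        [_pad(lbl, 16) for lbl in rec.channel_labels],
        [_pad("AgAgCl electrode", 80)] * nch,
        [_pad("uV", 8)] * nch,
        [_pad(f"{-p:.6g}"[:8], 8) for p in phys_max],
        [_pad(f"{p:.6g}"[:8], 8) for p in phys_max],
        [_pad(str(-dig_max), 8)] * nch,
        [_pad(str(dig_max), 8)] * nch,
        [_pad("", 80)] * nch,
        [_pad(str(spr), 8)] * nch,
        [_pad("", 32)] * nch,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for fld in fields:
            fh.write(b"".join(fld))
        # data records: for each second, all samples of ch0, then ch1, ...
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def read_edf(path, subject_id: str | None = None, label: str | None = None,
             therapy: str | None = None) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()  # volts
    return EEGRecording(
        samples=data * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=subject_id or Path(path).stem,
        label=label,
        therapy=therapy,
    )
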