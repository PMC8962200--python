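"""European Data Format (EDF) output with a JSON events sidecar.

Recordings are written as plain 16-bit EDF (physical units microvolts, one
data record per second).  Event markers and exact sample counts travel in a
JSON sidecar (``<stem>.events.json``) rather than an EDF+ annotation
channel, keeping the data file strictly tabular.  Reading goes through
:func:`mne.io.read_raw_edf`.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import numpy as np

from .containers import Recording, StructureError

_DIG_MAX = 32767


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as 16-bit EDF plus a JSON events sidecar.

    The last data record is zero-padded; the true sample count is stored in
    the sidecar and restored by :func:`read_edf`.  Returns the EDF path.
    """
    path = Path(path)
    fs = rec.sampling_rate
    spr = round(fs)  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = -(-rec.n_samples // spr)
    n_sig = rec.n_channels

    phys_max = float(np.max(np.abs(rec.data)))
    phys_max = max(np.ceil(phys_max), 1.0)

    header = b"".join([
        _field("0", 8),
        _field(f"subject {rec.subject_id}", 80),
        _field("synthetic intermittent motor task EEG", 80),
        _field(datetime.date(2000, 1, 1).strftime("%d.%m.%y"), 8),
        _field("00.00.00", 8),
        _field(str(256 * (n_sig + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(n_sig), 4),
    ])
    labels = [str(lab) for lab in rec.channel_labels]
    header += b"".join(_field(lab, 16) for lab in labels)
    header += b"".join(_field("synthetic", 80) for _ in labels)
    header += b"".join(_field("uV", 8) for _ in labels)
    header += b"".join(_field(f"{-phys_max:g}", 8) for _ in labels)
    header += b"".join(_field(f"{phys_max:g}", 8) for _ in labels)
    header += b"".join(_field(str(-_DIG_MAX - 1), 8) for _ in labels)
    header += b"".join(_field(str(_DIG_MAX), 8) for _ in labels)
    header += b"".join(_field("", 80) for _ in labels)
    header += b"".join(_field(str(spr), 8) for _ in labels)
    header += b"".join(_field("", 32) for _ in labels)

    padded = np.zeros((n_sig, n_records * spr))
    padded[:, : rec.n_samples] = rec.data
    digital = np.clip(
        np.round(padded / phys_max * _DIG_MAX), -_DIG_MAX - 1, _DIG_MAX
    ).astype("<i2")
    # record-interleaved layout: record 0 of every channel, record 1, ...
    interleaved = digital.reshape(n_sig, n_records, spr).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(interleaved.tobytes())

    sidecar = {
        "subject_id": rec.subject_id,
        "sampling_rate": fs,
        "n_samples": rec.n_samples,
        "events": [{"label": lab, "sample": int(s)} for lab, s in rec.events],
    }
    path.with_suffix(".events.json").write_text(
        json.dumps(sidecar, indent=1) + "\n"
    )
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file and its JSON events sidecar back into a Recording."""
    import mne

    path = Path(path)
    sidecar_path = path.with_suffix(".events.json")
    if not sidecar_path.exists():
        raise StructureError(f"events sidecar missing: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # Volts -> microvolts
    n = int(sidecar["n_samples"])
    return Recording(
        data=data[:, :n],
        sampling_rate=float(sidecar["sampling_rate"]),
        channel_labels=list(raw.ch_names),
        events=[(e["label"], int(e["sample"])) for e in sidecar["events"]],
        subject_id=str(sidecar["subject_id"]),
    )
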