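"""On-disk interchange for intermediate pipeline artefacts.

Epoch sets are stored as NumPy ``.npz`` containers holding the data cube
plus a JSON header (shape, anchor, sampling rate, labels, per-trial
conditions) so every stage of the command-line pipeline can be run, and
inspected, independently.  Continuous recordings travel as EDF + JSON
sidecar (see :mod:`fatiguersp.edf`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import EpochSet


def save_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write an EpochSet to an .npz container with a JSON header."""
    path = Path(path)
    header = {
        "anchor": epochs.anchor,
        "t0_offset_s": epochs.t0_offset_s,
        "sampling_rate": epochs.sampling_rate,
        "channel_labels": list(epochs.channel_labels),
        "subject_id": epochs.subject_id,
        "shape": list(epochs.data.shape),
    }
    np.savez_compressed(
        path,
        header=np.array(json.dumps(header)),
        data=epochs.data,
        trial_order=epochs.trial_order,
        condition=epochs.condition.astype(str),
        rejected=epochs.rejected,
    )
    return path


def load_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`save_epochs`."""
    with np.load(path, allow_pickle=False) as npz:
        header = json.loads(str(npz["header"]))
        return EpochSet(
            data=npz["data"],
            anchor=header["anchor"],
            t0_offset_s=float(header["t0_offset_s"]),
            sampling_rate=float(header["sampling_rate"]),
            channel_labels=header["channel_labels"],
            trial_order=npz["trial_order"],
            condition=npz["condition"].astype(object),
            rejected=npz["rejected"],
            subject_id=header["subject_id"],
        )
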