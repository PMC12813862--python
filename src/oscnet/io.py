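"""Serialization: epochs to HDF5 (+JSON sidecar), trials to CSV."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import pandas as pd

from .containers import EpochSet

__all__ = ["save_epochs", "load_epochs", "save_trials_csv", "load_trials_csv"]


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    """Write epoch data to HDF5 with a JSON sidecar (<path>.json).

    The array and scalar attributes go into the HDF5 file; the sampling
    rate, window offset and per-epoch condition labels go into the sidecar
    so they stay human-readable.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["t0"] = epochs.t0
    sidecar = {
        "sfreq": epochs.sfreq,
        "t0": epochs.t0,
        "shape": list(epochs.data.shape),
        "labels": epochs.labels.to_dict(orient="list") if epochs.labels is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        sfreq = float(f.attrs["sfreq"])
        t0 = float(f.attrs["t0"])
    sidecar_path = path.with_suffix(path.suffix + ".json")
    labels = None
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        if side.get("labels") is not None:
            labels = pd.DataFrame(side["labels"])
    return EpochSet(data=data, sfreq=sfreq, t0=t0, labels=labels)


def save_trials_csv(path: str | Path, frame: pd.DataFrame, config: dict | None = None) -> None:
    """One row per trial; an optional config echo lands in <path>.json."""
    path = Path(path)
    frame.to_csv(path, index=False)
    if config is not None:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(config))


def load_trials_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
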