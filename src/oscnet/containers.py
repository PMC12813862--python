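"""Shared in-memory containers for epoch-level data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EpochSet"]


@dataclass
class EpochSet:
    """Per-epoch multichannel time series.

    Attributes
    ----------
    data : (n_epochs, n_locations, n_samples) float array
        Source- (or sensor-) space time courses.
    sfreq : float
        Sampling rate, Hz.
    t0 : float
        Time of the first sample relative to item onset, s.
    labels : pandas.DataFrame or None
        One row per epoch: condition labels (task, modality, segment
        category, context_prev, context_next), behavioral outcome links
        (correct, rt_ms) and any planted ground truth (phase_delay).
    """

    data: np.ndarray
    sfreq: float
    t0: float = 0.0
    labels: pd.DataFrame | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, locations, samples)")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data must be finite")
        if self.labels is not None and len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must have one row per epoch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_locations(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sfreq

    def select(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        lab = self.labels.iloc[idx].reset_index(drop=True) if self.labels is not None else None
        return EpochSet(self.data[idx], self.sfreq, self.t0, lab)
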