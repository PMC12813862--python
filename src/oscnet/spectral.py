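"""Multitaper time-frequency decomposition on an octave-spaced grid.

Frequencies are logarithmically spaced (default 19 centers from 5.66 = 2^2.5
to 128 = 2^7 Hz in 0.25-octave steps).  Spectral smoothing targets a 3/4
octave full bandwidth B(f) = f * (2^(3/8) - 2^(-3/8)) at every frequency:

* f >= 16 Hz: fixed 250 ms windows, n_tapers = max(1, floor(T*B - 1))
  Slepian (DPSS) tapers (the 2TW - 1 heuristic with half-bandwidth W = B/2);
* f < 16 Hz: a single taper with window length T = 2/B.

Windows extending beyond the epoch are zero-padded.  This yields homogeneous
time-frequency smoothing, which the downstream cluster statistics assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss

from .containers import EpochSet

__all__ = [
    "FrequencyGrid",
    "TaperPlan",
    "SpectralSet",
    "frequency_grid",
    "taper_plan",
    "tf_transform",
    "induced_epochs",
    "power_spectra",
]

#: full smoothing bandwidth per Hz of center frequency: 3/4 octave
_OCTAVE_FRACTION = 0.75
_BW_FACTOR = 2.0 ** (_OCTAVE_FRACTION / 2) - 2.0 ** (-_OCTAVE_FRACTION / 2)


@dataclass(frozen=True)
class FrequencyGrid:
    """Octave-spaced center frequencies."""

    centers: np.ndarray
    step_octaves: float

    @property
    def n_freqs(self) -> int:
        return len(self.centers)


@dataclass(frozen=True)
class TaperPlan:
    """Per-frequency window length (s), DPSS taper count, half-bandwidth (Hz)."""

    window_s: np.ndarray
    n_tapers: np.ndarray
    half_bandwidth_hz: np.ndarray


@dataclass
class SpectralSet:
    """Complex TF coefficients, one array per frequency.

    ``coeffs[k]`` has shape (n_epochs, n_tapers_k, n_locations, n_times);
    the taper axis is treated as an extra observation index by the power and
    coherency estimators.
    """

    coeffs: list[np.ndarray]
    grid: FrequencyGrid
    plan: TaperPlan
    times: np.ndarray  # bin centers, s
    labels: "object" = None  # pandas DataFrame of condition labels, optional

    @property
    def n_epochs(self) -> int:
        return self.coeffs[0].shape[0]

    @property
    def n_locations(self) -> int:
        return self.coeffs[0].shape[2]

    def select_epochs(self, idx) -> "SpectralSet":
        lab = self.labels.iloc[idx].reset_index(drop=True) if self.labels is not None else None
        return SpectralSet([c[idx] for c in self.coeffs], self.grid, self.plan, self.times, lab)


def frequency_grid(
    f_min: float = 2.0**2.5, f_max: float = 2.0**7, step_octaves: float = 0.25
) -> FrequencyGrid:
    """Centers ``f_min * 2**(k*step)`` up to ``f_max`` (inclusive).

    ``f_max`` must sit an integer number of steps above ``f_min``.
    """
    if not (0.0 < f_min <= f_max):
        raise ValueError("need 0 < f_min <= f_max")
    if step_octaves <= 0:
        raise ValueError("step_octaves must be positive")
    n_steps = np.log2(f_max / f_min) / step_octaves
    if abs(n_steps - round(n_steps)) > 1e-6:
        raise ValueError("f_max must be an integer number of octave steps above f_min")
    k = np.arange(round(n_steps) + 1)
    return FrequencyGrid(centers=f_min * 2.0 ** (k * step_octaves), step_octaves=step_octaves)


def taper_plan(grid: FrequencyGrid, fixed_window_s: float = 0.25, f_split_hz: float = 16.0) -> TaperPlan:
    """Frequency-dependent window/taper schedule for 3/4-octave smoothing."""
    f = np.asarray(grid.centers, dtype=float)
    bw = f * _BW_FACTOR  # full smoothing bandwidth
    window = np.where(f >= f_split_hz, fixed_window_s, 2.0 / bw)
    n_tapers = np.where(
        f >= f_split_hz,
        np.maximum(1, np.floor(fixed_window_s * bw - 1).astype(int)),
        1,
    )
    return TaperPlan(window_s=window, n_tapers=n_tapers.astype(int), half_bandwidth_hz=bw / 2.0)


def _taper_kernels(f: float, window_s: float, n_tapers: int, half_bw: float, sfreq: float) -> np.ndarray:
    """Complex demodulation kernels: DPSS taper x carrier at frequency f.

    Returns (n_tapers, m) complex array; m = round(window_s * sfreq).  The
    carrier phase is referenced to the window center.  Tapers are normalized
    to unit energy so coefficient magnitude is comparable across frequencies.
    """
    m = max(2, int(round(window_s * sfreq)))
    nw = max(window_s * half_bw, 1.0)  # time-halfbandwidth product, >= 1 for a valid DPSS
    tapers = dpss(m, NW=nw, Kmax=n_tapers)
    tapers = np.atleast_2d(tapers)
    tapers = tapers / np.sqrt((tapers**2).sum(axis=1, keepdims=True))
    t = (np.arange(m) - (m - 1) / 2.0) / sfreq
    carrier = np.exp(-2j * np.pi * f * t)
    return tapers * carrier[None, :]


def tf_transform(
    epochs: EpochSet,
    grid: FrequencyGrid | None = None,
    plan: TaperPlan | None = None,
    time_step_s: float = 0.1,
    times: np.ndarray | None = None,
) -> SpectralSet:
    """Sliding-window multitaper transform at the grid frequencies.

    Time-bin centers default to ``t0, t0 + step, ...`` over the epoch
    (inclusive of the end when it falls on a step).  Windows reaching outside
    the epoch are zero-padded.  Coefficients are stored per taper.
    """
    grid = frequency_grid() if grid is None else grid
    plan = taper_plan(grid) if plan is None else plan
    data = epochs.data
    if data.shape[-1] < 2:
        raise ValueError("epochs too short for spectral analysis")
    n_ep, n_loc, n_samp = data.shape
    sfreq = epochs.sfreq
    if grid.centers.max() > sfreq / 2:
        raise ValueError("grid exceeds the Nyquist frequency")
    if times is None:
        # bin centers span the nominal epoch window inclusively (0, step, ...,
        # window length); a center on the right edge is half zero-padded
        n_bins = int(np.floor(n_samp / sfreq / time_step_s + 1e-9)) + 1
        times = epochs.t0 + time_step_s * np.arange(n_bins)
    times = np.asarray(times, dtype=float)

    flat = data.reshape(n_ep * n_loc, n_samp)
    n_bins = len(times)
    coeffs: list[np.ndarray] = []
    for f, w, k, hbw in zip(grid.centers, plan.window_s, plan.n_tapers, plan.half_bandwidth_hz):
        k = int(k)
        kern = _taper_kernels(f, w, k, hbw, sfreq)  # (k, m)
        m = kern.shape[1]
        # one projection matrix per frequency: column (bin, taper) holds the
        # kernel shifted to the bin center, truncated at the epoch edges
        # (equivalent to zero-padding the signal)
        proj = np.zeros((n_samp, n_bins * k), dtype=complex)
        for bi, tc in enumerate(times):
            center = int(round((tc - epochs.t0) * sfreq))
            lo = center - m // 2
            s_lo, s_hi = max(lo, 0), min(lo + m, n_samp)
            if s_lo < s_hi:
                proj[s_lo:s_hi, bi * k : (bi + 1) * k] = kern[:, s_lo - lo : s_hi - lo].T
        out = flat @ proj  # (n_ep*n_loc, n_bins*k)
        coeffs.append(
            out.reshape(n_ep, n_loc, n_bins, k).transpose(0, 3, 1, 2)
        )
    labels = getattr(epochs, "labels", None)
    return SpectralSet(coeffs=coeffs, grid=grid, plan=plan, times=times, labels=labels)


def induced_epochs(
    epochs: EpochSet,
    condition: np.ndarray | list | None = None,
    rng: np.random.Generator | None = None,
    stratify: bool = True,
) -> EpochSet:
    """Remove the per-condition evoked waveform, keeping induced activity.

    For each condition the across-trial mean waveform (the evoked response)
    is subtracted from every member epoch.  When ``stratify`` is set and
    condition counts differ, the mean is computed from a random subsample of
    equal size per condition (seeded via ``rng``) so that no condition
    dominates the evoked estimate.  Conditions with a single epoch are left
    untouched.
    """
    import warnings

    if condition is None:
        condition = np.zeros(epochs.n_epochs, dtype=int)
    condition = np.asarray(condition)
    rng = np.random.default_rng() if rng is None else rng
    data = epochs.data.copy()
    uniq, counts = np.unique(condition, return_counts=True)
    n_min = counts.min()
    for c in uniq:
        idx = np.flatnonzero(condition == c)
        if len(idx) < 2:
            warnings.warn(f"condition {c!r} has a single epoch; evoked subtraction skipped")
            continue
        sel = rng.choice(idx, size=n_min, replace=False) if (stratify and len(idx) > n_min) else idx
        erf = data[sel].mean(axis=0)
        data[idx] -= erf
    return EpochSet(data=data, sfreq=epochs.sfreq, t0=epochs.t0, labels=epochs.labels)


def power_spectra(spectra: SpectralSet) -> np.ndarray:
    """Trial- and taper-averaged power, shape (locations, freqs, times).

    power(f, t) = mean_i X_i(f, t) X_i*(f, t), the taper index folded into
    the observation index i.
    """
    if spectra.n_epochs < 1:
        raise ValueError("need at least one epoch")
    out = np.empty((spectra.n_locations, spectra.grid.n_freqs, len(spectra.times)))
    for k, c in enumerate(spectra.coeffs):
        # (n_ep, n_tap, n_loc, n_t) -> mean |.|^2 over ep and taper
        out[:, k, :] = (c.real**2 + c.imag**2).mean(axis=(0, 1))
    return out
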