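"""Pairwise and cross-frequency coupling measures.

Imaginary coherency (ImC) quantifies frequency-specific phase coupling with
minimal sensitivity to instantaneous (volume-conducted) mixing:

    ImC_xy(f, t) = Im( mean_i X_i Y_i* / sqrt(mean_i |X_i|^2 * mean_i |Y_i|^2) )

where i runs over trials (and tapers).  Theta-phase -> beta-amplitude
coupling is quantified with the Kullback-Leibler modulation index over 18
phase bins and normalized by a trial-shuffling shift predictor, which keeps
stimulus-locked structure but destroys the within-trial phase-amplitude
correspondence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .containers import EpochSet
from .spectral import SpectralSet

__all__ = [
    "CouplingTensor",
    "PacResult",
    "canonical_pairs",
    "imaginary_coherency",
    "pairwise_phase_delay",
    "bandpass_phase_amplitude",
    "select_pac_sites",
    "pac_modulation_index",
    "shift_predictor_mi",
    "pac_contrast",
]


@dataclass
class CouplingTensor:
    """ImC values over (pair, frequency, time) with canonical i < j pairs."""

    values: np.ndarray  # (n_pairs, n_freqs, n_times)
    pairs: np.ndarray  # (n_pairs, 2) int, i < j
    mask: np.ndarray  # True where a zero-power bin forced the value to 0
    n_trials: int


@dataclass
class PacResult:
    """Raw MI, shift-predictor statistics and the normalized contrast."""

    raw_mi: float
    predictor_mean: float
    predictor_sd: float
    contrast: float
    z: float
    n_surrogates: int
    phase_band: tuple[float, float] = (5.0, 7.0)
    amplitude_band: tuple[float, float] = (12.0, 32.0)


def canonical_pairs(n_locations: int, kept_mask: np.ndarray | None = None) -> np.ndarray:
    """All location pairs (i, j) with i < j, restricted to kept locations."""
    keep = np.ones(n_locations, bool) if kept_mask is None else np.asarray(kept_mask, bool)
    idx = np.flatnonzero(keep)
    ii, jj = np.triu_indices(len(idx), k=1)
    return np.column_stack([idx[ii], idx[jj]])


def _stacked_coeffs(spectra: SpectralSet) -> list[np.ndarray]:
    """Fold the taper axis into the observation axis: (obs, loc, times) per freq."""
    out = []
    for c in spectra.coeffs:
        n_ep, n_tap, n_loc, n_t = c.shape
        out.append(c.reshape(n_ep * n_tap, n_loc, n_t))
    return out


def imaginary_coherency(spectra: SpectralSet, pair_list: np.ndarray | None = None) -> CouplingTensor:
    """ImC for every listed location pair, frequency and time bin.

    Zero-power bins (either signal has no energy) are set to 0 and flagged
    in ``mask`` so downstream clustering stays well-defined.
    """
    if spectra.n_epochs < 2:
        raise ValueError("need at least two trials for coherency")
    pairs = canonical_pairs(spectra.n_locations) if pair_list is None else np.asarray(pair_list, int)
    if pairs.size and (pairs.min() < 0 or pairs.max() >= spectra.n_locations):
        raise ValueError("pair indices out of range")
    n_pairs, n_f = len(pairs), spectra.grid.n_freqs
    n_t = len(spectra.times)
    values = np.zeros((n_pairs, n_f, n_t))
    mask = np.zeros((n_pairs, n_f, n_t), dtype=bool)
    i, j = pairs[:, 0], pairs[:, 1]
    for k, c in enumerate(_stacked_coeffs(spectra)):
        power = (c.real**2 + c.imag**2).mean(axis=0)  # (loc, t)
        cross = np.einsum("olt,omt->lmt", c, c.conj()) / c.shape[0]  # (loc, loc, t)
        num = cross[i, j, :].imag  # (n_pairs, t)
        den = np.sqrt(power[i, :] * power[j, :])
        bad = den <= 0
        den[bad] = 1.0
        values[:, k, :] = np.where(bad, 0.0, num / den)
        mask[:, k, :] = bad
    return CouplingTensor(values=values, pairs=pairs, mask=mask, n_trials=spectra.n_epochs)


def pairwise_phase_delay(
    spectra: SpectralSet,
    pair: tuple[int, int],
    f_bin: int,
    t_bin: int,
    segment_subset: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-segment phase difference arg(X_i Y_i*) at one (pair, f, t) bin,
    plus its circular mean (the component's optimal phase relation when
    computed on the cluster-defining data).

    Tapers are averaged within segment before taking the phase.
    """
    i, j = pair
    c = spectra.coeffs[f_bin]  # (ep, tap, loc, t)
    sub = np.arange(c.shape[0]) if segment_subset is None else np.asarray(segment_subset, int)
    if sub.size == 0:
        raise ValueError("segment subset is empty")
    cross = (c[sub, :, i, t_bin] * c[sub, :, j, t_bin].conj()).mean(axis=1)
    if np.allclose(cross, 0):
        raise ValueError("all-zero coefficients at the requested bin")
    phases = np.angle(cross)
    mean_phase = float(np.angle(np.exp(1j * phases).sum()))
    return phases, mean_phase


def bandpass_phase_amplitude(
    epochs: EpochSet,
    location: int,
    band: tuple[float, float],
    output: str = "phase",
    order: int = 4,
) -> np.ndarray:
    """Band-limited instantaneous phase or envelope per epoch.

    Zero-phase Butterworth band-pass followed by the analytic-signal
    transform, applied at the native sampling rate.
    """
    sos = butter(order, band, btype="bandpass", fs=epochs.sfreq, output="sos")
    x = sosfiltfilt(sos, epochs.data[:, location, :], axis=-1)
    analytic = hilbert(x, axis=-1)
    if output == "phase":
        return np.angle(analytic)
    if output == "amplitude":
        return np.abs(analytic)
    raise ValueError("output must be 'phase' or 'amplitude'")


def select_pac_sites(per_location_stat: np.ndarray, locations: np.ndarray | None = None) -> np.ndarray:
    """Locations whose integrated cluster statistic exceeds mean + 1 SD.

    Invariant to affine rescaling of the statistic map.  If no location
    clears the threshold (e.g. a uniform map), falls back to the single
    top-value location with a warning.
    """
    stat = np.asarray(per_location_stat, dtype=float)
    locs = np.arange(len(stat)) if locations is None else np.asarray(locations, int)
    sd = stat.std(ddof=0)
    sel = np.flatnonzero(stat > stat.mean() + sd) if sd > 0 else np.array([], int)
    if sel.size == 0:
        warnings.warn("no location exceeds mean + 1 SD; falling back to the top location")
        sel = np.array([int(np.argmax(stat))])
    return locs[sel]


def pac_modulation_index(
    phase_series: np.ndarray, amplitude_series: np.ndarray, n_phase_bins: int = 18
) -> float:
    """KL-based modulation index of amplitude by phase.

    Amplitudes are binned by phase; bin-mean amplitudes are normalized to a
    distribution P and MI = KL(P || uniform) / log(n_bins), in [0, 1]:
    0 for phase-independent amplitude, 1 when all amplitude concentrates in
    a single bin.
    """
    phase = np.asarray(phase_series, float).ravel()
    amp = np.asarray(amplitude_series, float).ravel()
    if phase.shape != amp.shape:
        raise ValueError("phase and amplitude series must have equal length")
    if n_phase_bins < 4:
        raise ValueError("need at least 4 phase bins")
    edges = np.linspace(-np.pi, np.pi, n_phase_bins + 1)
    which = np.clip(np.digitize(np.mod(phase + np.pi, 2 * np.pi) - np.pi, edges) - 1, 0, n_phase_bins - 1)
    sums = np.bincount(which, weights=amp, minlength=n_phase_bins)
    counts = np.bincount(which, minlength=n_phase_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = means.sum()
    if total <= 0:
        raise ValueError("total binned amplitude is zero")
    p = means / total
    nz = p > 0
    kl = np.log(n_phase_bins) + (p[nz] * np.log(p[nz])).sum()
    return float(kl / np.log(n_phase_bins))


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of 0..n-1 with no fixed points."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def shift_predictor_mi(
    phase_epochs: np.ndarray,
    amplitude_epochs: np.ndarray,
    n_surrogates: int = 100,
    rng: np.random.Generator | None = None,
    n_phase_bins: int = 18,
) -> np.ndarray:
    """Surrogate MI distribution from trial-shuffled phase/amplitude pairing.

    Each surrogate pairs the phase of trial A with the amplitude of a
    different trial B (a random derangement over epochs), so stimulus-locked
    structure survives while within-trial coupling is destroyed.
    """
    phase = np.asarray(phase_epochs, float)
    amp = np.asarray(amplitude_epochs, float)
    if phase.shape != amp.shape or phase.ndim != 2:
        raise ValueError("expect matching (n_epochs, n_samples) arrays")
    if phase.shape[0] < 3:
        raise ValueError("need at least 3 epochs for a shift predictor")
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    out = np.empty(n_surrogates)
    for s in range(n_surrogates):
        perm = _derangement(phase.shape[0], rng)
        out[s] = pac_modulation_index(phase, amp[perm], n_phase_bins)
    return out


def pac_contrast(raw_mi: float, surrogate_mis: np.ndarray, **bands) -> PacResult:
    """Shift-predictor-normalized PAC: raw MI minus the surrogate mean
    (plus a z-scored variant)."""
    sur = np.asarray(surrogate_mis, float)
    if sur.size == 0:
        raise ValueError("surrogate distribution is empty")
    mean = float(sur.mean())
    sd = float(sur.std(ddof=1)) if sur.size > 1 else 0.0
    z = (raw_mi - mean) / sd if sd > 0 else np.nan
    return PacResult(
        raw_mi=float(raw_mi),
        predictor_mean=mean,
        predictor_sd=sd,
        contrast=float(raw_mi - mean),
        z=float(z),
        n_surrogates=sur.size,
        **bands,
    )
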