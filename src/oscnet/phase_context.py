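"""Behavioral tuning by coupling phase, and stimulus-context modulation.

For a coupling cluster, each component (location pair, frequency, time bin)
has an *optimal phase relation*: the circular mean of its per-segment phase
differences.  Behavioral performance is then analyzed as a function of each
segment's delay from that optimum — binned into 8 phase bins centered on
zero delay — with safeguards against circular reuse of data (split-half for
accuracy) and against unequal bin occupancy (equal-count bins of absolute
delay, Spearman trend).

The context modulation index (same - different)/(same + different) of band
power indexes sensitivity to whether a neighboring sequence item matches
the current one.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
from scipy import stats

__all__ = [
    "TuningCurve",
    "N_PHASE_BINS",
    "phase_bin_centers",
    "bin_index",
    "wrap_phase",
    "optimal_phase_relation",
    "rt_tuning_curve",
    "split_half_accuracy_tuning",
    "average_tuning_curves",
    "absolute_delay_correlation",
    "extreme_delay_voxel_correlation",
    "context_labels",
    "context_modulation_index",
]

N_PHASE_BINS = 8


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, 2 * np.pi) - np.pi


def phase_bin_centers(n_bins: int = N_PHASE_BINS) -> np.ndarray:
    """Bin centers 0, ±pi/4, ... with the first bin centered on zero delay."""
    k = np.arange(n_bins)
    return wrap_phase(k * 2 * np.pi / n_bins)


def bin_index(delays: np.ndarray, n_bins: int = N_PHASE_BINS) -> np.ndarray:
    """Assign wrapped delays to bins centered on 0 (first bin [-pi/8, pi/8))."""
    width = 2 * np.pi / n_bins
    return (np.floor(wrap_phase(delays) / width + 0.5).astype(int)) % n_bins


@dataclass
class TuningCurve:
    """Mean-removed performance per phase-delay bin."""

    bin_centers: np.ndarray
    values: np.ndarray  # NaN where a bin is empty
    counts: np.ndarray

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, float)
        self.values = np.asarray(self.values, float)
        self.counts = np.asarray(self.counts, int)


def optimal_phase_relation(component_phases: np.ndarray) -> float:
    """Circular mean of per-segment phase differences for one component.

    Raises if the resultant vector vanishes (undefined mean direction).
    """
    phases = np.asarray(component_phases, float)
    if phases.size == 0:
        raise ValueError("need at least one segment")
    r = np.exp(1j * phases).sum()
    if np.abs(r) < 1e-12:
        raise ValueError("zero resultant: optimal phase relation undefined")
    return float(np.angle(r))


def _binned_means(delays: np.ndarray, values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    which = bin_index(delays, n_bins)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=values, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    return means, counts


def rt_tuning_curve(
    segment_phases: list[np.ndarray] | np.ndarray,
    rts: list[np.ndarray] | np.ndarray,
    optima: list[float] | float | None = None,
    n_bins: int = N_PHASE_BINS,
) -> TuningCurve:
    """RT by phase-delay bin for one subject.

    ``segment_phases`` / ``rts`` are per-component arrays (a single array is
    treated as one component).  Each component's optimum defaults to the
    circular mean of its own segments.  Per-bin means are averaged across
    components (unweighted), then the curve is mean-removed; empty bins are
    NaN and excluded from averaging.
    """
    if isinstance(segment_phases, np.ndarray) and segment_phases.ndim == 1:
        segment_phases, rts = [segment_phases], [np.asarray(rts)]
    if optima is None:
        optima = [optimal_phase_relation(p) for p in segment_phases]
    elif np.isscalar(optima):
        optima = [float(optima)] * len(segment_phases)
    per_comp = []
    counts = np.zeros(n_bins, int)
    for phases, r, opt in zip(segment_phases, rts, optima):
        m, c = _binned_means(np.asarray(phases) - opt, np.asarray(r, float), n_bins)
        per_comp.append(m)
        counts += c
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins allowed
        mean_curve = np.nanmean(np.vstack(per_comp), axis=0)
    mean_curve = mean_curve - np.nanmean(mean_curve)
    return TuningCurve(phase_bin_centers(n_bins), mean_curve, counts)


def split_half_accuracy_tuning(
    segment_phases: np.ndarray,
    correct: np.ndarray,
    rng: np.random.Generator | None = None,
    n_bins: int = N_PHASE_BINS,
) -> TuningCurve:
    """Hit percentage by phase-delay bin, with a split-half optimum.

    A random half of the correct segments defines the optimal phase
    relation; the complementary half of the *full* data (correct and
    incorrect, excluding the defining segments) is binned by delay from that
    optimum and hit percentage computed per bin.  Roles are swapped and the
    two curves averaged.  The result is mean-removed.
    """
    rng = np.random.default_rng() if rng is None else rng
    phases = np.asarray(segment_phases, float)
    corr = np.asarray(correct, bool)
    correct_idx = np.flatnonzero(corr)
    if len(correct_idx) < 4:
        raise ValueError("need at least two correct segments per half")
    perm = rng.permutation(correct_idx)
    halves = (perm[: len(perm) // 2], perm[len(perm) // 2 :])
    curves, counts = [], np.zeros(n_bins, int)
    for defining in halves:
        if defining.size == 0:
            raise ValueError("a split half contains no correct segments")
        opt = optimal_phase_relation(phases[defining])
        rest = np.setdiff1d(np.arange(len(phases)), defining)
        m, c = _binned_means(phases[rest] - opt, corr[rest].astype(float), n_bins)
        curves.append(100.0 * m)
        counts += c
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = np.nanmean(np.vstack(curves), axis=0)
    curve = curve - np.nanmean(curve)
    return TuningCurve(phase_bin_centers(n_bins), curve, counts)


def average_tuning_curves(curves: list[TuningCurve]) -> TuningCurve:
    """Across-subject average (delay is a relative measure, so curves from
    different subjects are directly comparable)."""
    vals = np.vstack([c.values for c in curves])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=0)
    return TuningCurve(curves[0].bin_centers, mean, np.sum([c.counts for c in curves], axis=0))


def absolute_delay_correlation(
    delays: np.ndarray,
    performance: np.ndarray,
    optimal: float = 0.0,
    n_bins: int = N_PHASE_BINS,
) -> tuple[float, float, np.ndarray]:
    """Spearman trend of performance over equal-count bins of |delay|.

    Bins hold (as nearly as possible) equal segment counts, so the bin near
    zero delay is narrow and the farthest bin wide; ties are split by stable
    sort order.  Returns (rho, p, per-bin mean performance).
    """
    d = np.abs(wrap_phase(np.asarray(delays) - optimal))
    perf = np.asarray(performance, float)
    if d.size < n_bins:
        raise ValueError("need at least one segment per bin")
    order = np.argsort(d, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(d.size)
    which = (ranks * n_bins) // d.size
    means = np.array([perf[which == b].mean() for b in range(n_bins)])
    rho, p = stats.spearmanr(np.arange(n_bins), means)
    return float(rho), float(p), means


def extreme_delay_voxel_correlation(
    voxel_delays: list[list[np.ndarray]],
    voxel_performance: list[list[np.ndarray]],
    integrated_stat: np.ndarray,
    tail_fraction: float = 0.25,
) -> tuple[float, float, np.ndarray]:
    """Correlate per-voxel phase-tuning strength with cluster statistics.

    For every voxel, each subject contributes the performance difference
    between the bottom and top ``tail_fraction`` of segments ranked by
    absolute delay from the optimum; a one-sample t across subjects gives a
    per-voxel tuning-strength t value.  Returns the Pearson correlation of
    these t values with the voxels' integrated cluster statistic (r, p,
    t values; voxels whose tails hold < 4 segments, or with undefined t,
    are NaN and excluded).
    """
    integrated_stat = np.asarray(integrated_stat, float)
    n_vox = len(voxel_delays)
    t_vals = np.full(n_vox, np.nan)
    for v in range(n_vox):
        diffs = []
        for d, perf in zip(voxel_delays[v], voxel_performance[v]):
            d = np.abs(wrap_phase(np.asarray(d)))
            perf = np.asarray(perf, float)
            k = int(np.floor(tail_fraction * d.size))
            if k < 4:
                continue
            order = np.argsort(d, kind="stable")
            diffs.append(perf[order[:k]].mean() - perf[order[-k:]].mean())
        if len(diffs) >= 2 and np.std(diffs) > 0:
            t_vals[v] = stats.ttest_1samp(diffs, 0.0).statistic
    ok = np.isfinite(t_vals)
    if ok.sum() < 3 or np.std(t_vals[ok]) == 0 or np.std(integrated_stat[ok]) == 0:
        raise ValueError("correlation undefined: too few voxels or zero variance")
    r, p = stats.pearsonr(t_vals[ok], integrated_stat[ok])
    return float(r), float(p), t_vals


def context_labels(items: list[int], item_index: int) -> tuple[str | None, str | None]:
    """('same'|'different'|None) for the previous and next item.

    ``item_index`` is 0-based within the attended-modality item list; the
    first item has no previous label, the last no next label.
    """
    def rel(j):
        if j < 0 or j >= len(items):
            return None
        return "same" if items[j] == items[item_index] else "different"

    return rel(item_index - 1), rel(item_index + 1)


def context_modulation_index(power_same: float, power_diff: float) -> float:
    """MI = (same - different) / (same + different) of band power."""
    if power_same < 0 or power_diff < 0:
        raise ValueError("powers must be nonnegative")
    s = power_same + power_diff
    if s == 0:
        raise ValueError("modulation index undefined for zero total power")
    return (power_same - power_diff) / s
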