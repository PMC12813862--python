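"""Synthetic source-space epochs carrying planted oscillatory structure.

The generator emulates, per subject, the statistical structure the analysis
pipeline is designed to detect:

* 1/f background noise at every source location;
* a theta oscillation at two spatially contiguous patches whose cross-patch
  phase lag is von Mises distributed around a preferred lag, with a
  task-dependent concentration (stronger phase coupling in the prediction
  task) — detectable as an imaginary-coherency cluster;
* a beta oscillation whose amplitude is scaled by the stimulus context
  (previous/next item same vs. different in the attended modality);
* theta-phase -> beta-amplitude coupling at designated sites, randomized at
  the trial level so a trial-shuffling shift predictor destroys it;
* behavioral accuracy and response time cosine-tuned by the deviation of
  the realized phase lag from the preferred lag.

Every planted quantity (realized phase delay, context labels, behavioral
outcome) is recorded in the epoch labels so recovery can be verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import taskgen
from .containers import EpochSet
from .sourcespace import SourceSpace, bilateral_source_space, spatial_adjacency

__all__ = [
    "ScenarioConfig",
    "default_scenario",
    "pink_noise",
    "generate_source_epochs",
    "generate_study",
    "toy_forward_and_project",
]


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic dataset.

    Defaults plant effects that the full pipeline recovers at 12 subjects
    and 60 trials per condition on a depth-0 bilateral source space.
    """

    n_subjects: int = 12
    n_trials_per_condition: int = 60
    sampling_rate: float = 400.0
    epoch_window: tuple[float, float] = (0.0, 0.7)
    source_depth: int = 0  # icosphere subdivision depth (24 locations bilaterally)

    # theta coupling between two patches of locations
    theta_freq: float = 6.0  # Hz, inside the 5-7 Hz band
    theta_amp: float = 1.0
    patch_a: tuple[int, ...] = ()  # filled by default_scenario / __post_init__
    patch_b: tuple[int, ...] = ()
    preferred_lag: float = np.pi / 2  # rad; maximizes the imaginary part
    kappa_by_task: dict = field(default_factory=lambda: {"prediction": 4.0, "memory": 0.0})

    # beta context effect
    beta_freq: float = 20.0  # Hz, inside the 12-32 Hz band
    beta_amp: float = 1.0
    beta_sites: tuple[int, ...] = ()
    context_feature: str = "prev"  # which neighbor item drives the gain
    context_gain_same: float = 1.5
    context_gain_diff: float = 1.0

    # theta-phase -> beta-amplitude coupling
    pac_phase_sites: tuple[int, ...] = ()
    pac_amp_sites: tuple[int, ...] = ()
    pac_depth: float = 0.0  # in [0, 1]

    # background noise
    noise_exponent: float = 1.0
    noise_amp: float = 1.0

    # behavior tuning by phase delay
    behavior_p0: float = 0.8
    behavior_acc_depth: float = 0.15
    behavior_r0_ms: float = 500.0
    behavior_rt_depth_ms: float = 40.0
    behavior_rt_noise_ms: float = 30.0

    segments_per_trial: tuple[str, ...] = ("prediction",)

    def __post_init__(self):
        if self.pac_depth < 0 or self.pac_depth > 1:
            raise ValueError("pac_depth must lie in [0, 1]")
        for k, v in self.kappa_by_task.items():
            if v < 0:
                raise ValueError(f"kappa for task {k!r} must be >= 0")
        nyq = self.sampling_rate / 2
        if not (0 < self.theta_freq < nyq and 0 < self.beta_freq < nyq):
            raise ValueError("oscillation frequencies must lie below Nyquist")
        if self.behavior_p0 - self.behavior_acc_depth < 0 or self.behavior_p0 + self.behavior_acc_depth > 1:
            raise ValueError("behavioral accuracy tuning must stay inside [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_window[1] - self.epoch_window[0]) * self.sampling_rate))

    def space(self) -> SourceSpace:
        return bilateral_source_space(self.source_depth)

    def performance_model(self) -> taskgen.PhaseTunedPerformanceModel:
        return taskgen.PhaseTunedPerformanceModel(
            p0=self.behavior_p0,
            acc_depth=self.behavior_acc_depth,
            r0_ms=self.behavior_r0_ms,
            rt_depth_ms=self.behavior_rt_depth_ms,
            rt_noise_ms=self.behavior_rt_noise_ms,
            preferred_lag=self.preferred_lag,
            kappa_by_task=dict(self.kappa_by_task),
        )


def default_scenario() -> ScenarioConfig:
    """The documented default study conditions.

    The theta patches are a vertex and its mesh neighbors in each
    hemisphere, so the planted coupling forms a connected cluster in pair
    space; the beta/PAC sites sit on the right-hemisphere patch.
    """
    cfg = ScenarioConfig()
    space = cfg.space()
    nbrs = spatial_adjacency(space)
    n_hemi = space.n_locations // 2
    seed_a, seed_b = 0, n_hemi  # one seed vertex per hemisphere
    patch_a = (seed_a, *sorted(nbrs[seed_a])[:3])
    patch_b = (seed_b, *sorted(nbrs[seed_b])[:3])
    cfg.patch_a, cfg.patch_b = patch_a, patch_b
    cfg.beta_sites = patch_b
    cfg.pac_phase_sites = (seed_a,)
    cfg.pac_amp_sites = (seed_b,)
    cfg.pac_depth = 0.6
    return cfg


def pink_noise(
    shape: tuple[int, ...],
    n_samples: int,
    sfreq: float,
    exponent: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Gaussian 1/f^exponent noise (power spectral density slope), unit SD.

    Synthesized in the frequency domain: independent complex Gaussian
    coefficients scaled by f^(-exponent/2), inverse-FFT'd to time.
    """
    rng = np.random.default_rng() if rng is None else rng
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    coeff = rng.standard_normal((*shape, len(freqs))) + 1j * rng.standard_normal((*shape, len(freqs)))
    x = np.fft.irfft(coeff * scale, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _context_label(items: list[int], idx0: int, which: str) -> str | None:
    """'same'/'different' relative to the previous or next item (0-indexed)."""
    j = idx0 - 1 if which == "prev" else idx0 + 1
    if j < 0 or j >= len(items):
        return None
    return "same" if items[j] == items[idx0] else "different"


def generate_source_epochs(
    config: ScenarioConfig,
    trials: list[taskgen.TrialRecord],
    rng: np.random.Generator | None = None,
) -> EpochSet:
    """Source-space epochs for one subject's trials.

    One epoch per trial and per requested segment category.  If a trial
    carries a realized ``phase_delay`` (from the phase-tuned performance
    model), that exact lag is planted in the theta component so behavior and
    neural coupling are generated from the same latent variable; otherwise a
    lag is drawn from the task's von Mises law.
    """
    rng = np.random.default_rng() if rng is None else rng
    space = config.space()
    n_loc = space.n_locations
    n_samp = config.n_samples
    t = config.epoch_window[0] + np.arange(n_samp) / config.sampling_rate
    model = config.performance_model()

    rows = []
    segs = []
    for tr in trials:
        for cat in config.segments_per_trial:
            if cat == "sampling":
                lo, hi = 1, min(3, tr.n_items - 2)  # items 2..4, 0-indexed 1..3
            elif cat == "prediction":
                lo, hi = 5, max(5, tr.n_items - 2)  # item 6 .. penultimate
            else:  # response
                lo = hi = tr.n_items - 1
            item_idx = int(rng.integers(lo, hi + 1))
            items = tr.attended_items
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "task": tr.task,
                    "modality": tr.attended_modality,
                    "segment": cat,
                    "item_index": item_idx,
                    "context_prev": _context_label(items, item_idx, "prev"),
                    "context_next": _context_label(items, item_idx, "next"),
                    "correct": tr.correct,
                    "rt_ms": tr.rt_ms,
                    "phase_delay": tr.phase_delay,
                }
            )
            segs.append(tr)

    labels = pd.DataFrame(rows)
    n_ep = len(labels)
    data = config.noise_amp * pink_noise(
        (n_ep, n_loc), n_samp, config.sampling_rate, config.noise_exponent, rng
    )

    omega_th = 2 * np.pi * config.theta_freq
    omega_be = 2 * np.pi * config.beta_freq
    gain_key = f"context_{config.context_feature}"
    delays = np.empty(n_ep)
    for e in range(n_ep):
        tr = segs[e]
        dphi = labels.at[e, "phase_delay"]
        if dphi is None or (isinstance(dphi, float) and np.isnan(dphi)):
            dphi = model.draw_phase(tr.task, rng)
        delays[e] = dphi
        phi_a = rng.uniform(0, 2 * np.pi)
        phi_b = phi_a - dphi
        if config.theta_amp > 0:
            for q in config.patch_a:
                data[e, q] += config.theta_amp * np.cos(omega_th * t + phi_a)
            for q in config.patch_b:
                data[e, q] += config.theta_amp * np.cos(omega_th * t + phi_b)
        if config.beta_amp > 0 and config.beta_sites:
            ctx = labels.at[e, gain_key]
            gain = config.context_gain_same if ctx == "same" else config.context_gain_diff
            for q in config.beta_sites:
                env = gain
                if config.pac_depth > 0 and q in config.pac_amp_sites and config.pac_phase_sites:
                    theta_phase = omega_th * t + (phi_a if config.pac_phase_sites[0] in config.patch_a else phi_b)
                    env = gain * (1.0 + config.pac_depth * np.cos(theta_phase))
                data[e, q] += config.beta_amp * env * np.cos(omega_be * t + rng.uniform(0, 2 * np.pi))
    labels["phase_delay"] = delays
    return EpochSet(data=data, sfreq=config.sampling_rate, t0=config.epoch_window[0], labels=labels)


def generate_study(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> list[tuple[list[taskgen.TrialRecord], EpochSet]]:
    """Simulate every subject: task trials (phase-tuned behavior) + epochs.

    Trials cycle through the task x modality cells, with
    ``n_trials_per_condition`` trials in each of the four cells.
    """
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for _ in range(config.n_subjects):
        trials = taskgen.simulate_session(
            n_trials=4 * config.n_trials_per_condition,
            design=taskgen.SessionDesign(),
            performance_model=config.performance_model(),
            rng=rng,
        )
        epochs = generate_source_epochs(config, trials, rng)
        out.append((trials, epochs))
    return out


def toy_forward_and_project(
    epochs: EpochSet,
    n_sensors: int,
    snr: float = 10.0,
    rng: np.random.Generator | None = None,
    lead_field: np.ndarray | None = None,
    orientations: np.ndarray | None = None,
) -> tuple[EpochSet, np.ndarray, np.ndarray]:
    """Project source epochs through a toy forward model to sensors.

    A random Gaussian lead field with three columns per location (unit-norm
    columns) stands in for a physical head model.  Each scalar source feeds
    its location's columns through a random unit orientation; white sensor
    noise is added at the requested power SNR.

    Returns (sensor_epochs, lead_field, orientations); the lead field has
    shape (n_sensors, 3 * n_locations).
    """
    rng = np.random.default_rng() if rng is None else rng
    n_loc = epochs.n_locations
    if n_sensors < n_loc:
        raise ValueError("need at least as many sensors as source locations")
    if lead_field is None:
        lead_field = rng.standard_normal((n_sensors, 3 * n_loc))
        lead_field /= np.linalg.norm(lead_field, axis=0, keepdims=True)
    if np.linalg.matrix_rank(lead_field) < min(lead_field.shape):
        raise ValueError("lead field is rank-deficient; increase n_sensors or reseed")
    if orientations is None:
        orientations = rng.standard_normal((n_loc, 3))
        orientations /= np.linalg.norm(orientations, axis=1, keepdims=True)
    # effective scalar gain per location
    gains = np.stack(
        [lead_field[:, 3 * q : 3 * q + 3] @ orientations[q] for q in range(n_loc)], axis=1
    )  # (n_sensors, n_loc)
    sensor = np.einsum("sq,eqn->esn", gains, epochs.data)
    p_sig = (sensor**2).mean()
    if np.isfinite(snr):
        sigma = np.sqrt(p_sig / snr) if snr > 0 else 0.0
        sensor = sensor + sigma * rng.standard_normal(sensor.shape)
    return (
        EpochSet(sensor, epochs.sfreq, epochs.t0, epochs.labels),
        lead_field,
        orientations,
    )
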