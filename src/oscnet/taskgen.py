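"""Serial-prediction task simulation and behavioral measures.

The simulated paradigm presents a 5-item binary audiovisual base sequence
that repeats cyclically for 8-20 items; the trial endpoint follows an
approximately constant hazard rate so it cannot be anticipated.  The final
item independently violates the base sequence in each modality with
probability 0.5.  Participants respond whether the last item in the attended
modality complied with the sequence (prediction task) or matched an n-back
item (memory control task).

Behavioral summary measures follow signal-detection conventions:
``corrected_accuracy = (hit - false_alarm) / (1 - false_alarm)`` and
response times of correct trials are trimmed at 3 SD.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SequenceSpec",
    "HazardConfig",
    "TrialRecord",
    "BehaviorSummary",
    "FlatPerformanceModel",
    "PhaseTunedPerformanceModel",
    "enumerate_sequences",
    "sample_trial",
    "simulate_session",
    "corrected_accuracy",
    "filter_response_times",
    "summarize_behavior",
    "trials_to_frame",
]


@dataclass(frozen=True)
class SequenceSpec:
    """Base-sequence layout: ``length`` items, binary feature per modality."""

    length: int = 5
    n_symbols: int = 2

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("sequence length must be >= 1")
        if self.n_symbols != 2:
            raise ValueError("exactly 2 symbols per modality are supported")


@dataclass(frozen=True)
class HazardConfig:
    """Truncated-geometric trial-length law.

    After each of items ``min_items .. max_items - 1`` the trial stops with
    probability ``hazard``; any residual probability mass is placed on
    ``max_items``, so the conditional stopping probability is constant over
    the interior of the range.
    """

    hazard: float = 0.15
    min_items: int = 8
    max_items: int = 20

    def __post_init__(self):
        if not 0.0 < self.hazard <= 1.0:
            raise ValueError("hazard must lie in (0, 1]")
        if self.min_items > self.max_items:
            raise ValueError("min_items must not exceed max_items")


@dataclass
class TrialRecord:
    """One simulated trial."""

    trial_id: int
    items_visual: list[int]
    items_auditory: list[int]
    n_items: int
    attended_modality: str  # "visual" | "auditory"
    task: str  # "prediction" | "memory"
    nback: int = 1  # memory-control load (1-back or 2-back)
    violation_visual: bool = False
    violation_auditory: bool = False
    correct: bool = True
    rt_ms: float = 500.0
    phase_delay: float | None = None  # realized theta phase lag (rad), if modeled

    @property
    def attended_violation(self) -> bool:
        return self.violation_visual if self.attended_modality == "visual" else self.violation_auditory

    @property
    def attended_items(self) -> list[int]:
        return self.items_visual if self.attended_modality == "visual" else self.items_auditory


@dataclass(frozen=True)
class BehaviorSummary:
    hit_rate: float
    false_alarm_rate: float
    corrected_accuracy: float
    mean_rt_ms: float
    n_excluded_rts: int


def enumerate_sequences(spec: SequenceSpec = SequenceSpec()) -> list[tuple[int, ...]]:
    """All distinct base sequences for one modality (2**length of them)."""
    return list(itertools.product(range(spec.n_symbols), repeat=spec.length))


def _sample_n_items(cfg: HazardConfig, rng: np.random.Generator) -> int:
    for k in range(cfg.min_items, cfg.max_items):
        if rng.random() < cfg.hazard:
            return k
    return cfg.max_items


def sample_trial(
    base_visual: Sequence[int],
    base_auditory: Sequence[int],
    task: str,
    attended_modality: str,
    hazard_config: HazardConfig = HazardConfig(),
    rng: np.random.Generator | None = None,
    trial_id: int = 0,
    violation_prob: float = 0.5,
    nback: int = 1,
) -> TrialRecord:
    """Draw one trial: cyclic repetition of the base sequences, a
    hazard-governed length, and independent final-item violations per modality.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_items = _sample_n_items(hazard_config, rng)
    items_v = [base_visual[i % len(base_visual)] for i in range(n_items)]
    items_a = [base_auditory[i % len(base_auditory)] for i in range(n_items)]
    viol_v = bool(rng.random() < violation_prob)
    viol_a = bool(rng.random() < violation_prob)
    # binary alphabet: a violation flips the expected final symbol
    if viol_v:
        items_v[-1] = 1 - items_v[-1]
    if viol_a:
        items_a[-1] = 1 - items_a[-1]
    return TrialRecord(
        trial_id=trial_id,
        items_visual=items_v,
        items_auditory=items_a,
        n_items=n_items,
        attended_modality=attended_modality,
        task=task,
        nback=nback,
        violation_visual=viol_v,
        violation_auditory=viol_a,
    )


class FlatPerformanceModel:
    """Phase-independent responder: fixed accuracy, lognormal-ish RT."""

    def __init__(self, accuracy: float = 0.9, rt_mean_ms: float = 500.0, rt_sd_ms: float = 80.0):
        if not 0.0 <= accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        self.accuracy = accuracy
        self.rt_mean_ms = rt_mean_ms
        self.rt_sd_ms = rt_sd_ms

    def respond(self, trial: TrialRecord, rng: np.random.Generator) -> tuple[bool, float, float | None]:
        correct = bool(rng.random() < self.accuracy)
        rt = max(50.0, rng.normal(self.rt_mean_ms, self.rt_sd_ms))
        return correct, rt, None


class PhaseTunedPerformanceModel:
    """Responder whose performance is cosine-tuned by theta coupling phase.

    For each trial a cross-region phase delay ``phi`` is drawn from a von
    Mises law centered on the preferred lag ``mu`` with concentration
    ``kappa`` (per task); performance then follows

        P(correct) = p0 + acc_depth * cos(phi - mu)
        RT         = r0 - rt_depth_ms * cos(phi - mu) + noise

    so accuracy peaks, and RT troughs, at zero delay from the preferred lag.
    The realized delay is stored on the trial so a signal generator can plant
    the identical lag in the neural data.
    """

    def __init__(
        self,
        p0: float = 0.8,
        acc_depth: float = 0.15,
        r0_ms: float = 500.0,
        rt_depth_ms: float = 40.0,
        rt_noise_ms: float = 30.0,
        preferred_lag: float = np.pi / 2,
        kappa_by_task: dict[str, float] | None = None,
    ):
        if not 0.0 <= acc_depth <= 1.0:
            raise ValueError("acc_depth must lie in [0, 1]")
        if p0 - acc_depth < 0.0 or p0 + acc_depth > 1.0:
            raise ValueError("p0 +/- acc_depth must stay inside [0, 1]")
        self.p0 = p0
        self.acc_depth = acc_depth
        self.r0_ms = r0_ms
        self.rt_depth_ms = rt_depth_ms
        self.rt_noise_ms = rt_noise_ms
        self.preferred_lag = preferred_lag
        self.kappa_by_task = kappa_by_task or {"prediction": 2.0, "memory": 0.0}

    def draw_phase(self, task: str, rng: np.random.Generator) -> float:
        kappa = self.kappa_by_task.get(task, 0.0)
        if kappa <= 0:
            return float(rng.uniform(-np.pi, np.pi))
        return float(rng.vonmises(self.preferred_lag, kappa))

    def respond(self, trial: TrialRecord, rng: np.random.Generator) -> tuple[bool, float, float | None]:
        phi = self.draw_phase(trial.task, rng)
        dphi = phi - self.preferred_lag
        p = np.clip(self.p0 + self.acc_depth * math.cos(dphi), 0.0, 1.0)
        correct = bool(rng.random() < p)
        rt = max(50.0, self.r0_ms - self.rt_depth_ms * math.cos(dphi) + rng.normal(0.0, self.rt_noise_ms))
        return correct, rt, phi


@dataclass(frozen=True)
class SessionDesign:
    """Block structure: which task x modality cells appear, with n-back load."""

    tasks: tuple[str, ...] = ("prediction", "memory")
    modalities: tuple[str, ...] = ("visual", "auditory")
    nback: int = 1
    hazard: HazardConfig = field(default_factory=HazardConfig)
    violation_prob: float = 0.5


def simulate_session(
    n_trials: int,
    design: SessionDesign = SessionDesign(),
    performance_model=None,
    rng: np.random.Generator | None = None,
    spec: SequenceSpec = SequenceSpec(),
) -> list[TrialRecord]:
    """Simulate ``n_trials`` trials cycling through the design's cells.

    Each trial draws a fresh base sequence per modality, a hazard-governed
    length and final-item violations; the performance model fills in
    correctness, RT and (optionally) the realized coupling phase delay.
    Deterministic under a fixed ``rng`` seed.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng() if rng is None else rng
    model = FlatPerformanceModel() if performance_model is None else performance_model
    bases = enumerate_sequences(spec)
    cells = [(t, m) for t in design.tasks for m in design.modalities]
    trials = []
    for i in range(n_trials):
        task, modality = cells[i % len(cells)]
        bv = bases[rng.integers(len(bases))]
        ba = bases[rng.integers(len(bases))]
        tr = sample_trial(
            bv, ba, task, modality, design.hazard, rng,
            trial_id=i, violation_prob=design.violation_prob, nback=design.nback,
        )
        correct, rt, phi = model.respond(tr, rng)
        tr.correct, tr.rt_ms, tr.phase_delay = correct, rt, phi
        trials.append(tr)
    return trials


def corrected_accuracy(hit_rate: float, false_alarm_rate: float) -> float:
    """Guessing-corrected accuracy ``(hit - FA) / (1 - FA)``."""
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= false_alarm_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if false_alarm_rate >= 1.0:
        raise ValueError("corrected accuracy undefined for false_alarm_rate = 1")
    return (hit_rate - false_alarm_rate) / (1.0 - false_alarm_rate)


def filter_response_times(
    rts: Sequence[float], correct_flags: Sequence[bool]
) -> tuple[np.ndarray, int]:
    """Keep correct-response RTs within 3 SD of their mean (single pass).

    Mean and SD are computed once on the correct-response RTs; incorrect
    responses are never included.  Returns the kept RTs and the number of
    correct-response RTs excluded as outliers.
    """
    rts = np.asarray(rts, dtype=float)
    flags = np.asarray(correct_flags, dtype=bool)
    if rts.size == 0:
        raise ValueError("rts must be nonempty")
    correct_rts = rts[flags]
    if correct_rts.size == 0:
        return np.array([]), 0
    mu = correct_rts.mean()
    sd = correct_rts.std(ddof=1) if correct_rts.size > 1 else 0.0
    keep = np.abs(correct_rts - mu) <= 3.0 * sd if sd > 0 else np.ones(correct_rts.size, bool)
    return correct_rts[keep], int((~keep).sum())


def summarize_behavior(trials: Sequence[TrialRecord]) -> BehaviorSummary:
    """Hit/false-alarm rates on attended-modality violations, corrected
    accuracy, and the 3-SD-trimmed mean RT of correct responses."""
    viol = np.array([t.attended_violation for t in trials])
    corr = np.array([t.correct for t in trials])
    rts = np.array([t.rt_ms for t in trials])
    # hit: responded "violation" when violated == correct response on a violation trial
    hits = corr[viol].mean() if viol.any() else 1.0
    fas = (~corr[~viol]).mean() if (~viol).any() else 0.0
    kept, n_excl = filter_response_times(rts, corr)
    return BehaviorSummary(
        hit_rate=float(hits),
        false_alarm_rate=float(fas),
        corrected_accuracy=corrected_accuracy(float(hits), float(fas)),
        mean_rt_ms=float(kept.mean()) if kept.size else float("nan"),
        n_excluded_rts=n_excl,
    )


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """One row per trial; symbol lists serialized as compact strings."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "task": [t.task for t in trials],
            "modality": [t.attended_modality for t in trials],
            "nback": [t.nback for t in trials],
            "n_items": [t.n_items for t in trials],
            "items_v": ["".join(map(str, t.items_visual)) for t in trials],
            "items_a": ["".join(map(str, t.items_auditory)) for t in trials],
            "viol_v": [t.violation_visual for t in trials],
            "viol_a": [t.violation_auditory for t in trials],
            "correct": [t.correct for t in trials],
            "rt_ms": [t.rt_ms for t in trials],
            "phase_delay": [t.phase_delay for t in trials],
        }
    )
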