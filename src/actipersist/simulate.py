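"""Synthetic actigraphy cohorts with controllable group structure.

Minute-level activity counts are generated as a rounded, truncated-at-zero
sum of three ingredients:

* a circadian baseline — a clipped sinusoid with a 24 h (1440 min) period,
  raised to a power so night troughs sit near zero and daytime activity is
  a broad hump;
* randomly timed activity bouts — Poisson-started episodes (errands,
  exercise) whose start probability follows the circadian profile, each
  with a geometric duration and exponential amplitude;
* additive Gaussian minute noise, larger during the day than at night.

Group structure follows the observation that activity profiles vary more
between subjects who fail to maintain weight loss than between subjects
who succeed: every "success" subject uses the cohort's base parameters
exactly, while each "failure" subject multiplies its amplitude, bout rate
and bout amplitude by independent log-normal factors with log-scale
``heterogeneity_delta`` (and jitters its circadian phase proportionally).
``heterogeneity_delta = 0`` therefore makes the two groups statistically
identical — the null configuration for calibration checks.

Default scales are anchored to a real weight-management cohort's armband
summaries: mean minute counts near 290 with a standard deviation of a few
hundred.  All randomness flows from one integer seed through spawned
generators; nothing touches global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cohort import (
    FAILURE,
    INDETERMINATE,
    SUCCESS,
    ParticipantRecord,
    assign_outcome_label,
)
from .signal import Signal

__all__ = [
    "CohortSpec",
    "SubjectParams",
    "generate_signal",
    "generate_cohort",
    "generate_weight_trajectories",
]

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generator parameters.

    n_success, n_failure : group sizes (the reference cohort is 21 / 79).
    signal_length : samples per subject, minutes (default 7000, ~4.9 days).
    circadian_amplitude : peak of the daytime baseline, counts/min.
    bout_rate : bout starts per minute at circadian peak.
    bout_duration : mean bout length, minutes (geometric).
    bout_amplitude : mean extra counts/min during a bout (exponential).
    noise_scale : SD of the additive minute noise at circadian peak.
    heterogeneity_delta : log-scale SD of the failure group's per-subject
        parameter factors; 0 makes both groups draw identical parameters.
    seed : root seed for all randomness.
    """

    n_success: int = 21
    n_failure: int = 79
    signal_length: int = 7000
    circadian_amplitude: float = 650.0
    bout_rate: float = 0.045
    bout_duration: float = 15.0
    bout_amplitude: float = 300.0
    noise_scale: float = 90.0
    heterogeneity_delta: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_success < 0 or self.n_failure < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.signal_length < 0:
            raise ValueError("signal_length must be nonnegative")
        for name in (
            "circadian_amplitude",
            "bout_rate",
            "bout_duration",
            "bout_amplitude",
            "noise_scale",
            "heterogeneity_delta",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject realisation of the generator parameters."""

    circadian_amplitude: float
    bout_rate: float
    bout_duration: float
    bout_amplitude: float
    noise_scale: float
    phase_minutes: float = 0.0


def _base_params(spec: CohortSpec) -> SubjectParams:
    return SubjectParams(
        circadian_amplitude=spec.circadian_amplitude,
        bout_rate=spec.bout_rate,
        bout_duration=spec.bout_duration,
        bout_amplitude=spec.bout_amplitude,
        noise_scale=spec.noise_scale,
    )


def _heterogeneous_params(
    spec: CohortSpec, rng: np.random.Generator
) -> SubjectParams:
    """Failure-group subject parameters: base values with log-normal spread."""
    d = spec.heterogeneity_delta
    factors = np.exp(rng.normal(0.0, d, size=3))
    return SubjectParams(
        circadian_amplitude=spec.circadian_amplitude * factors[0],
        bout_rate=spec.bout_rate * factors[1],
        bout_duration=spec.bout_duration,
        bout_amplitude=spec.bout_amplitude * factors[2],
        noise_scale=spec.noise_scale,
        phase_minutes=float(rng.normal(0.0, d * 120.0)),
    )


def _circadian_profile(length: int, phase_minutes: float) -> np.ndarray:
    """Clipped-sinusoid day/night profile in [0, 1], near-zero at night."""
    t = np.arange(1, length + 1, dtype=float)
    s = np.sin(2.0 * np.pi * (t - phase_minutes) / MINUTES_PER_DAY)
    return np.clip(s, 0.0, None) ** 1.5


def generate_signal(
    length: int, params: SubjectParams, rng: np.random.Generator
) -> np.ndarray:
    """One subject's minute counts: nonnegative integers of the given length."""
    if length == 0:
        return np.zeros(0, dtype=float)
    c = _circadian_profile(length, params.phase_minutes)
    intensity = params.circadian_amplitude * c

    # Poisson bout starts modulated by the circadian profile
    start_prob = np.clip(params.bout_rate * c, 0.0, 1.0)
    starts = np.flatnonzero(rng.random(length) < start_prob)
    bouts = np.zeros(length, dtype=float)
    if starts.size and params.bout_duration > 0:
        durations = rng.geometric(1.0 / params.bout_duration, size=starts.size)
        amplitudes = rng.exponential(params.bout_amplitude, size=starts.size)
        for s, dur, amp in zip(starts, durations, amplitudes):
            bouts[s : s + dur] += amp

    noise_sd = params.noise_scale * (0.15 + 0.85 * c)
    noise = rng.normal(0.0, 1.0, size=length) * noise_sd
    counts = np.rint(np.clip(intensity + bouts + noise, 0.0, None))
    return counts


def generate_weight_trajectories(
    labels: Sequence[str], seed: int = 0
) -> List[Tuple[float, float, Optional[float]]]:
    """Phase weights (w1, w2, w3) consistent with the requested labels.

    The outcome rule applied to each returned triple reproduces the
    requested label exactly.  Failures split between the two failure
    modes: insufficient Phase-2 loss (w2 above 85% of start, w3 absent
    half the time) and failed Phase-3 maintenance (w3 above 90% of
    start despite a successful Phase 2).
    """
    rng = np.random.default_rng(seed)
    out: List[Tuple[float, float, Optional[float]]] = []
    for label in labels:
        w1 = float(np.clip(rng.normal(110.0, 15.0), 60.0, 200.0))
        if label == SUCCESS:
            w2 = w1 * float(rng.uniform(0.70, 0.85))
            w3 = w1 * float(rng.uniform(0.78, 0.90))
        elif label == FAILURE:
            if rng.random() < 0.5:  # never reached the Phase-2 target
                w2 = w1 * float(rng.uniform(0.86, 1.00))
                w3 = w1 * float(rng.uniform(0.88, 1.05)) if rng.random() < 0.5 else None
            else:  # lost the weight, then regained past the 90% line
                w2 = w1 * float(rng.uniform(0.70, 0.85))
                w3 = w1 * float(rng.uniform(0.905, 1.05))
        elif label == INDETERMINATE:
            w2 = w1 * float(rng.uniform(0.70, 0.85))
            w3 = None
        else:
            raise ValueError(f"unknown label {label!r}")
        assert assign_outcome_label(w1, w2, w3) == label
        out.append((w1, w2, w3))
    return out


def generate_cohort(spec: CohortSpec) -> List[ParticipantRecord]:
    """Labeled synthetic cohort: failures first, then successes.

    Participant ids are "F001..", "S001.."; each subject's parameters and
    signal derive from an independent spawn of the root seed, so the
    cohort is reproducible and signals are mutually independent.
    """
    n_total = spec.n_failure + spec.n_success
    seeds = np.random.SeedSequence(spec.seed).spawn(n_total)
    records: List[ParticipantRecord] = []
    for k in range(n_total):
        rng = np.random.default_rng(seeds[k])
        if k < spec.n_failure:
            label = FAILURE
            pid = f"F{k + 1:03d}"
            params = _heterogeneous_params(spec, rng)
        else:
            label = SUCCESS
            pid = f"S{k - spec.n_failure + 1:03d}"
            params = _base_params(spec)
        values = generate_signal(spec.signal_length, params, rng)
        records.append(
            ParticipantRecord(
                participant_id=pid,
                signal=Signal(values, participant_id=pid),
                label=label,
            )
        )
    return records
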