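"""Conventional whole-signal features used as comparison baselines.

Power, histogram entropy and mean are per-signal features; the Pearson
correlation coefficient compares two signals sample-by-sample.  These are
the standard actigraphy summaries that the windowed-persistence pipeline
is benchmarked against.

Conventions (the literature leaves both underspecified):
power is the mean squared amplitude (average per-sample energy), and
entropy is the Shannon entropy of an equal-width value histogram,
normalised by log(bins) so it lands in [0, 1].  Both choices are isolated
here so an alternative convention is a one-line change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .signal import Signal

__all__ = [
    "FeatureRow",
    "signal_power",
    "signal_entropy",
    "signal_mean",
    "pearson_correlation",
    "feature_row",
]

DEFAULT_ENTROPY_BINS = 16


@dataclass(frozen=True)
class FeatureRow:
    participant_id: Optional[str]
    power: float
    entropy: float
    mean: float


def signal_power(signal: Signal) -> float:
    """Mean squared amplitude: (1/n) sum f(i)^2."""
    if len(signal) == 0:
        raise ValueError("power of an empty signal is undefined")
    return float(np.mean(signal.values**2))


def signal_entropy(signal: Signal, bins: int = DEFAULT_ENTROPY_BINS) -> float:
    """Normalised Shannon entropy of the value histogram, in [0, 1].

    Equal-width bins over [min, max]; entropy is divided by log(bins) so
    a uniform occupancy scores 1 and a constant signal scores 0.
    """
    if len(signal) == 0:
        raise ValueError("entropy of an empty signal is undefined")
    if bins < 2:
        raise ValueError(f"need at least 2 bins, got {bins}")
    values = signal.values
    if np.min(values) == np.max(values):
        return 0.0
    counts, _ = np.histogram(values, bins=bins)
    h = stats.entropy(counts)  # natural log, ignores empty bins
    return float(h / np.log(bins))


def signal_mean(signal: Signal) -> float:
    """Arithmetic mean of the samples."""
    if len(signal) == 0:
        raise ValueError("mean of an empty signal is undefined")
    return float(np.mean(signal.values))


def pearson_correlation(a: Signal, b: Signal) -> float:
    """Sample Pearson correlation between two equal-length signals."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 2:
        raise ValueError("correlation requires at least 2 samples")
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        raise ValueError("correlation with a constant signal is undefined")
    return float(stats.pearsonr(a.values, b.values).statistic)


def feature_row(signal: Signal, bins: int = DEFAULT_ENTROPY_BINS) -> FeatureRow:
    """Power, entropy and mean of one signal, bundled."""
    return FeatureRow(
        participant_id=signal.participant_id,
        power=signal_power(signal),
        entropy=signal_entropy(signal, bins=bins),
        mean=signal_mean(signal),
    )
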