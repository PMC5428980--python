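"""Cohort-level pipeline: outcome labels, pair strata, and group tests.

Participants carry a binary weight-maintenance outcome ("success" /
"failure") derived from their weight trajectory.  Every unordered pair of
participants is compared (windowed-persistence mean distance, or Pearson
correlation as a baseline) and the pair value is stratified by the labels
of its two members: failure-failure (FF), failure-success (FS),
success-success (SS).  Group means are contrasted with unpaired two-sample
t-tests, and a random-label control reruns the tests under label
permutations that preserve the class sizes.

Caveat, by design: pair values sharing a participant are statistically
dependent, yet the t-test treats them as independent observations.  That
replicates the procedure this pipeline implements; the random-label
control is the empirical check on the resulting significance levels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .baselines import pearson_correlation
from .distances import DistanceConfig, distance_signal, mean_distance
from .signal import Signal
from .windowing import DiagramSequence, WindowConfig, windowed_diagrams

__all__ = [
    "SUCCESS",
    "FAILURE",
    "INDETERMINATE",
    "GROUPS",
    "GROUP_PAIRINGS",
    "ParticipantRecord",
    "PairComparison",
    "GroupSummary",
    "TTestResult",
    "assign_outcome_label",
    "pair_groups",
    "pairwise_cohort_analysis",
    "group_summary",
    "unpaired_ttest",
    "group_ttests",
    "random_label_control",
]

logger = logging.getLogger(__name__)

SUCCESS = "success"
FAILURE = "failure"
INDETERMINATE = "indeterminate"

GROUPS = ("FF", "FS", "SS")
GROUP_PAIRINGS = (("FF", "SS"), ("FF", "FS"), ("FS", "SS"))

# outcome thresholds, as fractions of starting weight
PHASE2_LOSS_FRACTION = 0.15  # must lose >= 15% by the end of intensive phase
PHASE3_MAINTAIN_FRACTION = 0.10  # must hold >= 10% loss at study end


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    signal: Signal
    label: str

    def __post_init__(self) -> None:
        if self.label not in (SUCCESS, FAILURE, INDETERMINATE):
            raise ValueError(f"unknown outcome label {self.label!r}")


@dataclass(frozen=True)
class PairComparison:
    """One unordered participant pair with its stratum and scalar value."""

    id_a: str
    id_b: str
    group: str
    value: float


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: Optional[float]  # sample (n-1) SD; None when n < 2


@dataclass(frozen=True)
class TTestResult:
    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    variant: str = "student"


def assign_outcome_label(
    w1: float, w2: float, w3: Optional[float] = None
) -> str:
    """Weight-maintenance outcome from phase weights (kg).

    failure: lost < 15% of starting weight by Phase 2, or finished Phase 3
    above 90% of starting weight (i.e. did not maintain a 10% loss).
    success: lost >= 15% by Phase 2 and finished Phase 3 at <= 90% of
    starting weight.  A participant who achieved the Phase-2 loss but has
    no Phase-3 weight yet is indeterminate.
    """
    weights = [w for w in (w1, w2, w3) if w is not None]
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    if w2 > (1.0 - PHASE2_LOSS_FRACTION) * w1:
        return FAILURE
    if w3 is None:
        return INDETERMINATE
    if w3 > (1.0 - PHASE3_MAINTAIN_FRACTION) * w1:
        return FAILURE
    return SUCCESS


def _pair_group(label_a: str, label_b: str) -> str:
    n_fail = (label_a == FAILURE) + (label_b == FAILURE)
    return {2: "FF", 1: "FS", 0: "SS"}[n_fail]


def pair_groups(
    records: Sequence[ParticipantRecord],
) -> Tuple[List[Tuple[str, str, str]], Dict[str, int]]:
    """All unordered pairs of definite-label participants, stratified.

    Returns (pairs, counts): pairs as (id_a, id_b, group) triples, each
    unordered pair once; counts per group, summing to n(n-1)/2 over the
    n definite-label records.  Indeterminate records are excluded with a
    logged warning.
    """
    definite = [r for r in records if r.label != INDETERMINATE]
    dropped = len(records) - len(definite)
    if dropped:
        logger.warning(
            "excluding %d participant(s) with indeterminate outcome", dropped
        )
    if len(definite) < 2:
        raise ValueError("need at least 2 participants with definite labels")
    pairs = [
        (a.participant_id, b.participant_id, _pair_group(a.label, b.label))
        for a, b in itertools.combinations(definite, 2)
    ]
    counts = {g: 0 for g in GROUPS}
    for _, _, g in pairs:
        counts[g] += 1
    return pairs, counts


def _diagram_sequences(
    records: Sequence[ParticipantRecord], window_config: WindowConfig
) -> Dict[str, DiagramSequence]:
    return {
        r.participant_id: windowed_diagrams(r.signal, window_config)
        for r in records
    }


def pairwise_cohort_analysis(
    records: Sequence[ParticipantRecord],
    method: str = "windowed_ph",
    distance_config: DistanceConfig = DistanceConfig(),
    window_config: WindowConfig = WindowConfig(),
) -> List[PairComparison]:
    """Scalar comparison value for every unordered participant pair.

    method "windowed_ph": each signal is windowed, one persistence diagram
    per window; a pair's value is the mean of the per-window diagram
    distances.  method "correlation": the pair's value is the Pearson
    correlation of the two raw signals.  Deterministic; diagram sequences
    are computed once per participant.
    """
    if method not in ("windowed_ph", "correlation"):
        raise ValueError(f"unknown method {method!r}")
    definite = [r for r in records if r.label != INDETERMINATE]
    pairs, _ = pair_groups(records)
    by_id = {r.participant_id: r for r in definite}
    lengths = {len(r.signal) for r in definite}
    if len(lengths) > 1:
        raise ValueError(
            f"signals must share one length after inclusion/cropping, got {sorted(lengths)}"
        )
    if method == "windowed_ph":
        seqs = _diagram_sequences(definite, window_config)
        return [
            PairComparison(
                id_a,
                id_b,
                group,
                mean_distance(
                    distance_signal(seqs[id_a], seqs[id_b], distance_config)
                ),
            )
            for id_a, id_b, group in pairs
        ]
    return [
        PairComparison(
            id_a,
            id_b,
            group,
            pearson_correlation(by_id[id_a].signal, by_id[id_b].signal),
        )
        for id_a, id_b, group in pairs
    ]


def group_summary(pairs: Sequence[PairComparison]) -> Dict[str, GroupSummary]:
    """Unweighted mean and sample SD of pair values, per present stratum."""
    out: Dict[str, GroupSummary] = {}
    for g in GROUPS:
        vals = np.array([p.value for p in pairs if p.group == g], dtype=float)
        if vals.size == 0:
            continue  # absent group is reported as absent, not as zero
        sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else None
        out[g] = GroupSummary(group=g, n=int(vals.size), mean=float(np.mean(vals)), sd=sd)
    return out


def unpaired_ttest(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "student",
    group_a: str = "x",
    group_b: str = "y",
) -> TTestResult:
    """Two-sample t-test on two groups of pair values.

    "student" pools the variances (the classical unpaired t-test);
    "welch" drops the equal-variance assumption.  Two-sided p-value.
    Degenerate zero-variance input with equal means yields t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        df = float(x.size + y.size - 2)
        return TTestResult(group_a, group_b, 0.0, df, 1.0, variant)
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return TTestResult(
        group_a=group_a,
        group_b=group_b,
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        variant=variant,
    )


def group_ttests(
    pairs: Sequence[PairComparison], variant: str = "student"
) -> Dict[str, TTestResult]:
    """T-tests for every pairing of present strata (FF vs SS, etc.)."""
    values = {
        g: [p.value for p in pairs if p.group == g] for g in GROUPS
    }
    out: Dict[str, TTestResult] = {}
    for ga, gb in GROUP_PAIRINGS:
        if len(values[ga]) >= 2 and len(values[gb]) >= 2:
            out[f"{ga}_vs_{gb}"] = unpaired_ttest(
                values[ga], values[gb], variant=variant, group_a=ga, group_b=gb
            )
    return out


def random_label_control(
    records: Sequence[ParticipantRecord],
    n_trials: int = 100,
    seed: int = 0,
    method: str = "windowed_ph",
    distance_config: DistanceConfig = DistanceConfig(),
    window_config: WindowConfig = WindowConfig(),
    variant: str = "student",
    preserve_class_sizes: bool = True,
) -> Dict[str, float]:
    """Mean p-value per group pairing under random label reassignment.

    Pairwise comparison values do not depend on the labels, so they are
    computed once; each trial redraws the labels (a uniform permutation
    preserving the observed class sizes by default, or an independent
    fair relabeling otherwise), restratifies the pairs and reruns the
    t-tests.  Reproducible for a given seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    base_pairs = pairwise_cohort_analysis(
        records, method=method, distance_config=distance_config,
        window_config=window_config,
    )
    definite = [r for r in records if r.label != INDETERMINATE]
    ids = [r.participant_id for r in definite]
    orig_labels = [r.label for r in definite]
    value_of = {(p.id_a, p.id_b): p.value for p in base_pairs}
    p_sums: Dict[str, float] = {}
    p_counts: Dict[str, int] = {}
    for _ in range(n_trials):
        if preserve_class_sizes:
            labels = list(orig_labels)
            rng.shuffle(labels)
        else:
            labels = [
                FAILURE if rng.random() < 0.5 else SUCCESS for _ in ids
            ]
        lab = dict(zip(ids, labels))
        trial_pairs = [
            PairComparison(a, b, _pair_group(lab[a], lab[b]), value_of[(a, b)])
            for a, b, _ in ((p.id_a, p.id_b, p.group) for p in base_pairs)
        ]
        for name, res in group_ttests(trial_pairs, variant=variant).items():
            p_sums[name] = p_sums.get(name, 0.0) + res.p
            p_counts[name] = p_counts.get(name, 0) + 1
    return {name: p_sums[name] / p_counts[name] for name in p_sums}
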