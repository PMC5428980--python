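"""Outcome labeling, pair strata, group summaries, t-tests, blind control."""

import numpy as np
import pytest

from actipersist import (
    FAILURE,
    INDETERMINATE,
    SUCCESS,
    CohortSpec,
    DistanceConfig,
    ParticipantRecord,
    Signal,
    WindowConfig,
    assign_outcome_label,
    generate_cohort,
    group_summary,
    group_ttests,
    pair_groups,
    pairwise_cohort_analysis,
    random_label_control,
    unpaired_ttest,
)


def make_records(labels, length=40, seed=0):
    rng = np.random.default_rng(seed)
    return [
        ParticipantRecord(
            f"P{k}", Signal(rng.integers(0, 50, size=length).astype(float), participant_id=f"P{k}"), lab
        )
        for k, lab in enumerate(labels)
    ]


class TestOutcomeLabel:
    @pytest.mark.parametrize(
        "w1, w2, w3, expected",
        [
            (100, 84, 88, SUCCESS),  # 16% loss held below the 90% line
            (100, 90, None, FAILURE),  # under 15% loss at Phase 2
            (100, 80, 92, FAILURE),  # regained past 90% of start
            (100, 84, None, INDETERMINATE),  # Phase 3 not reached yet
            (100, 85, 90, SUCCESS),  # thresholds are inclusive
            (100, 85.01, 90, FAILURE),
            (100, 85, 90.01, FAILURE),
        ],
    )
    def test_rule(self, w1, w2, w3, expected):
        assert assign_outcome_label(w1, w2, w3) == expected

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            assign_outcome_label(0, 50, None)
        with pytest.raises(ValueError):
            assign_outcome_label(100, -5, None)


class TestPairGroups:
    def test_reference_cohort_counts(self):
        records = make_records([FAILURE] * 79 + [SUCCESS] * 21, length=4)
        _, counts = pair_groups(records)
        assert counts == {"FF": 3081, "FS": 1659, "SS": 210}

    def test_small_example(self):
        _, counts = pair_groups(make_records([FAILURE, FAILURE, SUCCESS], length=4))
        assert counts == {"FF": 1, "FS": 2, "SS": 0}

    def test_total_is_n_choose_2(self, rng):
        for _ in range(10):
            labels = [
                FAILURE if rng.random() < 0.6 else SUCCESS
                for _ in range(int(rng.integers(2, 30)))
            ]
            _, counts = pair_groups(make_records(labels, length=4))
            n = len(labels)
            assert sum(counts.values()) == n * (n - 1) // 2

    def test_indeterminate_excluded(self):
        records = make_records([FAILURE, SUCCESS, INDETERMINATE, FAILURE], length=4)
        pairs, counts = pair_groups(records)
        assert sum(counts.values()) == 3  # 3 definite participants
        assert all("P2" not in (a, b) for a, b, _ in pairs)

    def test_too_few_definite_labels(self):
        with pytest.raises(ValueError):
            pair_groups(make_records([FAILURE, INDETERMINATE], length=4))


class TestPairwiseAnalysis:
    def test_row_count_and_determinism(self):
        records = make_records([FAILURE, FAILURE, SUCCESS], length=60)
        pairs1 = pairwise_cohort_analysis(records)
        pairs2 = pairwise_cohort_analysis(records)
        assert len(pairs1) == 3
        assert [(p.id_a, p.id_b, p.group, p.value) for p in pairs1] == [
            (p.id_a, p.id_b, p.group, p.value) for p in pairs2
        ]

    def test_identical_signals_give_zero_distances(self):
        sig = Signal(np.arange(60, dtype=float))
        records = [
            ParticipantRecord(f"P{k}", sig, FAILURE if k else SUCCESS)
            for k in range(3)
        ]
        pairs = pairwise_cohort_analysis(records)
        assert all(p.value == 0.0 for p in pairs)

    def test_correlation_method(self):
        records = make_records([FAILURE, SUCCESS], length=100)
        pairs = pairwise_cohort_analysis(records, method="correlation")
        assert len(pairs) == 1
        assert -1.0 <= pairs[0].value <= 1.0

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        records = [
            ParticipantRecord("A", Signal(rng.normal(size=40)), FAILURE),
            ParticipantRecord("B", Signal(rng.normal(size=60)), SUCCESS),
        ]
        with pytest.raises(ValueError):
            pairwise_cohort_analysis(records)


class TestGroupSummary:
    def test_mean_and_sample_sd(self):
        records = make_records([FAILURE] * 3, length=4)
        from actipersist import PairComparison

        pairs = [
            PairComparison("a", "b", "FF", 1.0),
            PairComparison("a", "c", "FF", 2.0),
            PairComparison("b", "c", "FF", 3.0),
        ]
        summary = group_summary(pairs)["FF"]
        assert summary.n == 3
        assert summary.mean == pytest.approx(2.0)
        assert summary.sd == pytest.approx(1.0)

    def test_single_pair_group_has_no_sd(self):
        from actipersist import PairComparison

        s = group_summary([PairComparison("a", "b", "SS", 5.0)])["SS"]
        assert s.n == 1 and s.sd is None

    def test_absent_group_is_absent(self):
        from actipersist import PairComparison

        out = group_summary([PairComparison("a", "b", "FF", 1.0)])
        assert "SS" not in out and "FS" not in out

    def test_permutation_invariant(self, rng):
        from actipersist import PairComparison

        pairs = [
            PairComparison(f"a{k}", f"b{k}", "FS", float(v))
            for k, v in enumerate(rng.normal(size=20))
        ]
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        a, b = group_summary(pairs)["FS"], group_summary(shuffled)["FS"]
        assert a.n == b.n
        assert a.mean == pytest.approx(b.mean)
        assert a.sd == pytest.approx(b.sd)


class TestTTest:
    def test_equal_groups_give_p_one(self):
        res = unpaired_ttest([1.0, 2, 3], [1.0, 2, 3])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_known_pooled_value(self):
        res = unpaired_ttest([1.0, 2, 3], [4.0, 5, 6])
        assert res.t == pytest.approx(-3.6742346, abs=1e-6)
        assert res.df == pytest.approx(4.0)
        assert res.p == pytest.approx(0.0213, abs=5e-4)

    def test_swap_negates_t_keeps_p(self, rng):
        x, y = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        a = unpaired_ttest(x, y)
        b = unpaired_ttest(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_zero_variance_equal_means_convention(self):
        res = unpaired_ttest([2.0, 2.0], [2.0, 2.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_welch_variant(self, rng):
        x = rng.normal(0, 1, size=10)
        y = rng.normal(0, 5, size=40)
        res = unpaired_ttest(x, y, variant="welch")
        assert res.variant == "welch"
        assert res.df != pytest.approx(48.0)  # Welch df is not n1+n2-2

    def test_validation(self):
        with pytest.raises(ValueError):
            unpaired_ttest([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            unpaired_ttest([1.0, 2], [3.0, 4], variant="median")


@pytest.fixture(scope="module")
def cohort():
    spec = CohortSpec(
        n_success=5, n_failure=7, signal_length=200, heterogeneity_delta=0.5,
        seed=11,
    )
    return generate_cohort(spec)


class TestRandomLabelControl:
    def test_reproducible_for_fixed_seed(self, cohort):
        kwargs = dict(n_trials=5, seed=3, window_config=WindowConfig(20))
        assert random_label_control(cohort, **kwargs) == random_label_control(
            cohort, **kwargs
        )

    def test_reports_mean_p_per_pairing(self, cohort):
        out = random_label_control(
            cohort, n_trials=4, seed=1, window_config=WindowConfig(20)
        )
        assert set(out) <= {"FF_vs_SS", "FF_vs_FS", "FS_vs_SS"}
        assert all(0.0 < p <= 1.0 for p in out.values())

    def test_class_sizes_preserved_distinct_from_free_relabeling(self, cohort):
        preserved = random_label_control(
            cohort, n_trials=3, seed=5, window_config=WindowConfig(20)
        )
        free = random_label_control(
            cohort, n_trials=3, seed=5, preserve_class_sizes=False,
            window_config=WindowConfig(20),
        )
        assert preserved != free


def test_group_ttests_runs_all_present_pairings():
    spec = CohortSpec(n_success=4, n_failure=5, signal_length=100, seed=2)
    pairs = pairwise_cohort_analysis(generate_cohort(spec))
    tests = group_ttests(pairs)
    assert set(tests) == {"FF_vs_SS", "FF_vs_FS", "FS_vs_SS"}
    for res in tests.values():
        assert 0.0 < res.p <= 1.0
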