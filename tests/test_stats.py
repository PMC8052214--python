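"""Wilcoxon signed-rank, descriptives, SUS scoring and the cohort report."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

import vnsim
from vnsim.stats import (
    Descriptives,
    SUSResponse,
    cohort_report,
    describe,
    sus_score,
    wilcoxon_signed_rank,
)


def brute_force_two_tailed_p(diffs):
    """Independent oracle: doubling rule over all 2^n sign assignments (itertools)."""
    d = [x for x in diffs if x != 0]
    ranks = rankdata([abs(x) for x in d])
    w_plus = sum(r for r, x in zip(ranks, d) if x > 0)
    n = len(d)
    le = ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        t = sum(r for r, s in zip(ranks, signs) if s)
        le += t <= w_plus + 1e-9
        ge += t >= w_plus - 1e-9
    total = 2**n
    return min(1.0, 2.0 * min(le / total, ge / total))


class TestWilcoxon:
    def test_five_concordant_pairs(self):
        pairs = np.array([[3, 1], [4, 2], [5, 1], [6, 3], [7, 2]], dtype=float)
        res = wilcoxon_signed_rank(pairs)
        assert res.method == "exact"
        assert res.p_two_tailed == pytest.approx(0.0625)  # 2 * 1/2^5
        assert res.n_effective == 5
        assert res.significant  # 0.0625 < 0.1

    def test_all_zero_differences_degenerate(self):
        pairs = np.array([[2.0, 2.0]] * 6)
        res = wilcoxon_signed_rank(pairs)
        assert res.method == "degenerate"
        assert res.p_two_tailed == 1.0
        assert not res.significant

    @pytest.mark.parametrize("n", [3, 5, 8, 10, 12])
    def test_exact_p_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for rep in range(8):
            d = np.round(rng.normal(size=n), 1)  # rounding induces ties
            d[d == 0] = 0.1
            res = wilcoxon_signed_rank(np.column_stack([d, np.zeros(n)]))
            assert res.method == "exact"
            assert res.p_two_tailed == pytest.approx(brute_force_two_tailed_p(d))

    def test_exact_p_matches_scipy_without_ties(self):
        rng = np.random.default_rng(0)
        for n in (6, 9, 12):
            d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d)
            ref = scipy_wilcoxon(d, mode="exact", alternative="two-sided")
            assert res.p_two_tailed == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_scipy_above_cutoff(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.4, 1.0, size=20)
        res = wilcoxon_signed_rank(d)
        assert res.method == "normal_approx"
        ref = scipy_wilcoxon(d, mode="approx", correction=True,
                             alternative="two-sided")
        assert res.p_two_tailed == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invariant_under_subject_relabelling_and_scaling(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=10)
        p0 = wilcoxon_signed_rank(d).p_two_tailed
        perm = rng.permutation(d)
        assert wilcoxon_signed_rank(perm).p_two_tailed == pytest.approx(p0)
        assert wilcoxon_signed_rank(3.7 * d).p_two_tailed == pytest.approx(p0)

    def test_zeros_dropped_before_ranking(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -0.5, 3.0, 1.5])
        res = wilcoxon_signed_rank(d)
        assert res.n_effective == 5
        assert res.p_two_tailed == pytest.approx(brute_force_two_tailed_p(d))

    def test_pratt_option_keeps_zero_ranks_out_of_sums(self):
        d = np.array([0.0, 1.0, -2.0, 3.0])
        res = wilcoxon_signed_rank(d, zero_method="pratt")
        # zero takes rank 1; ranks of nonzeros become 2,3,4
        assert res.n_effective == 3
        assert res.w_statistic == pytest.approx(3.0)  # min(2+4, 3)

    def test_single_pair_underpowered(self):
        res = wilcoxon_signed_rank(np.array([[2.0, 1.0]]))
        assert res.underpowered
        assert res.p_two_tailed == 1.0  # 2 * 1/2, capped


class TestDescribe:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3, 4, 5], (3, 2, 4)),
        ([7], (7, 7, 7)),
        ([2, 4], (3, 2.5, 3.5)),
    ])
    def test_linear_interpolation_examples(self, values, expected):
        d = describe(values)
        assert (d.median, d.q1, d.q3) == pytest.approx(expected)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = describe(rng.normal(size=rng.integers(1, 30)))
            assert d.q1 <= d.median <= d.q3

    def test_permutation_invariant_and_affine_equivariant(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=11)
        d0 = describe(x)
        dp = describe(rng.permutation(x))
        assert (dp.median, dp.q1, dp.q3) == pytest.approx((d0.median, d0.q1, d0.q3))
        da = describe(2.0 * x + 5.0)
        assert da.median == pytest.approx(2 * d0.median + 5)
        assert da.q1 == pytest.approx(2 * d0.q1 + 5)
        assert da.q3 == pytest.approx(2 * d0.q3 + 5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            describe([])


class TestSUS:
    def test_neutral_response_scores_50(self):
        assert sus_score([3] * 10) == pytest.approx(50.0)

    def test_extremes_attain_bounds(self):
        best = [5 if i % 2 == 0 else 1 for i in range(10)]  # odd positions 5, even 1
        worst = [1 if i % 2 == 0 else 5 for i in range(10)]
        assert sus_score(best) == pytest.approx(100.0)
        assert sus_score(worst) == pytest.approx(0.0)

    def test_affine_in_each_item(self):
        base = [3] * 10
        for pos in range(10):
            items = list(base)
            items[pos] = 4
            delta = sus_score(items) - 50.0
            # +1 rating moves the score by +2.5 on odd positions, -2.5 on even
            assert delta == pytest.approx(2.5 if pos % 2 == 0 else -2.5)

    def test_validation(self):
        with pytest.raises(ValueError):
            sus_score([3] * 9)
        with pytest.raises(ValueError):
            SUSResponse(tuple([3] * 9 + [6]))


def _metrics_for(pairs_by_subject, group="student", platform="OH", start=0):
    rows = []
    for s, (a, b) in enumerate(pairs_by_subject, start=start):
        for attempt, dur in (("A", a), ("B", b)):
            rows.append(vnsim.InsertionMetrics(
                insertion_angle=45.0, relative_error=0.0, duration=dur,
                n_forbidden_contacts=0, n_wrong_orientation=0,
                subject=f"S{s:02d}", group=group, platform=platform, attempt=attempt,
            ))
    return rows


class TestCohortReport:
    def test_constructed_learning_effect_is_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(80, 5, size=50)
        pairs = np.column_stack([a, a * 0.5 + rng.normal(0, 1, 50)])
        rep = cohort_report(_metrics_for(pairs), grouping="all")
        entry = rep.cells[("all", "all")]["duration"]
        assert entry["test"].significant
        assert entry["B"].median < entry["A"].median

    def test_single_subject_flagged_underpowered(self):
        rep = cohort_report(_metrics_for([(70.0, 60.0)]), grouping="all")
        test = rep.cells[("all", "all")]["duration"]["test"]
        assert test.underpowered
        assert not test.significant

    def test_unpaired_subject_excluded(self):
        rows = _metrics_for([(70.0, 60.0), (80.0, 65.0), (75.0, 62.0),
                             (72.0, 61.0), (78.0, 64.0)])
        rows = [r for r in rows if not (r.subject == "S04" and r.attempt == "B")]
        rep = cohort_report(rows, grouping="all")
        assert rep.excluded_subjects == ["S04"]
        assert rep.cells[("all", "all")]["duration"]["test"].n_effective == 4

    def test_merged_grouping_pools_groups(self):
        rows = (_metrics_for([(70, 60), (75, 61), (72, 62)], group="experienced")
                + _metrics_for([(90, 70), (85, 72), (88, 69)], group="student",
                               start=3))
        rep = cohort_report(rows, grouping="merged")
        assert list(rep.cells) == [("all", "OH")]
        assert rep.cells[("all", "OH")]["duration"]["test"].n_effective == 6

    def test_improvement_deltas_reported_per_subject(self):
        rows = _metrics_for([(70.0, 60.0), (80.0, 65.0), (75.0, 62.0)])
        rep = cohort_report(rows, grouping="all")
        imp = rep.cells[("all", "all")]["duration"]["improvement"]
        assert imp.median == pytest.approx(np.median([10.0, 15.0, 13.0]))

    def test_summary_renders_table2_layout(self):
        rows = _metrics_for([(70.0, 60.0), (80.0, 65.0), (75.0, 62.0),
                             (72.0, 61.0), (78.0, 64.0)])
        rep = cohort_report(rows, grouping="by_group")
        text = rep.summary()
        assert "student/OH" in text
        assert "duration" in text and "Attempt A" in text and "Attempt B" in text

    def test_report_serialises_to_dict(self):
        rows = _metrics_for([(70.0, 60.0), (80.0, 65.0)])
        doc = cohort_report(rows, grouping="all").as_dict()
        cell = doc["cells"]["all/all"]["duration"]
        assert {"A", "B", "improvement", "test"} <= set(cell)
        assert isinstance(Descriptives(**cell["A"]), Descriptives)
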