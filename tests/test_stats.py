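"""Cohort statistics against enumeration oracles and hand-computed values."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from plexiquant.stats import (
    anova_oneway_tukey,
    anova_suite,
    anova_twoway,
    apply_inclusion_and_recurrence,
    kruskal_dunn,
    mann_whitney,
    patient_level_means,
    spearman,
)


def _cohort_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "group",
            "ganglion_id",
            "n_tcells_apposed",
            "rutgeerts",
            "clinical_recurrence_18mo",
        ],
    )


def _subject(pid, group, n_ganglia, rutgeerts=None, clinical=None):
    return [
        (pid, group, g + 1, 0, rutgeerts, clinical) for g in range(n_ganglia)
    ]


class TestInclusionAndRecurrence:
    def test_subject_below_ten_ganglia_excluded(self):
        frame = _cohort_frame(
            _subject("A", "Crohn", 9, "i2") + _subject("B", "Crohn", 10, "i2")
        )
        out = apply_inclusion_and_recurrence(frame)
        assert set(out["patient_id"]) == {"B"}

    def test_rutgeerts_i2_without_clinical_is_recurrent(self):
        frame = _cohort_frame(_subject("A", "Crohn", 12, "i2", None))
        out = apply_inclusion_and_recurrence(frame)
        assert (out["recurrence_status"] == "recurrent").all()

    def test_i0_and_no_clinical_recurrence_is_non_recurrent(self):
        frame = _cohort_frame(_subject("A", "Crohn", 12, "i0", False))
        out = apply_inclusion_and_recurrence(frame)
        assert (out["recurrence_status"] == "non_recurrent").all()

    def test_clinical_recurrence_alone_is_recurrent(self):
        frame = _cohort_frame(_subject("A", "Crohn", 12, None, True))
        out = apply_inclusion_and_recurrence(frame)
        assert (out["recurrence_status"] == "recurrent").all()

    def test_no_assessment_is_lost_to_followup(self):
        frame = _cohort_frame(_subject("A", "Crohn", 12, None, None))
        out = apply_inclusion_and_recurrence(frame)
        assert (out["recurrence_status"] == "lost_to_followup").all()

    def test_control_subjects_keep_control_status(self):
        frame = _cohort_frame(_subject("C", "Ctrl", 12, None, None))
        out = apply_inclusion_and_recurrence(frame)
        assert (out["recurrence_status"] == "control").all()

    def test_unknown_rutgeerts_level_raises(self):
        frame = _cohort_frame(_subject("A", "Crohn", 12, "i9"))
        with pytest.raises(ValueError, match="i9"):
            apply_inclusion_and_recurrence(frame)


class TestMannWhitney:
    def test_exact_small_case(self):
        # all C(4,2)=6 rank splits: U=0 has probability 1/6, two-sided 1/3
        report = mann_whitney([1, 2], [3, 4])
        assert report.statistic == 0.0
        assert report.p_value == pytest.approx(1 / 3, abs=1e-10)

    def test_identical_multisets_give_p_one(self):
        report = mann_whitney([1, 2, 3], [1, 2, 3])
        assert report.p_value == 1.0

    def test_enumeration_matches_scipy_exact_without_ties(self, rng):
        for _ in range(5):
            a = rng.permutation(20)[:4].astype(float)
            b = rng.permutation(40)[20:26].astype(float)
            if len(np.unique(np.concatenate([a, b]))) < len(a) + len(b):
                continue
            ours = mann_whitney(a, b).p_value
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_large_sample_uses_tie_corrected_normal_approximation(self, rng):
        a = rng.poisson(3, 30).astype(float)
        b = rng.poisson(3, 30).astype(float)
        report = mann_whitney(a, b)
        assert "normal" in report.test
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert report.p_value == pytest.approx(float(ref))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_invariant_under_within_group_reordering(self):
        a, b = [3.0, 1.0, 5.0], [2.0, 8.0]
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(list(reversed(a)), list(reversed(b)))
        assert r1.p_value == r2.p_value


class TestKruskalDunn:
    def test_identical_groups_h_zero_p_one(self):
        report = kruskal_dunn([[2, 2], [2, 2], [2, 2]])
        assert report.statistic == 0.0
        assert report.p_value == 1.0
        assert all(c.p_adjusted == 1.0 for c in report.pairwise)

    def test_hand_computed_h(self):
        # groups [1,2,3],[4,5,6],[7,8,9]: mean ranks 2,5,8 over N=9
        # H = 12/(9*10) * 3*((2-5)^2 + 0 + (8-5)^2) = 7.2
        report = kruskal_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert report.statistic == pytest.approx(7.2)
        assert report.p_value == pytest.approx(float(sps.chi2.sf(7.2, 2)))

    def test_adjusted_p_not_below_unadjusted(self, rng):
        groups = [rng.normal(size=8) for _ in range(4)]
        report = kruskal_dunn(groups)
        for comp in report.pairwise:
            assert comp.p_adjusted >= comp.p_unadjusted - 1e-15

    def test_dunn_z_matches_direct_formula_without_ties(self):
        groups = [[1.0, 4.0, 7.0], [2.0, 5.0, 8.0], [3.0, 6.0, 9.0]]
        report = kruskal_dunn(groups, names=["a", "b", "c"], adjust="none")
        pooled = np.concatenate(groups)
        ranks = sps.rankdata(pooled)
        mr = [ranks[i * 3 : (i + 1) * 3].mean() for i in range(3)]
        n = 9
        se = np.sqrt(n * (n + 1) / 12 * (1 / 3 + 1 / 3))
        for comp, (i, j) in zip(report.pairwise, itertools.combinations(range(3), 2)):
            assert comp.statistic == pytest.approx((mr[i] - mr[j]) / se)
            assert comp.p_adjusted == pytest.approx(
                2 * sps.norm.sf(abs(comp.statistic))
            )

    def test_label_permutation_leaves_null_invariant(self, rng):
        # permuting pooled values across groups leaves the H null calibrated
        rejections = 0
        reps = 400
        for _ in range(reps):
            pooled = rng.negative_binomial(1, 0.3, 24).astype(float)
            rng.shuffle(pooled)
            groups = [pooled[:8], pooled[8:16], pooled[16:]]
            if kruskal_dunn(groups).p_value < 0.05:
                rejections += 1
        assert rejections / reps < 0.1  # coarse calibration check

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn([[1.0], []])


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
        assert rho == pytest.approx(1.0)

    def test_reversed_order_is_minus_one(self):
        rho, _ = spearman([1, 2, 3, 4, 5], [160, 80, 40, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_full_permutation_oracle(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho, p = spearman(x, y)
        rx = sps.rankdata(x)
        count = 0
        for perm in itertools.permutations(sps.rankdata(y)):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 720)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_large_n_matches_scipy_t_approximation(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))


class TestAnova:
    def test_equal_means_f_near_zero(self):
        report = anova_oneway_tukey([[1, 2, 3], [2, 1, 3], [3, 2, 1]])
        assert report.statistic == pytest.approx(0.0)
        assert all(c.p_adjusted > 0.99 for c in report.pairwise)

    def test_two_group_f_equals_squared_t(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(1.0, size=12)
        f_report = anova_oneway_tukey([a, b])
        t = sps.ttest_ind(a, b)
        assert f_report.statistic == pytest.approx(float(t.statistic) ** 2)
        assert f_report.p_value == pytest.approx(float(t.pvalue))

    def test_hand_computed_sums_of_squares(self):
        # groups [1,2] and [5,6]: between-SS 16, within-SS 1, F = 16/(1/2) = 32
        report = anova_suite([[1, 2], [5, 6]], design="oneway_tukey")
        assert report.statistic == pytest.approx(32.0)

    def test_twoway_reports_three_effects(self, rng):
        rows = []
        for cond in ("ctrl", "lps"):
            for size_bin in ("small", "large"):
                shift = 2.0 if (cond == "lps" and size_bin == "large") else 0.0
                for _ in range(6):
                    rows.append(
                        {"freq": rng.normal(shift), "cond": cond, "bin": size_bin}
                    )
        table = pd.DataFrame(rows)
        report = anova_twoway(table, value="freq", factor_a="cond", factor_b="bin")
        assert set(report.effects) == {"cond", "bin", "interaction"}
        for f, p in report.effects.values():
            assert f >= 0 and 0 <= p <= 1

    def test_twoway_empty_cell_raises(self):
        table = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0],
                "a": ["x", "x", "y"],
                "b": ["u", "v", "u"],  # cell (y, v) empty
            }
        )
        with pytest.raises(ValueError, match="empty"):
            anova_twoway(table, value="y", factor_a="a", factor_b="b")


class TestPatientLevelMeans:
    def test_means_per_patient(self):
        frame = pd.DataFrame(
            {
                "patient_id": ["A", "A", "B", "B"],
                "group": ["g1", "g1", "g2", "g2"],
                "n_tcells_apposed": [1, 3, 0, 4],
            }
        )
        means = patient_level_means(frame)
        assert dict(zip(means["patient_id"], means["mean_n_tcells_apposed"])) == {
            "A": 2.0,
            "B": 2.0,
        }
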