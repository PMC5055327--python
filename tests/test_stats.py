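import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from t2texture import ValidationError, cohort_dataframe, roc_auc, two_sample_ttest


def pair_counting_auc(scores, labels):
    """Exhaustive oracle: (#concordant + 0.5 * #tied) / (n_pos * n_neg)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = conc = tied = 0
    for p in pos:
        for q in neg:
            total += 1
            conc += p > q
            tied += p == q
    return (conc + 0.5 * tied) / total


class TestTwoSampleTTest:
    def test_identical_groups(self):
        r = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_difference == 0.0
        assert r.p_two_sided == pytest.approx(1.0)

    def test_hand_computed_two_point_groups(self):
        # pooled variance 1, SE 1 => t = 0, p = 1
        r = two_sample_ttest([0.0, 2.0], [1.0, 1.0])
        assert r.mean_difference == 0.0
        assert r.t_statistic == 0.0
        assert r.degrees_of_freedom == 2
        assert r.p_two_sided == pytest.approx(1.0)

    def test_matches_scipy_student_t(self, rng):
        for _ in range(10):
            g1 = rng.normal(0, 1, size=rng.integers(2, 15))
            g2 = rng.normal(0.5, 2, size=rng.integers(2, 15))
            r = two_sample_ttest(g1, g2)
            ref = sps.ttest_ind(g1, g2, equal_var=True)
            assert r.t_statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert r.p_two_sided == pytest.approx(ref.pvalue, rel=1e-12)
            lo, hi = ref.confidence_interval(0.95)
            assert r.ci95 == pytest.approx((lo, hi), rel=1e-10)

    def test_ci_brackets_difference(self, rng):
        g1, g2 = rng.normal(2, 1, 8), rng.normal(0, 1, 5)
        r = two_sample_ttest(g1, g2)
        assert r.ci95[0] <= r.mean_difference <= r.ci95[1]

    def test_zero_variance_degenerate_cases(self):
        equal = two_sample_ttest([5.0, 5.0], [5.0, 5.0])
        assert equal.p_two_sided == 1.0 and equal.ci95 == (0.0, 0.0)
        apart = two_sample_ttest([5.0, 5.0], [3.0, 3.0])
        assert apart.mean_difference == 2.0
        assert apart.p_two_sided < 1e-100

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_ttest([1.0], [1.0, 2.0])


class TestROCAUC:
    def test_perfect_separation(self):
        r = roc_auc([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.significant

    def test_interleaved_scores(self):
        # positives {2, 4} vs negatives {1, 3}: 3 of 4 pairs concordant
        assert roc_auc([1.0, 3.0, 2.0, 4.0], [0, 0, 1, 1]).auc == 0.75

    def test_positive_high_flag_flips_orientation(self):
        scores, labels = [1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0]
        assert roc_auc(scores, labels).auc == 0.0
        assert roc_auc(scores, labels, positive_high=False).auc == 1.0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 8), st.booleans()), min_size=4, max_size=20
        ).filter(lambda d: 0 < sum(lab for _, lab in d) < len(d))
    )
    def test_midrank_auc_equals_pair_counting_oracle(self, data):
        scores = [float(s) for s, _ in data]
        labels = [lab for _, lab in data]
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)
        # score-reversal symmetry holds with midrank ties
        flipped = roc_auc([-s for s in scores], labels)
        assert r.auc + flipped.auc == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_strictly_increasing_transform(self, rng):
        scores = rng.integers(0, 10, size=30).astype(float)
        labels = rng.integers(0, 2, size=30).astype(bool)
        labels[:2] = [True, False]
        base = roc_auc(scores, labels)
        warped = roc_auc(np.expm1(scores / 3.0), labels)
        assert warped.auc == pytest.approx(base.auc, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40).astype(bool)
        labels[:2] = [True, False]
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_curve_spans_unit_square_and_integrates_to_auc(self, rng):
        scores = rng.integers(0, 6, size=25).astype(float)  # ties included
        labels = rng.integers(0, 2, size=25).astype(bool)
        labels[:2] = [True, False]
        r = roc_auc(scores, labels)
        fpr, tpr = r.curve[:, 0], r.curve[:, 1]
        assert (fpr[0], tpr[0]) == (0.0, 0.0)
        assert (fpr[-1], tpr[-1]) == (1.0, 1.0)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
        assert np.trapezoid(tpr, fpr) == pytest.approx(r.auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_delong_machinery_matches_r_proc(self, tmp_path):
        """Independent oracle: R pROC (DeLong) on the cohort entropy scores."""
        frame = cohort_dataframe()
        r = roc_auc(frame["entropy"], frame["heterogeneity_label"] == "hetero")
        table = tmp_path / "cohort.tsv"
        frame.to_csv(table, sep="\t", index=False)
        script = (
            "suppressMessages(library(pROC));"
            f"d <- read.delim('{table}');"
            "roc <- roc(d$heterogeneity_label == 'hetero', d$entropy,"
            "           direction='<', quiet=TRUE);"
            "ci <- ci.auc(roc, method='delong');"
            "cat(sprintf('%.12f %.12f %.12f', ci[1], ci[2], ci[3]))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        lo, auc, hi = (float(x) for x in out.stdout.split())
        assert r.auc == pytest.approx(auc, abs=1e-10)
        # pROC's DeLong CI uses the same variance; match the implied SE
        se_proc = (hi - auc) / sps.norm.ppf(0.975)
        assert r.se == pytest.approx(se_proc, rel=1e-6)
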