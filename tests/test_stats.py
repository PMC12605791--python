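import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

import hsdetect as h


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def cp_by_bisection(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Invert the exact binomial tails by bisection (independent of the
    beta-quantile route used by the implementation)."""
    alpha = 1 - conf

    def solve(f, lo, hi):
        for _ in range(80):
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if x == 0 else solve(
        lambda p: sps.binom.sf(x - 1, n, p) < alpha / 2, 0.0, 1.0)
    upper = 1.0 if x == n else 1.0 - solve(
        lambda q: sps.binom.cdf(x, n, 1 - q) < alpha / 2, 0.0, 1.0)
    return lower, upper


def mcnemar_by_enumeration(b: int, c: int) -> float:
    """Exact two-sided p by full enumeration of Binomial(b+c, 1/2) in
    rational arithmetic."""
    n = b + c
    if n == 0:
        return 1.0
    pmf = [Fraction(math.comb(n, k), 2 ** n) for k in range(n + 1)]
    m = min(b, c)
    tail = sum(pmf[: m + 1])
    return float(min(Fraction(1), 2 * tail))


# ---------------------------------------------------------------------------
# Clopper-Pearson
# ---------------------------------------------------------------------------

class TestClopperPearson:
    @pytest.mark.parametrize("x,n,lo,hi", [
        (59, 59, 0.939, 1.0),
        (21, 22, 0.772, 0.999),
        (71, 72, 0.925, 1.0),
        (80, 90, 0.805, 0.945),
        (137, 144, 0.902, 0.980),
        (70, 72, 0.903, 0.997),
    ])
    def test_reproduces_reported_intervals(self, x, n, lo, hi):
        lower, upper = h.clopper_pearson(x, n)
        assert round(lower, 3) == lo
        assert round(upper, 3) == hi

    def test_boundary_counts(self):
        assert h.clopper_pearson(0, 10)[0] == 0.0
        assert h.clopper_pearson(10, 10)[1] == 1.0

    def test_invalid_counts_rejected(self):
        for x, n in [(-1, 5), (6, 5), (0, 0)]:
            with pytest.raises(h.ValidationError):
                h.clopper_pearson(x, n)

    def test_matches_bisection_oracle(self):
        for n in (1, 2, 3, 5, 10, 22, 59, 90, 144, 200):
            for x in range(n + 1):
                lo, hi = h.clopper_pearson(x, n)
                olo, ohi = cp_by_bisection(x, n)
                assert lo == pytest.approx(olo, abs=1e-6)
                assert hi == pytest.approx(ohi, abs=1e-6)

    def test_matches_statsmodels_for_all_n_up_to_200(self):
        from statsmodels.stats.proportion import proportion_confint
        ks, ns = [], []
        for n in range(1, 201):
            ks.extend(range(n + 1))
            ns.extend([n] * (n + 1))
        ks, ns = np.array(ks), np.array(ns)
        lo, hi = proportion_confint(ks, ns, alpha=0.05, method="beta")
        lo = np.nan_to_num(lo, nan=0.0)
        hi = np.where(np.isnan(hi), 1.0, hi)
        ours = np.array([h.clopper_pearson(int(k), int(n)) for k, n in zip(ks, ns)])
        assert np.allclose(ours[:, 0], lo, atol=1e-12)
        assert np.allclose(ours[:, 1], hi, atol=1e-12)

    def test_interval_width_shrinks_with_n(self):
        widths = []
        for n in (10, 40, 160, 640):
            lo, hi = h.clopper_pearson(int(0.9 * n), n)
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)


# ---------------------------------------------------------------------------
# exact McNemar
# ---------------------------------------------------------------------------

class TestMcNemar:
    @pytest.mark.parametrize("b,c,p3", [
        # discordant splits forced by the reported paired accuracies:
        # 80 vs 73 of 90 correct fixes b-c = 7, and only c = 0 is
        # consistent with the reported p; likewise 137 vs 131 of 144.
        (7, 0, 0.016),
        (6, 0, 0.031),
    ])
    def test_reproduces_reported_pvalues(self, b, c, p3):
        assert round(h.mcnemar_exact(b, c), 3) == p3

    def test_no_discordance_gives_p_one(self):
        assert h.mcnemar_exact(0, 0) == 1.0

    def test_symmetric_and_capped(self):
        assert h.mcnemar_exact(3, 9) == h.mcnemar_exact(9, 3)
        assert h.mcnemar_exact(10, 10) == 1.0

    def test_matches_enumeration_oracle(self):
        for b in range(0, 21):
            for c in range(0, 21):
                assert h.mcnemar_exact(b, c) == pytest.approx(
                    mcnemar_by_enumeration(b, c), abs=1e-12)

    def test_matches_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        for b, c in [(7, 0), (6, 0), (5, 5), (12, 3), (0, 17), (100, 100),
                     (150, 50)]:
            table = [[0, b], [c, 0]]
            assert h.mcnemar_exact(b, c) == pytest.approx(
                sm_mcnemar(table, exact=True).pvalue, abs=1e-12)


# ---------------------------------------------------------------------------
# binary metrics
# ---------------------------------------------------------------------------

class TestBinaryMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 0, 1, 1, 1])
        m = h.binary_metrics(y, y, scores=y.astype(float))
        assert (m.accuracy, m.sensitivity, m.specificity, m.f1, m.roc_auc) \
            == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_all_negative_predictions(self):
        y_true = np.array([1] * 5 + [0] * 5)
        y_pred = np.zeros(10, dtype=int)
        m = h.binary_metrics(y_true, y_pred)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert m.accuracy == 0.5

    def test_auc_from_scores(self):
        y = np.array([0, 0, 1, 1])
        assert h.binary_metrics(y, y, y.astype(float)).roc_auc == 1.0
        assert h.binary_metrics(y, y, -y.astype(float)).roc_auc == 0.0

    def test_single_class_auc_flagged_none(self):
        y = np.ones(4, dtype=int)
        m = h.binary_metrics(y, y, scores=np.ones(4))
        assert m.roc_auc is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(h.ValidationError):
            h.binary_metrics(np.array([0, 1]), np.array([0]))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

class TestKfoldCv:
    def test_separable_cohort_perfect_accuracy(self, dataset_128):
        X, y, _ = dataset_128
        rep = h.kfold_cv(X, y, k=4, seed=0)
        assert rep.three_class_accuracy == 1.0
        assert rep.n_correct == rep.n_total == len(y)
        assert rep.three_class_ci == h.clopper_pearson(len(y), len(y))

    def test_folds_partition_and_pool(self, dataset_128):
        X, y, _ = dataset_128
        rep = h.kfold_cv(X, y, k=4, seed=1)
        assert sorted(set(rep.fold_assignments)) == [0, 1, 2, 3]
        assert len(rep.fold_assignments) == len(y)
        assert sum(rep.correct) == rep.n_correct
        # pooled counts equal the sum of per-fold corrects
        folds = np.asarray(rep.fold_assignments)
        per_fold = [int(np.sum(np.asarray(rep.correct)[folds == f]))
                    for f in range(4)]
        assert sum(per_fold) == rep.n_correct

    def test_same_seed_identical_report(self, dataset_128):
        X, y, _ = dataset_128
        r1 = h.kfold_cv(X, y, k=4, seed=9)
        r2 = h.kfold_cv(X, y, k=4, seed=9)
        assert r1.fold_assignments == r2.fold_assignments
        assert r1.predictions == r2.predictions
        assert r1.as_dict() == r2.as_dict()

    def test_shuffled_labels_near_chance(self, dataset_128, rng):
        X, y, _ = dataset_128
        perm = rng.permutation(len(y))
        y_null = [y[i] for i in perm]
        accs = [h.kfold_cv(X, y_null, k=4, seed=s).three_class_accuracy
                for s in range(3)]
        # majority class is 50%; binomial noise at n=24 is wide
        assert np.median(accs) < 0.85

    def test_k_exceeding_n_rejected(self, dataset_128):
        X, y, _ = dataset_128
        with pytest.raises(h.ValidationError):
            h.kfold_cv(X, y, k=len(y) + 1, seed=0)

    def test_report_table_renders(self, dataset_128):
        X, y, _ = dataset_128
        rep = h.kfold_cv(X, y, k=4, seed=0)
        table = rep.to_table()
        assert "Accuracy (3-class)" in table
        assert "Recall (Sens)" in table and "Recall (Spec)" in table


# ---------------------------------------------------------------------------
# external evaluation and paired comparison
# ---------------------------------------------------------------------------

class TestExternalEvaluation:
    def test_external_cohort_within_training_ci(self, small_config, norm_model,
                                                dataset_128):
        X, y, _ = dataset_128
        cset = h.ClassifierSet.train_all(X, y, h.SCHEMA_VOL_FLAIR_128)
        subs, fbs, labels = h.make_patient_cohort(small_config, seed=99)
        feats = [h.assemble(h.compute_volume_block(s, norm_model), fb,
                            subject_id=s.subject_id, label=lab)
                 for s, fb, lab in zip(subs, fbs, labels)]
        Xe, ye, _ = h.build_dataset(feats, h.SCHEMA_VOL_FLAIR_128)
        rep = h.evaluate_external(cset, Xe, ye)
        cv = h.kfold_cv(X, y, k=4, seed=0)
        lo, hi = cv.three_class_ci
        assert lo <= rep.three_class_accuracy <= hi
        assert rep.fold_assignments == []

    def test_empty_cohort_rejected(self, dataset_128):
        X, y, _ = dataset_128
        cset = h.ClassifierSet.train_all(X, y, h.SCHEMA_VOL_FLAIR_128)
        with pytest.raises(h.ValidationError):
            h.evaluate_external(cset, np.empty((0, 128)), [])


class TestPairedComparison:
    def test_discordant_counts_and_p(self):
        a = [True] * 80 + [False] * 10
        b = [True] * 73 + [False] * 7 + [True] * 3 + [False] * 7
        res = h.compare_paired(a, b)
        assert (res.n_discordant_a, res.n_discordant_b) == (7, 3)
        assert res.p_value == h.mcnemar_exact(7, 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(h.ValidationError):
            h.compare_paired([True], [True, False])
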