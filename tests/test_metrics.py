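"""Evaluation suite against from-definition oracles and known cases."""

import numpy as np
import pytest
from scipy import stats

from ggnav.metrics import (ConfusionMatrix, accuracy, bootstrap_ci,
                           confusion_matrix, contingency_test, grouped_auc,
                           precision_recall_f1, quadratic_kappa,
                           upgrade_downgrade)


def random_cm(rng, lam=8.0):
    return ConfusionMatrix(rng.poisson(lam, size=(5, 5)).astype(np.int64) +
                           np.eye(5, dtype=np.int64))


# ------------------------------------------------------------ brute oracles

def kappa_bruteforce(counts):
    """Quadratic kappa by explicit double loops over the definition."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = counts.shape[0]
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    num = den = 0.0
    for i in range(k):
        for j in range(k):
            w = (i - j) ** 2 / (k - 1) ** 2
            num += w * counts[i, j]
            den += w * row[i] * col[j] / n
    return 1.0 - num / den


def prf_bruteforce(counts, grade):
    k = grade - 1
    tp = fp = fn = 0
    for i in range(5):
        for j in range(5):
            if i == k and j == k:
                tp += counts[i, j]
            elif j == k:
                fp += counts[i, j]
            elif i == k:
                fn += counts[i, j]
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def auc_bruteforce(scores, labels):
    """All-pairs count with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def chi2_bruteforce(table):
    table = np.asarray(table, dtype=float)
    n = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / n
            stat += (table[i, j] - e) ** 2 / e
    return stat


# ------------------------------------------------------------------- tests

class TestConfusionMatrix:
    def test_tabulation(self):
        cm = confusion_matrix([1, 1, 2, 5], [1, 2, 2, 4])
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1
        assert cm.counts[1, 1] == 1 and cm.counts[4, 3] == 1
        assert cm.total == 4

    def test_accuracy_is_trace_over_total(self, rng):
        for _ in range(10):
            cm = random_cm(rng)
            assert accuracy(cm) == pytest.approx(
                np.trace(cm.counts) / cm.counts.sum())

    def test_invalid_grades_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0], [1])


class TestPrecisionRecallF1:
    def test_diagonal_matrix_is_perfect(self):
        cm = ConfusionMatrix(np.diag([3, 4, 5, 6, 7]).astype(np.int64))
        for g in range(1, 6):
            assert precision_recall_f1(cm, g) == (1.0, 1.0, 1.0)

    def test_absent_prediction_flagged_zero(self):
        counts = np.zeros((5, 5), dtype=np.int64)
        counts[0, 1] = 3                        # grade 1 never predicted
        cm = ConfusionMatrix(counts)
        with pytest.warns(UserWarning, match="never predicted"):
            p, r, f1 = precision_recall_f1(cm, 1)
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_matches_bruteforce_on_random_matrices(self, rng):
        for _ in range(100):
            cm = random_cm(rng)
            for g in range(1, 6):
                got = precision_recall_f1(cm, g)
                want = prf_bruteforce(cm.counts, g)
                assert np.allclose(got, want, atol=1e-9)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        ref = rng.integers(1, 6, size=200)
        cmp_ = rng.integers(1, 6, size=200)
        cm = confusion_matrix(ref, cmp_)
        p, r, f, _ = precision_recall_fscore_support(
            ref, cmp_, labels=[1, 2, 3, 4, 5], zero_division=0)
        for g in range(1, 6):
            with np.errstate(all="ignore"):
                got = precision_recall_f1(cm, g)
            # rows are the reference, so recall is along rows
            assert got[1] == pytest.approx(r[g - 1], abs=1e-12)
            assert got[0] == pytest.approx(p[g - 1], abs=1e-12)


class TestQuadraticKappa:
    def test_perfect_agreement_is_one(self):
        cm = ConfusionMatrix(np.diag([5, 1, 9, 2, 3]).astype(np.int64))
        assert quadratic_kappa(cm) == pytest.approx(1.0)

    def test_chance_agreement_is_zero(self):
        """O equal to the outer product of its marginals has kappa 0."""
        row = np.array([10, 20, 30, 20, 20])
        col = np.array([30, 10, 20, 20, 20])
        counts = np.outer(row, col)            # total 100*100
        assert quadratic_kappa(ConfusionMatrix(counts)) == pytest.approx(
            0.0, abs=1e-12)

    def test_matches_bruteforce_to_1e12(self, rng):
        for _ in range(100):
            cm = random_cm(rng)
            assert quadratic_kappa(cm) == pytest.approx(
                kappa_bruteforce(cm.counts), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score

        ref = rng.integers(1, 6, size=300)
        cmp_ = np.clip(ref + rng.integers(-1, 2, size=300), 1, 5)
        cm = confusion_matrix(ref, cmp_)
        assert quadratic_kappa(cm) == pytest.approx(
            cohen_kappa_score(ref, cmp_, weights="quadratic"), abs=1e-12)

    def test_transposition_invariance_and_range(self, rng):
        for _ in range(20):
            cm = random_cm(rng)
            sym = ConfusionMatrix(cm.counts + cm.counts.T)
            assert quadratic_kappa(sym) == pytest.approx(
                quadratic_kappa(ConfusionMatrix(sym.counts.T)), abs=1e-12)
            assert -1.0 <= quadratic_kappa(cm) <= 1.0

    def test_degenerate_single_cell(self):
        counts = np.zeros((5, 5), dtype=np.int64)
        counts[2, 2] = 7
        assert quadratic_kappa(ConfusionMatrix(counts)) == 1.0
        counts = np.zeros((5, 5), dtype=np.int64)
        counts[2, 3] = 7
        with pytest.raises(ValueError):
            quadratic_kappa(ConfusionMatrix(counts))


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        pairs = [(1, 1)] * 10
        lo, hi, _ = bootstrap_ci(pairs, lambda p: 42.0, n_boot=100, seed=0)
        assert lo == hi == 42.0

    def test_same_seed_identical(self, rng):
        pairs = list(zip(rng.integers(1, 6, 30), rng.integers(1, 6, 30)))
        stat = lambda p: np.mean([a == b for a, b in p])
        assert bootstrap_ci(pairs, stat, seed=7) == bootstrap_ci(
            pairs, stat, seed=7)

    def test_interval_contains_point_estimate(self):
        """Percentile interval covers the plug-in estimate in >= 99% of
        200 seeded trials on simulated agreement data."""
        master = np.random.default_rng(0)
        hits = 0
        for trial in range(200):
            ref = master.integers(1, 6, 40)
            cmp_ = np.clip(ref + master.integers(-1, 2, 40), 1, 5)
            pairs = list(zip(ref, cmp_))
            stat = lambda p: np.mean([a == b for a, b in p])
            lo, hi, _ = bootstrap_ci(pairs, stat, n_boot=200, seed=trial)
            hits += lo - 1e-12 <= stat(pairs) <= hi + 1e-12
        assert hits >= 198

    def test_interval_widens_with_level(self, rng):
        pairs = list(zip(rng.integers(1, 6, 50), rng.integers(1, 6, 50)))
        stat = lambda p: np.mean([a == b for a, b in p])
        widths = []
        for level in (0.90, 0.95, 0.99):
            lo, hi, _ = bootstrap_ci(pairs, stat, n_boot=500, level=level,
                                     seed=3)
            widths.append(hi - lo)
        assert widths[0] <= widths[1] <= widths[2]

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([(1, 1)], lambda p: 0.0)


class TestUpgradeDowngrade:
    def test_all_concordant(self):
        res = upgrade_downgrade([(g, g) for g in (1, 3, 5)])
        assert res.upgrade_rate == 0.0 and res.downgrade_rate == 0.0
        assert res.concordance_rate == 1.0

    def test_small_enumeration(self):
        res = upgrade_downgrade([(2, 1), (2, 3), (2, 2), (2, 2)])
        assert res.upgrade_rate == 0.25
        assert res.downgrade_rate == 0.25

    def test_rates_recoverable_from_shift_matrix(self, rng):
        ref = rng.integers(1, 6, 100)
        cmp_ = rng.integers(1, 6, 100)
        res = upgrade_downgrade(list(zip(ref, cmp_)))
        m = res.shift_matrix
        up = np.tril(m, -1).sum() / m.sum()      # compared < reference
        down = np.triu(m, 1).sum() / m.sum()
        assert res.upgrade_rate == pytest.approx(up)
        assert res.downgrade_rate == pytest.approx(down)

    def test_rates_sum_to_one(self, rng):
        ref = rng.integers(1, 6, 57)
        cmp_ = rng.integers(1, 6, 57)
        res = upgrade_downgrade(list(zip(ref, cmp_)))
        assert res.upgrade_rate + res.downgrade_rate + res.concordance_rate \
            == pytest.approx(1.0, abs=1e-9)


class TestContingency:
    def test_independent_table_gives_zero_statistic(self):
        table = np.outer([2, 3, 5], [4, 6]) * 10
        chi2, p = contingency_test(table, method="chi2")
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_formula(self, rng):
        for _ in range(100):
            table = rng.integers(1, 40, size=(rng.integers(2, 5),
                                              rng.integers(2, 5)))
            chi2, _ = contingency_test(table, method="chi2")
            assert chi2 == pytest.approx(chi2_bruteforce(table), abs=1e-9)

    def test_fisher_2x2_matches_scipy(self):
        table = [[8, 2], [1, 5]]
        stat, p = contingency_test(table, method="fisher")
        want = stats.fisher_exact(table)
        assert (stat, p) == (pytest.approx(want[0]), pytest.approx(want[1]))

    def test_auto_switches_to_fisher_on_small_expected(self):
        # tiny counts force expected < 5
        table = [[1, 2], [3, 1]]
        stat_auto, p_auto = contingency_test(table, method="auto")
        stat_f, p_f = contingency_test(table, method="fisher")
        assert (stat_auto, p_auto) == (stat_f, p_f)

    def test_monte_carlo_fisher_seeded(self):
        table = [[5, 1, 0], [2, 4, 1], [0, 2, 4]]
        a = contingency_test(table, method="fisher", seed=5)
        b = contingency_test(table, method="fisher", seed=5)
        assert a == b
        assert 0.0 < a[1] <= 1.0

    def test_zero_margin_dropped_with_warning(self):
        table = [[5, 3, 0], [2, 6, 0]]
        with pytest.warns(UserWarning, match="zero-margin"):
            chi2, p = contingency_test(table, method="chi2")
        want, _ = contingency_test([[5, 3], [2, 6]], method="chi2")
        assert chi2 == pytest.approx(want)


class TestGroupedAUC:
    def test_perfect_separation(self):
        probs = np.zeros((6, 5))
        grades = np.array([1, 1, 1, 4, 5, 5])
        probs[grades <= 3, 0] = 1.0
        probs[grades >= 4, 4] = 1.0
        aucs = grouped_auc(probs, grades)
        assert aucs["high"] == 1.0

    def test_shuffled_labels_near_half(self):
        """Random scores vs labels: AUC within 3 SE of 0.5 at n=2000."""
        rng = np.random.default_rng(8)
        grades = rng.integers(1, 6, 2000)
        probs = rng.dirichlet(np.ones(5), size=2000)
        aucs = grouped_auc(probs, grades)
        for name, (neg, pos) in [("low", ((1,), (2, 3, 4, 5)))]:
            n_pos = np.isin(grades, pos).sum()
            n_neg = 2000 - n_pos
            se = np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
            assert abs(aucs[name] - 0.5) <= 3 * se

    def test_matches_allpairs_bruteforce(self, rng):
        grades = rng.integers(1, 6, 50)
        probs = rng.dirichlet(np.ones(5), size=50)
        aucs = grouped_auc(probs, grades)
        from ggnav.metrics import GRADE_SPLITS
        for name, (neg, pos) in GRADE_SPLITS.items():
            labels = np.isin(grades, pos)
            scores = probs[:, [g - 1 for g in pos]].sum(axis=1)
            assert aucs[name] == pytest.approx(
                auc_bruteforce(scores, labels), abs=1e-9)

    def test_single_class_split_missing(self):
        probs = np.full((4, 5), 0.2)
        grades = np.array([1, 1, 1, 1])
        with pytest.warns(UserWarning, match="single class"):
            aucs = grouped_auc(probs, grades)
        assert aucs["low"] is None
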