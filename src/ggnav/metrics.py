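"""Concordance evaluation suite for five-tier grade groups.

Implements the full comparison battery used when judging a grading method
against the prostatectomy reference: multiclass accuracy, quadratic-weighted
Cohen's kappa, one-vs-rest precision/recall/F1 per grade, patient-level
bootstrap confidence intervals, the upgrading/downgrading decomposition,
contingency-table tests (Pearson chi-square / Fisher), and grouped ROC AUCs
for the low/medium/high-grade dichotomies.

Conventions
-----------
* Confusion matrices are indexed ``counts[reference - 1, compared - 1]``
  with the prostatectomy grade (GG-RP) as reference rows.
* "Upgrading" means the reference grade exceeds the compared grade — the
  biopsy or model under-called and pathology upgraded; "downgrading" is the
  reverse.  Stated explicitly because confusion matrices can be read either
  way.
* Kappa, precision/recall/F1 and AUC are computed from definition in-module;
  scipy provides the contingency-table tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix", "ConcordanceReport", "confusion_matrix",
    "accuracy", "precision_recall_f1", "quadratic_kappa", "bootstrap_ci",
    "upgrade_downgrade", "contingency_test", "grouped_auc",
    "concordance_report", "GRADE_SPLITS",
]

N_GRADES = 5

# Binary dichotomies used for grouped ROC analysis: positives are the
# higher-grade side of each split.
GRADE_SPLITS = {
    "low": ((1,), (2, 3, 4, 5)),
    "medium": ((1, 2), (3, 4, 5)),
    "high": ((1, 2, 3), (4, 5)),
}


@dataclass
class ConfusionMatrix:
    """5x5 integer grid; rows = reference grade, columns = compared."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_GRADES, N_GRADES):
            raise ValueError("confusion matrix must be 5x5")
        if (self.counts < 0).any() or not np.issubdtype(
                self.counts.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(reference, compared) -> ConfusionMatrix:
    """Tabulate paired grades (both in 1..5)."""
    reference = np.asarray(reference, dtype=int)
    compared = np.asarray(compared, dtype=int)
    if reference.shape != compared.shape:
        raise ValueError("paired grade arrays must have equal length")
    for arr in (reference, compared):
        if len(arr) and (arr.min() < 1 or arr.max() > N_GRADES):
            raise ValueError("grades must be in 1..5")
    counts = np.zeros((N_GRADES, N_GRADES), dtype=np.int64)
    np.add.at(counts, (reference - 1, compared - 1), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def precision_recall_f1(cm: ConfusionMatrix, grade: int):
    """One-vs-rest precision, recall and F1 for one grade.

    Empty denominators yield 0 with a warning (e.g. a grade never
    predicted has precision 0).
    """
    if grade not in range(1, N_GRADES + 1):
        raise ValueError("grade must be in 1..5")
    k = grade - 1
    tp = cm.counts[k, k]
    fp = cm.counts[:, k].sum() - tp
    fn = cm.counts[k, :].sum() - tp
    if tp + fp == 0:
        warnings.warn(f"grade {grade} never predicted; precision set to 0",
                      stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn(f"grade {grade} absent from reference; recall set "
                      "to 0", stacklevel=2)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else \
        2 * precision * recall / (precision + recall)
    return float(precision), float(recall), float(f1)


def quadratic_kappa(cm: ConfusionMatrix) -> float:
    """Quadratic-weighted Cohen's kappa.

    Weights w_ij = (i - j)^2 / (K - 1)^2; kappa = 1 - sum(wO) / sum(wE)
    with E the outer product of the marginals scaled to the total.  A
    matrix with all mass in one cell has no chance disagreement: kappa is
    1 on the diagonal and undefined otherwise.
    """
    o = cm.counts.astype(np.float64)
    n = o.sum()
    if n < 1:
        raise ValueError("confusion matrix must contain >= 1 observation")
    k = o.shape[0]
    if (o > 0).sum() == 1:
        # both raters constant: agreement is degenerate, not chance-corrected
        if np.trace(o) == n:
            return 1.0
        raise ValueError("kappa undefined: all mass in one off-diagonal cell")
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    w = (i - j) ** 2 / (k - 1) ** 2
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / n
    denom = (w * e).sum()
    if denom == 0:
        if np.trace(o) == n:
            return 1.0
        raise ValueError("kappa undefined: degenerate marginals with "
                         "off-diagonal mass")
    return float(1.0 - (w * o).sum() / denom)


def bootstrap_ci(pairs, statistic, n_boot: int = 1000, level: float = 0.95,
                 seed: int | np.random.Generator = 0,
                 max_redraws: int = 1000):
    """Patient-level percentile bootstrap interval for ``statistic``.

    ``pairs`` is a sequence of per-patient records (any indexable); the
    statistic receives a resampled list.  Resamples on which the statistic
    raises are redrawn (count available via the third return element).
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("bootstrap needs >= 2 patients")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    values = []
    n_redraws = 0
    while len(values) < n_boot:
        idx = rng.integers(len(pairs), size=len(pairs))
        try:
            values.append(float(statistic([pairs[i] for i in idx])))
        except Exception:
            n_redraws += 1
            if n_redraws > max_redraws:
                raise RuntimeError(
                    "statistic undefined on too many bootstrap resamples")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi), n_redraws


@dataclass
class UpDownResult:
    upgrade_rate: float
    downgrade_rate: float
    concordance_rate: float
    shift_matrix: np.ndarray = field(repr=False)   # rows=reference
    per_grade: dict = field(repr=False)


def upgrade_downgrade(pairs) -> UpDownResult:
    """Decompose (reference, compared) grade pairs into concordance,
    upgrading (compared < reference) and downgrading (compared > reference).

    ``per_grade`` maps each reference grade present in the data to its own
    (upgrade, downgrade, concordance) rates and shift distribution.
    """
    pairs = np.asarray(list(pairs), dtype=int)
    if pairs.size == 0:
        raise ValueError("no grade pairs given")
    ref, cmp_ = pairs[:, 0], pairs[:, 1]
    cm = confusion_matrix(ref, cmp_)
    n = cm.total
    up = float((cmp_ < ref).mean())
    down = float((cmp_ > ref).mean())
    per_grade = {}
    for g in range(1, N_GRADES + 1):
        mask = ref == g
        if not mask.any():
            continue
        shifts = cmp_[mask] - g
        per_grade[g] = {
            "upgrade": float((shifts < 0).mean()),
            "downgrade": float((shifts > 0).mean()),
            "concordance": float((shifts == 0).mean()),
            "shift_counts": {int(s): int((shifts == s).sum())
                             for s in np.unique(shifts)},
        }
    return UpDownResult(upgrade_rate=up, downgrade_rate=down,
                        concordance_rate=1.0 - up - down,
                        shift_matrix=cm.counts, per_grade=per_grade)


def contingency_test(table, method: str = "chi2",
                     seed: int = 0) -> tuple[float, float]:
    """Association test on an R x C count table; returns (statistic, p).

    ``chi2`` is the Pearson test without continuity correction; ``fisher``
    is exact for 2x2 and a seeded Monte-Carlo exact test (10,000 tables
    with fixed margins) otherwise; ``auto`` switches from chi2 to Fisher
    when any expected count falls below 5.  Zero-margin rows/columns are
    dropped with a warning.  P-values are two-sided.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    keep_r = table.sum(axis=1) > 0
    keep_c = table.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("zero-margin rows/columns dropped", stacklevel=2)
        table = table[keep_r][:, keep_c]
        if min(table.shape) < 2:
            raise ValueError("table degenerate after dropping zero margins")
    if method == "auto":
        expected = stats.contingency.expected_freq(table)
        method = "fisher" if (expected < 5).any() else "chi2"
    if method == "chi2":
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(chi2), float(p)
    if method == "fisher":
        if table.shape == (2, 2):
            res = stats.fisher_exact(table, alternative="two-sided")
            return float(res[0]), float(res[1])
        # R x C: Monte-Carlo exact test with fixed margins, chi2 ordering
        rng = np.random.default_rng(seed)
        obs_chi2, _, _, _ = stats.chi2_contingency(table, correction=False)
        n_mc = 10_000
        samples = stats.random_table(table.sum(axis=1), table.sum(axis=0)
                                     ).rvs(n_mc, random_state=rng)
        exceed = 0
        for s in samples:
            c, _, _, _ = stats.chi2_contingency(s, correction=False)
            if c >= obs_chi2 - 1e-12:
                exceed += 1
        return float(obs_chi2), float((exceed + 1) / (n_mc + 1))
    raise ValueError(f"unknown method {method!r}")


def _auc_midrank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC via midranks (ties get the average rank)."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for AUC")
    ranks = stats.rankdata(scores, method="average")
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def grouped_auc(probs: np.ndarray, reference: np.ndarray,
                splits: dict = GRADE_SPLITS) -> dict:
    """AUC for each grade dichotomy.

    ``probs`` is (n, 5) per-patient class probabilities; the binary score
    for a split is the summed probability of its positive (higher-grade)
    side.  Splits with a single observed class are reported as None.
    """
    probs = np.asarray(probs, dtype=np.float64)
    reference = np.asarray(reference, dtype=int)
    if probs.shape != (len(reference), N_GRADES):
        raise ValueError("probs must be (n_patients, 5)")
    out = {}
    for name, (neg, pos) in splits.items():
        labels = np.isin(reference, pos)
        scores = probs[:, [g - 1 for g in pos]].sum(axis=1)
        if labels.all() or not labels.any():
            warnings.warn(f"split {name!r} has a single class; AUC missing",
                          stacklevel=2)
            out[name] = None
        else:
            out[name] = _auc_midrank(scores, labels)
    return out


@dataclass
class ConcordanceReport:
    """Aggregate agreement report between a grading source and GG-RP."""

    accuracy: float
    accuracy_ci: tuple[float, float]
    kappa: float
    kappa_ci: tuple[float, float]
    per_grade: dict
    upgrade_rate: float
    downgrade_rate: float
    concordance_rate: float
    shift_matrix: np.ndarray = field(repr=False)
    n_patients: int = 0

    def __post_init__(self):
        total = self.upgrade_rate + self.downgrade_rate + self.concordance_rate
        if abs(total - 1.0) > 1e-9:
            raise ValueError("up/down/concordance rates must sum to 1")
        for r in (self.upgrade_rate, self.downgrade_rate,
                  self.concordance_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "accuracy": self.accuracy, "accuracy_ci": list(self.accuracy_ci),
            "kappa": self.kappa, "kappa_ci": list(self.kappa_ci),
            "upgrade_rate": self.upgrade_rate,
            "downgrade_rate": self.downgrade_rate,
            "concordance_rate": self.concordance_rate,
            "per_grade": self.per_grade,
            "shift_matrix": self.shift_matrix.tolist(),
        }


def concordance_report(reference, compared, n_boot: int = 1000,
                       level: float = 0.95, seed: int = 0) -> ConcordanceReport:
    """Full agreement report for paired patient-level grades."""
    reference = np.asarray(reference, dtype=int)
    compared = np.asarray(compared, dtype=int)
    pairs = list(zip(reference, compared))
    cm = confusion_matrix(reference, compared)

    def _acc(p):
        a = np.asarray(p)
        return (a[:, 0] == a[:, 1]).mean()

    def _kappa(p):
        a = np.asarray(p)
        return quadratic_kappa(confusion_matrix(a[:, 0], a[:, 1]))

    rng = np.random.default_rng(seed)
    acc_ci = bootstrap_ci(pairs, _acc, n_boot, level, rng)[:2]
    kap_ci = bootstrap_ci(pairs, _kappa, n_boot, level, rng)[:2]
    updown = upgrade_downgrade(pairs)
    per_grade = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in range(1, N_GRADES + 1):
            p, r, f1 = precision_recall_f1(cm, g)

            def _f1(pp, g=g):
                a = np.asarray(pp)
                return precision_recall_f1(
                    confusion_matrix(a[:, 0], a[:, 1]), g)[2]

            f1_ci = bootstrap_ci(pairs, _f1, n_boot, level, rng)[:2]
            per_grade[g] = {"precision": p, "recall": r, "f1": f1,
                            "f1_ci": list(f1_ci)}
    return ConcordanceReport(
        accuracy=accuracy(cm), accuracy_ci=tuple(acc_ci),
        kappa=quadratic_kappa(cm), kappa_ci=tuple(kap_ci),
        per_grade=per_grade,
        upgrade_rate=updown.upgrade_rate,
        downgrade_rate=updown.downgrade_rate,
        concordance_rate=updown.concordance_rate,
        shift_matrix=updown.shift_matrix,
        n_patients=len(pairs))
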