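"""Cross-validation, exact binomial intervals, and paired-model comparison.

Accuracy is the primary measure (it is defined for the three-class
problem); it is reported with an exact two-sided Clopper-Pearson interval
computed from the pooled correct/total counts, while the point estimate is
the mean of the per-fold accuracies.  Binary metrics (ROC-AUC, sensitivity,
specificity, F1) are evaluated per hemisphere on the HS vs no-HS problem.
Two classifiers evaluated on the same subjects are compared with the exact
McNemar test on their discordant predictions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classify import TrainedClassifier, binarize_per_hemisphere, train
from .errors import ValidationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# exact binomial statistics
# ---------------------------------------------------------------------------

def clopper_pearson(successes: int, trials: int, conf: float = 0.95
                    ) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (beta quantiles)."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValidationError(f"invalid counts ({successes}, {trials})")
    alpha = 1.0 - conf
    lower = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(
        sps.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lower, upper


def mcnemar_exact(n_discordant_a: int, n_discordant_b: int) -> float:
    """Two-sided exact McNemar p-value on discordant pairs.

    An exact binomial test of the discordant counts against p = 1/2,
    two-sided as ``min(1, 2 * smaller tail)``.
    """
    b, c = int(n_discordant_a), int(n_discordant_b)
    if b < 0 or c < 0:
        raise ValidationError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return 1.0
    p = 2.0 * float(sps.binom.cdf(min(b, c), n, 0.5))
    return min(1.0, p)


# ---------------------------------------------------------------------------
# report containers
# ---------------------------------------------------------------------------

@dataclass
class BinaryMetrics:
    accuracy: float
    roc_auc: float | None
    sensitivity: float
    specificity: float
    f1: float
    accuracy_ci: tuple[float, float]
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    # AUC and F1 are not binomial counts; their intervals are approximate
    # (binomial on correct decisions) and flagged as such.
    roc_auc_ci: tuple[float, float] | None
    f1_ci: tuple[float, float]
    approximate_cis: tuple[str, ...] = ("roc_auc", "f1")

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "roc_auc": self.roc_auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
            "accuracy_ci": list(self.accuracy_ci),
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity_ci": list(self.specificity_ci),
            "roc_auc_ci": None if self.roc_auc_ci is None else list(self.roc_auc_ci),
            "f1_ci": list(self.f1_ci),
            "approximate_cis": list(self.approximate_cis),
        }


@dataclass
class EvalReport:
    three_class_accuracy: float
    three_class_ci: tuple[float, float]
    n_correct: int
    n_total: int
    per_hemisphere: dict[str, BinaryMetrics]
    fold_assignments: list[int] = field(default_factory=list)
    fold_accuracies: list[float] = field(default_factory=list)
    predictions: list[str] = field(default_factory=list)
    correct: list[bool] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "three_class_accuracy": self.three_class_accuracy,
            "three_class_ci": list(self.three_class_ci),
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "per_hemisphere": {h: m.as_dict() for h, m in self.per_hemisphere.items()},
            "fold_accuracies": self.fold_accuracies,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    def to_table(self) -> str:
        """Human-readable summary (accuracy first, then per-hemisphere)."""
        lines = [
            f"{'Measure':28s}{'Mean':>8s}  95% CI",
            f"{'Accuracy (3-class)':28s}{self.three_class_accuracy:8.3f}"
            f"  {self.three_class_ci[0]:.3f}-{self.three_class_ci[1]:.3f}",
        ]
        for hemi, m in self.per_hemisphere.items():
            lines.append(f"{hemi.capitalize()} hemisphere (HS vs no HS)")
            rows = [
                ("Accuracy", m.accuracy, m.accuracy_ci),
                ("ROC-AUC", m.roc_auc, m.roc_auc_ci),
                ("Recall (Sens)", m.sensitivity, m.sensitivity_ci),
                ("Recall (Spec)", m.specificity, m.specificity_ci),
                ("F1 score", m.f1, m.f1_ci),
            ]
            for name, value, ci in rows:
                if value is None:
                    lines.append(f"  {name:26s}{'n/a':>8s}")
                else:
                    lo, hi = ci if ci is not None else (float("nan"), float("nan"))
                    lines.append(f"  {name:26s}{value:8.3f}  {lo:.3f}-{hi:.3f}")
        return "\n".join(lines)


@dataclass
class PairedComparison:
    n_discordant_a: int  # a correct, b wrong
    n_discordant_b: int  # b correct, a wrong
    p_value: float

    def as_dict(self) -> dict:
        return {"n_discordant_a": self.n_discordant_a,
                "n_discordant_b": self.n_discordant_b,
                "p_value": self.p_value}


# ---------------------------------------------------------------------------
# metric computation
# ---------------------------------------------------------------------------

def binary_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                   scores: np.ndarray | None = None) -> BinaryMetrics:
    """Standard binary metrics; positive class = HS (encoded 1).

    Sensitivity is recall on the HS class, specificity recall on no-HS.
    ROC-AUC needs continuous scores and both classes present; otherwise it
    is reported as None and flagged.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred length mismatch")
    n = y_true.size
    if n == 0:
        raise ValidationError("empty evaluation set")
    n_pos = int((y_true == 1).sum())
    n_neg = n - n_pos
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    n_correct = tp + tn
    accuracy = n_correct / n
    sensitivity = tp / n_pos if n_pos else float("nan")
    specificity = tn / n_neg if n_neg else float("nan")
    f1 = float(f1_score(y_true, y_pred, zero_division=0.0))
    auc = None
    if scores is not None and n_pos and n_neg:
        auc = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    elif scores is not None:
        log.warning("ROC-AUC undefined: only one class present in y_true")
    correct_ci = clopper_pearson(n_correct, n)
    return BinaryMetrics(
        accuracy=accuracy,
        roc_auc=auc,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
        accuracy_ci=correct_ci,
        sensitivity_ci=clopper_pearson(tp, n_pos) if n_pos else (0.0, 1.0),
        specificity_ci=clopper_pearson(tn, n_neg) if n_neg else (0.0, 1.0),
        roc_auc_ci=None if auc is None else correct_ci,
        f1_ci=correct_ci,
    )


def _binary_eval(y_true_str: list[str], y_pred_str: list[str],
                 scores: np.ndarray) -> BinaryMetrics:
    to_int = np.vectorize(lambda s: 1 if s == "HS" else 0)
    return binary_metrics(to_int(y_true_str), to_int(y_pred_str), scores)


# ---------------------------------------------------------------------------
# cross-validation and external evaluation
# ---------------------------------------------------------------------------

def kfold_cv(X: np.ndarray, labels: list[str], k: int, seed: int,
             schema_id: str = "vol_flair_128",
             standardize: bool = False, C: float = 1.0) -> EvalReport:
    """Stratified k-fold cross-validation of the three-class model plus
    per-hemisphere binary models, with pooled-count confidence intervals."""
    X = np.asarray(X, dtype=float)
    y = list(labels)
    n = X.shape[0]
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValidationError(f"k = {k} exceeds n = {n}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.full(n, -1, dtype=int)
    preds = np.empty(n, dtype=object)
    fold_accs: list[float] = []

    left_true, right_true = binarize_per_hemisphere(y)
    bin_pred = {"left": np.empty(n, dtype=object),
                "right": np.empty(n, dtype=object)}
    bin_scores = {"left": np.zeros(n), "right": np.zeros(n)}

    y_arr = np.asarray(y)
    for fold, (tr, te) in enumerate(skf.split(X, y_arr)):
        fold_of[te] = fold
        if len(set(y_arr[tr])) < 2:
            raise ValidationError(f"fold {fold}: training part has < 2 classes")
        model = train(X[tr], list(y_arr[tr]), "three_class", schema_id,
                      standardize=standardize, C=C, seed=seed)
        p, _ = model.predict_matrix(X[te])
        preds[te] = p
        fold_accs.append(float(np.mean(np.asarray(p) == y_arr[te])))

        for hemi, truth in (("left", left_true), ("right", right_true)):
            t_arr = np.asarray(truth)
            bmodel = train(X[tr], list(t_arr[tr]), f"binary_{hemi}", schema_id,
                           standardize=standardize, C=C, seed=seed)
            bp, bs = bmodel.predict_matrix(X[te])
            bin_pred[hemi][te] = bp
            # margin sign toward HS regardless of class order
            sign = 1.0 if bmodel.classes[1] == "HS" else -1.0
            bin_scores[hemi][te] = sign * np.asarray(bs)

    correct = [bool(p == t) for p, t in zip(preds, y)]
    n_correct = int(sum(correct))
    per_hemi = {
        hemi: _binary_eval(truth, list(bin_pred[hemi]), bin_scores[hemi])
        for hemi, truth in (("left", left_true), ("right", right_true))
    }
    return EvalReport(
        three_class_accuracy=float(np.mean(fold_accs)),
        three_class_ci=clopper_pearson(n_correct, n),
        n_correct=n_correct,
        n_total=n,
        per_hemisphere=per_hemi,
        fold_assignments=fold_of.tolist(),
        fold_accuracies=fold_accs,
        predictions=list(preds),
        correct=correct,
    )


@dataclass
class ClassifierSet:
    """The three models evaluated together: 3-class plus per-hemisphere."""

    three_class: TrainedClassifier
    binary_left: TrainedClassifier
    binary_right: TrainedClassifier

    @classmethod
    def train_all(cls, X: np.ndarray, labels: list[str], schema_id: str,
                  standardize: bool = False, C: float = 1.0, seed: int = 0
                  ) -> "ClassifierSet":
        left, right = binarize_per_hemisphere(labels)
        return cls(
            three_class=train(X, labels, "three_class", schema_id,
                              standardize=standardize, C=C, seed=seed),
            binary_left=train(X, left, "binary_left", schema_id,
                              standardize=standardize, C=C, seed=seed),
            binary_right=train(X, right, "binary_right", schema_id,
                               standardize=standardize, C=C, seed=seed),
        )


def evaluate_external(models: ClassifierSet, X: np.ndarray,
                      labels: list[str]) -> EvalReport:
    """Single-pass evaluation of trained models on an external cohort."""
    X = np.asarray(X, dtype=float)
    if X.size == 0 or not labels:
        raise ValidationError("empty external cohort")
    preds, _ = models.three_class.predict_matrix(X)
    correct = [p == t for p, t in zip(preds, labels)]
    n = len(labels)
    n_correct = int(sum(correct))

    left_true, right_true = binarize_per_hemisphere(labels)
    per_hemi = {}
    for hemi, truth, model in (("left", left_true, models.binary_left),
                               ("right", right_true, models.binary_right)):
        bp, bs = model.predict_matrix(X)
        sign = 1.0 if model.classes[1] == "HS" else -1.0
        per_hemi[hemi] = _binary_eval(truth, bp, sign * np.asarray(bs))

    return EvalReport(
        three_class_accuracy=n_correct / n,
        three_class_ci=clopper_pearson(n_correct, n),
        n_correct=n_correct,
        n_total=n,
        per_hemisphere=per_hemi,
        predictions=list(preds),
        correct=correct,
    )


def compare_paired(correct_a: list[bool], correct_b: list[bool]
                   ) -> PairedComparison:
    """Exact McNemar comparison of two classifiers on the same subjects."""
    if len(correct_a) != len(correct_b):
        raise ValidationError("paired comparison needs equal-length results")
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    n_a = int((a & ~b).sum())
    n_b = int((~a & b).sum())
    return PairedComparison(n_a, n_b, mcnemar_exact(n_a, n_b))
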