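"""Classifier bank, split/CV protocol, and the confusion-matrix metric suite.

Six classical families are trained on the selected PC scores — decision
tree, discriminant analysis, SVM, KNN, Gaussian naive Bayes, and a
random-subspace KNN ensemble (the configuration that wins on the benchmark
tables).  Each family is tuned over a small documented grid by validation
accuracy.  The evaluation protocol holds out a stratified test split
(default 70/15/15 train/validation/test) and additionally runs 5-fold
cross-validation over train+validation with the full LR-PCA reduction refit
inside every fold, so feature selection never sees a fold's held-out part.

Metrics are computed from the confusion matrix:
Acc = (TP+TN)/N, SE = TP/(TP+FN), SP = TN/(TN+FP), PRE = TP/(TP+FP),
FNR = 100-SE, FPR = 100-SP, F1 = 2*PRE*SE/(PRE+SE),
MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
AUC by trapezoid over the score-threshold ROC.  All except MCC are reported
in percent; MCC is kept in [-1, 1] with a percent view.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Callable, Hashable, Sequence

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import lrpca

FAMILY_ORDER = (
    "tree",
    "discriminant",
    "svm",
    "knn",
    "naive_bayes",
    "ensemble_subspace_knn",
)

DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)
DEFAULT_FOLDS = 5


# --------------------------------------------------------------------------
# Split plan
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    fold_of: dict[int, int]  # fold id per train+validation index
    fractions: tuple[float, float, float]
    folds: int
    seed: int
    stratified: bool = True

    def fold_split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train part, held-out part) of train+validation for one fold."""
        pool = np.concatenate([self.train, self.validation])
        held = np.array([i for i in pool if self.fold_of[int(i)] == fold])
        rest = np.array([i for i in pool if self.fold_of[int(i)] != fold])
        return rest, held


def _apportion(
    counts: dict, frac: float, total_target: int, prior_extra: dict | None = None
) -> dict:
    """Largest-remainder apportionment of a split quota across classes.

    ``prior_extra`` counts rounding extras a class already received in
    earlier sets; remainder ties go to classes with fewer prior extras so
    the leftover train split stays balanced too.
    """
    prior_extra = prior_extra or {}
    quotas = {c: n * frac for c, n in counts.items()}
    base = {c: int(math.floor(q)) for c, q in quotas.items()}
    leftover = total_target - sum(base.values())
    order = sorted(
        counts,
        key=lambda c: (-(quotas[c] - base[c]), prior_extra.get(c, 0), str(c)),
    )
    for c in order[:leftover]:
        base[c] += 1
    return base


def make_splits(
    labels: Sequence[Hashable],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> SplitPlan:
    """Stratified train/validation/test split plus CV folds over train+val.

    Overall set sizes are ``round(n * fraction)`` and per-class proportions
    are preserved within one sample (largest-remainder apportionment).  Fold
    assignment is a stratified partition of train+validation; the test set
    never enters any fold.  Deterministic for a fixed seed.
    """
    y = np.asarray(labels)
    n = len(y)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    classes, counts = np.unique(y, return_counts=True)
    for c, cnt in zip(classes, counts):
        if cnt < folds:
            raise ValueError(f"class {c!r} has {cnt} < folds={folds} samples")

    rng = np.random.default_rng(seed)
    count_map = dict(zip(classes.tolist(), counts.tolist()))
    n_test = int(round(n * fractions[2]))
    n_val = int(round(n * fractions[1]))
    test_quota = _apportion(count_map, fractions[2], n_test)
    extras = {
        c: test_quota[c] - math.floor(count_map[c] * fractions[2])
        for c in count_map
    }
    val_quota = _apportion(count_map, fractions[1], n_val, prior_extra=extras)

    tr, va, te = [], [], []
    for c in classes.tolist():
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        t, v = test_quota[c], val_quota[c]
        te.extend(idx[:t])
        va.extend(idx[t : t + v])
        tr.extend(idx[t + v :])
    train, val, test = (np.sort(np.array(s, dtype=int)) for s in (tr, va, te))

    pool = np.concatenate([train, val])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of: dict[int, int] = {}
    for f, (_, held) in enumerate(skf.split(pool.reshape(-1, 1), y[pool])):
        for i in pool[held]:
            fold_of[int(i)] = f
    return SplitPlan(
        train=train, validation=val, test=test, fold_of=fold_of,
        fractions=tuple(fractions), folds=folds, seed=seed,
    )


# --------------------------------------------------------------------------
# Metric suite
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int
    positive_class: Hashable

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricReport:
    """Acc/SE/SP/PRE/FNR/FPR/AUC/F1 in percent; MCC in [-1, 1]."""

    Acc: float
    SE: float
    SP: float
    PRE: float
    FNR: float
    FPR: float
    AUC: float | None
    MCC: float
    F1: float

    @property
    def MCC_percent(self) -> float:
        return self.MCC * 100.0

    def as_dict(self, decimals: int = 2) -> dict:
        d = {
            "Acc": self.Acc, "SE": self.SE, "SP": self.SP, "PRE": self.PRE,
            "FNR": self.FNR, "FPR": self.FPR, "AUC": self.AUC,
            "MCC": self.MCC_percent, "F1": self.F1,
        }
        return {
            k: (None if v is None else round(v, decimals)) for k, v in d.items()
        }


def confusion_from_predictions(
    y_true: Sequence, y_pred: Sequence, positive_class: Hashable
) -> ConfusionMatrix:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    pos_t, pos_p = yt == positive_class, yp == positive_class
    return ConfusionMatrix(
        TP=int(np.sum(pos_t & pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
        positive_class=positive_class,
    )


def roc_points(
    y_true: Sequence, scores: Sequence[float], positive_class: Hashable
) -> np.ndarray:
    """(FPR, TPR) per score threshold, thresholds descending, with the
    (0,0) and (1,1) anchors.  Ties share a threshold (one diagonal step)."""
    yt = np.asarray(y_true) == positive_class
    s = np.asarray(scores, dtype=float)
    P, N = int(yt.sum()), int((~yt).sum())
    if P == 0 or N == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    yt, s = yt[order], s[order]
    pts = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += int(yt[j])
            fp += int(not yt[j])
            j += 1
        pts.append((fp / N, tp / P))
        i = j
    return np.asarray(pts)


def auc_trapezoid(points: np.ndarray) -> float:
    """Area under the ROC polyline in percent."""
    fpr, tpr = points[:, 0], points[:, 1]
    return float(np.trapezoid(tpr, fpr) * 100.0)


def metrics_from_confusion(
    cm: ConfusionMatrix, auc: float | None = None
) -> MetricReport:
    TP, FP, TN, FN = cm.TP, cm.FP, cm.TN, cm.FN
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")

    def _pct(num, den):
        return 100.0 * num / den if den else float("nan")

    acc = _pct(TP + TN, total)
    se = _pct(TP, TP + FN)
    sp = _pct(TN, TN + FP)
    pre = _pct(TP, TP + FP)
    fnr = 100.0 - se
    fpr = 100.0 - sp
    f1 = 2 * pre * se / (pre + se) if (pre + se) > 0 else 0.0
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = (TP * TN - FP * FN) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricReport(
        Acc=acc, SE=se, SP=sp, PRE=pre, FNR=fnr, FPR=fpr,
        AUC=auc, MCC=mcc, F1=f1,
    )


def rates_to_fnr_f1(SE: float, PRE: float) -> tuple[float, float]:
    """Metric identities: FNR = 100 - SE and F1 = 2*PRE*SE/(PRE+SE)."""
    return 100.0 - SE, 2 * PRE * SE / (PRE + SE)


def default_positive_class(classes: Sequence[Hashable]) -> Hashable:
    """Positive class convention: malignant > abnormal > last sorted label."""
    cl = sorted(str(c) for c in classes)
    for pref in ("malignant", "abnormal"):
        if pref in cl:
            for c in classes:
                if str(c) == pref:
                    return c
    return sorted(classes, key=str)[-1]


# --------------------------------------------------------------------------
# Classifier bank
# --------------------------------------------------------------------------

def _family_grid(family: str, seed: int) -> list[tuple[str, object]]:
    """Documented hyperparameter grid, simplest setting first."""
    if family == "tree":
        return [
            (f"tree(max_depth={d})", DecisionTreeClassifier(max_depth=d, random_state=seed))
            for d in (3, 5, 10, None)
        ]
    if family == "discriminant":
        return [
            ("lda", LinearDiscriminantAnalysis()),
            ("qda", QuadraticDiscriminantAnalysis()),
        ]
    if family == "svm":
        return [
            (f"svm({kern},C={C})", SVC(kernel=kern, C=C, gamma="scale", random_state=seed))
            for kern in ("linear", "rbf")
            for C in (0.1, 1, 10)
        ]
    if family == "knn":
        return [
            (f"knn(k={k})", KNeighborsClassifier(n_neighbors=k))
            for k in (1, 3, 5, 7)
        ]
    if family == "naive_bayes":
        return [("gaussian_nb", GaussianNB())]
    if family == "ensemble_subspace_knn":
        return [
            (
                "subspace_knn(30x0.5,k=1)",
                BaggingClassifier(
                    estimator=KNeighborsClassifier(n_neighbors=1),
                    n_estimators=30,
                    max_features=0.5,
                    bootstrap=False,
                    bootstrap_features=False,
                    random_state=seed,
                ),
            )
        ]
    raise ValueError(f"unknown classifier family {family!r}")


@dataclass
class TrainedFamily:
    family: str
    setting: str
    model: object
    validation_accuracy: float


@dataclass
class BankResult:
    families: dict[str, TrainedFamily]
    winner: str

    @property
    def best(self) -> TrainedFamily:
        return self.families[self.winner]


def train_bank(
    scores_train: np.ndarray,
    y_train: Sequence,
    scores_val: np.ndarray,
    y_val: Sequence,
    families: Sequence[str] = FAMILY_ORDER,
    seed: int = 0,
) -> BankResult:
    """Tune each family on validation accuracy; return all plus the winner.

    Ties are broken by family order, then by grid order (simpler setting
    first).
    """
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    for fam in families:
        if fam not in FAMILY_ORDER:
            raise ValueError(f"unknown classifier family {fam!r}")
    out: dict[str, TrainedFamily] = {}
    for fam in FAMILY_ORDER:
        if fam not in families:
            continue
        best = None
        for setting, model in _family_grid(fam, seed):
            model.fit(scores_train, y_train)
            acc = float(np.mean(model.predict(scores_val) == y_val))
            if best is None or acc > best.validation_accuracy:
                best = TrainedFamily(fam, setting, model, acc)
        out[fam] = best
    winner = max(
        out, key=lambda f: (out[f].validation_accuracy, -FAMILY_ORDER.index(f))
    )
    return BankResult(families=out, winner=winner)


def decision_scores(model, X: np.ndarray, positive_class: Hashable) -> np.ndarray:
    """Probability-like score for the positive class, family-appropriate.

    ``predict_proba`` (vote fraction for KNN/ensemble, posterior for
    NB/discriminant/tree) where available, otherwise the SVM decision value.
    """
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        col = list(model.classes_).index(positive_class)
        return proba[:, col]
    dec = model.decision_function(X)
    # decision_function is oriented toward classes_[1]
    return dec if model.classes_[1] == positive_class else -dec


def evaluate(
    model,
    scores_test: np.ndarray,
    y_test: Sequence,
    positive_class: Hashable | None = None,
) -> tuple[ConfusionMatrix, MetricReport, np.ndarray | None]:
    """Confusion matrix, metric suite, and ROC points on a test set.

    AUC is the trapezoid area over the score-threshold ROC; with a
    single-class test set the ROC is undefined and AUC is reported missing.
    """
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    if positive_class is None:
        positive_class = default_positive_class(np.unique(y_test))
    y_pred = model.predict(scores_test)
    cm = confusion_from_predictions(y_test, y_pred, positive_class)
    if len(np.unique(y_test)) < 2:
        return cm, metrics_from_confusion(cm, auc=None), None
    s = decision_scores(model, scores_test, positive_class)
    pts = roc_points(y_test, s, positive_class)
    return cm, metrics_from_confusion(cm, auc=auc_trapezoid(pts)), pts


# --------------------------------------------------------------------------
# Cross-validation with per-fold LR-PCA refit
# --------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_reports: list[MetricReport]
    mean: dict[str, float]
    sd: dict[str, float]


def cross_validate(
    X: np.ndarray,
    y: Sequence,
    plan: SplitPlan,
    mode: str = "per_class",
    K: int = lrpca.DEFAULT_K,
    alpha: float = lrpca.DEFAULT_ALPHA,
    family: str = "ensemble_subspace_knn",
    seed: int = 0,
    positive_class: Hashable | None = None,
    reduce_fn: Callable | None = None,
) -> CVResult:
    """K-fold CV over train+validation with leakage-free per-fold reduction.

    For each fold the entire LR-PCA reduction (PCA basis, logistic fit, Wald
    selection) is refit on the fold's training part only; the held-out part
    is projected and filtered with that fold's frozen transform, then the
    named classifier family (tuned on the training part itself) is
    evaluated on it.  ``reduce_fn`` exists so tests can instrument the
    reduction; it defaults to :func:`mammocad.lrpca.lr_pca_reduce`.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    reduce_fn = reduce_fn or lrpca.lr_pca_reduce
    reports: list[MetricReport] = []
    for f in range(plan.folds):
        tr_idx, ho_idx = plan.fold_split(f)
        red = reduce_fn(X[tr_idx], y[tr_idx], X[ho_idx], mode=mode, K=K, alpha=alpha)
        tr_s, ho_s = red.train_scores, red.other_scores
        if tr_s.shape[1] == 0:  # empty selection: keep all K scores
            tr_s = red.full_train_scores.values
            ho_s = red.full_other_scores.values
        bank = train_bank(tr_s, y[tr_idx], tr_s, y[tr_idx], (family,), seed=seed)
        _, rep, _ = evaluate(bank.best.model, ho_s, y[ho_idx], positive_class)
        reports.append(rep)

    keys = ["Acc", "SE", "SP", "PRE", "FNR", "FPR", "AUC", "MCC", "F1"]
    mean, sd = {}, {}
    for k in keys:
        vals = [getattr(r, k) for r in reports]
        vals = [v for v in vals if v is not None]
        mean[k] = float(np.mean(vals)) if vals else float("nan")
        sd[k] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return CVResult(fold_reports=reports, mean=mean, sd=sd)


# --------------------------------------------------------------------------
# Report I/O
# --------------------------------------------------------------------------

def report_to_json(report: MetricReport, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=1)


def write_roc(points: np.ndarray, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("FPR\tTPR\n")
        for fpr, tpr in points:
            fh.write(f"{fpr:.6g}\t{tpr:.6g}\n")
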