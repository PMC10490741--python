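"""Classifier training, transfer protocols, metrics and paired testing.

Two evaluation protocols for two-session recordings:

* **SST** (session-to-session transfer): train on session 1, test on
  session 2.
* **CST** (calibration-session transfer): the chronologically first 40%
  of session 2, balanced per class (floor rounding), joins session 1 for
  training; the remaining 60% is the test set.

The classifier is a one-versus-the-rest ensemble of RBF-kernel SVMs
decided by argmax of the per-class decision values. Hyperparameters
(C, gamma and the number of selected features S) are chosen by grid
search over mean 10-fold stratified cross-validated accuracy on the
training set, with Fisher-score selection and standardization refit
inside every training fold so no test information leaks into selection.
The winning triple is refit on the full training set; the reported
validation accuracy is the winning mean CV accuracy.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .features import FeatureMatrix, Standardizer, fisher_score, select_top


class EvaluationError(ValueError):
    """Raised for invalid split/evaluation requests."""


# ---------------------------------------------------------------------------
# transfer splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Train/test epoch indices into the concatenation [session1; session2]."""

    strategy: str
    train_ids: np.ndarray
    test_ids: np.ndarray
    calibration_fraction: float | None = None

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_ids, self.test_ids).size:
            raise EvaluationError("train and test sets overlap")


def sst_split(session1, session2) -> SplitPlan:
    """All of session 1 for training, all of session 2 for testing."""
    _check_sessions(session1, session2)
    n1 = len(session1.labels)
    n2 = len(session2.labels)
    return SplitPlan(
        strategy="sst",
        train_ids=np.arange(n1),
        test_ids=n1 + np.arange(n2),
    )


def cst_split(session1, session2, fraction: float = 0.40) -> SplitPlan:
    """Move the first ``fraction`` of session 2, per class, into training.

    "First" is chronological (recording order within the session) and the
    per-class calibration count is ``floor(fraction * n_class)``, so the
    calibration set never exceeds the stated fraction.
    """
    _check_sessions(session1, session2)
    if not 0 < fraction < 1:
        raise EvaluationError("calibration fraction must be in (0, 1)")
    n1 = len(session1.labels)
    labels2 = np.asarray(session2.labels)
    calib = []
    test = []
    for cls in np.unique(np.asarray(session1.labels)):
        idx = np.flatnonzero(labels2 == cls)
        if idx.size == 0:
            raise EvaluationError(f"class {cls!r} absent from session 2")
        k = int(np.floor(fraction * idx.size))
        calib.extend(idx[:k])
        test.extend(idx[k:])
    return SplitPlan(
        strategy="cst",
        train_ids=np.concatenate([np.arange(n1), n1 + np.sort(np.asarray(calib, dtype=int))]),
        test_ids=n1 + np.sort(np.asarray(test, dtype=int)),
        calibration_fraction=fraction,
    )


def _check_sessions(session1, session2) -> None:
    if list(session1.montage) != list(session2.montage):
        raise EvaluationError("sessions use different montages")
    if session1.session_id == session2.session_id:
        raise EvaluationError("sessions must have distinct session ids")
    if set(np.unique(np.asarray(session1.labels))) != set(
        np.unique(np.asarray(session2.labels))
    ):
        raise EvaluationError("sessions contain different class sets")


# ---------------------------------------------------------------------------
# model training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Grid-search and cross-validation settings."""

    c_grid: tuple[float, ...] = tuple(2.0**k for k in range(-3, 10, 2))
    gamma_grid: tuple[float, ...] = tuple(2.0**k for k in range(-11, 2, 2))
    s_grid: tuple[int, ...] = (50, 100, 200, 400)
    n_folds: int = 10
    fold_seed: int = 7
    standardize: bool = True


@dataclass
class TrainedModel:
    """Fitted OVR RBF-SVM with its selection/standardization state."""

    classifier: OneVsRestClassifier
    standardizer: Standardizer | None
    selected: np.ndarray
    c: float
    gamma: float
    s: int
    validation_accuracy: float
    classes: np.ndarray
    cv_table: list = field(default_factory=list, repr=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))[:, self.selected]
        if self.standardizer is not None:
            x = self.standardizer.transform(x)
        return self.classifier.predict(x)


def _fit_one(x, y, c, gamma, s, standardize):
    scores = fisher_score(x, y)
    sel = select_top(scores, min(s, x.shape[1]))
    xs = x[:, sel]
    std = None
    if standardize:
        std = Standardizer.fit(xs)
        xs = std.transform(xs)
    clf = OneVsRestClassifier(SVC(C=c, gamma=gamma, kernel="rbf"))
    clf.fit(xs, y)
    return clf, std, sel


def train_model(train: FeatureMatrix, cfg: TrainConfig | None = None) -> TrainedModel:
    """Grid search over (C, gamma, S) with in-fold selection, then refit.

    Every fold recomputes the Fisher scores, the top-S selection and the
    standardization on that fold's training part alone.
    """
    if cfg is None:
        cfg = TrainConfig()
    x, y = train.values, train.labels
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cfg.n_folds:
        raise EvaluationError(
            f"smallest class has {counts.min()} epochs; "
            f"cannot form {cfg.n_folds} stratified folds"
        )
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.fold_seed)
    folds = list(skf.split(x, y))
    s_grid = sorted({min(s, x.shape[1]) for s in cfg.s_grid})

    best = None
    cv_table = []
    for c, gamma, s in itertools.product(cfg.c_grid, cfg.gamma_grid, s_grid):
        accs = []
        for tr, va in folds:
            clf, std, sel = _fit_one(x[tr], y[tr], c, gamma, s, cfg.standardize)
            xv = x[va][:, sel]
            if std is not None:
                xv = std.transform(xv)
            accs.append(float(np.mean(clf.predict(xv) == y[va])))
        mean_acc = float(np.mean(accs))
        cv_table.append((c, gamma, s, mean_acc))
        if best is None or mean_acc > best[3]:
            best = (c, gamma, s, mean_acc)

    c, gamma, s, val_acc = best
    clf, std, sel = _fit_one(x, y, c, gamma, s, cfg.standardize)
    return TrainedModel(
        classifier=clf,
        standardizer=std,
        selected=sel,
        c=c,
        gamma=gamma,
        s=s,
        validation_accuracy=100.0 * val_acc,
        classes=np.unique(y),
        cv_table=cv_table,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows are true classes, columns predictions."""

    counts: np.ndarray
    classes: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def evaluate(model: TrainedModel, test: FeatureMatrix) -> ConfusionMatrix:
    """Confusion matrix of the model's argmax-OVR predictions on ``test``."""
    if test.n_epochs == 0:
        raise EvaluationError("empty test set")
    if test.n_features <= int(model.selected.max()):
        raise EvaluationError("test feature count does not match the trained model")
    pred = model.predict(test.values)
    classes = model.classes
    k = len(classes)
    lut = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(test.labels, pred):
        cm[lut[t], lut[p]] += 1
    return ConfusionMatrix(counts=cm, classes=classes)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified epochs, in percent."""
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) in [-1, 1]."""
    n = cm.total
    if n == 0:
        raise EvaluationError("empty confusion matrix")
    po = float(np.trace(cm.counts)) / n
    pe = float(np.sum(cm.counts.sum(axis=1) * cm.counts.sum(axis=0))) / n**2
    if pe == 1:
        raise EvaluationError("degenerate confusion matrix: expected agreement is 1")
    return (po - pe) / (1 - pe)


def precision_recall(cm: ConfusionMatrix) -> tuple[float, float]:
    """Macro-averaged one-vs-rest precision and recall.

    A class that is never predicted (or never true) contributes 0 to the
    corresponding average.
    """
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    pred_pos = counts.sum(axis=0).astype(float)
    true_pos = counts.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_pos > 0, tp / pred_pos, 0.0)
        rec = np.where(true_pos > 0, tp / true_pos, 0.0)
    return float(prec.mean()), float(rec.mean())


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test on paired values.

    Differences ``d = b - a``; zeros are dropped; ``|d|`` is ranked with
    midranks for ties; the null distribution of the positive-rank sum is
    enumerated exactly over all sign assignments. Returns ``(w, p)``
    where ``w = min(W+, W-)``. With every difference zero there is no
    evidence either way: p = 1 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise EvaluationError("paired samples must be equal-length 1-D arrays")
    if not 1 <= a.size <= 25:
        raise EvaluationError("exact enumeration supported for 1 <= n <= 25 pairs")
    d = b - a
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p-value set to 1", stacklevel=2)
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)

    # exact null distribution of W+ by dynamic programming on twice the
    # ranks (midranks are half-integral)
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w))
    lower = dist[: w2 + 1].sum()
    upper = dist[total - w2:].sum()
    return w, float(min(1.0, lower + upper))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-subject metric table with cross-subject mean and sample SD."""

    per_subject: "object"  # pandas DataFrame, one row per subject
    mean: "object"
    sd: "object"


def aggregate_report(per_subject: dict[str, dict[str, float]]) -> EvaluationReport:
    """Mean and sample SD (n-1 denominator) across subjects per metric.

    With a single subject the SD is reported as missing rather than 0.
    """
    import pandas as pd

    if not per_subject:
        raise EvaluationError("no subjects to aggregate")
    df = pd.DataFrame.from_dict(per_subject, orient="index").sort_index()
    mean = df.mean()
    sd = df.std(ddof=1) if len(df) > 1 else pd.Series(np.nan, index=df.columns)
    return EvaluationReport(per_subject=df, mean=mean, sd=sd)
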