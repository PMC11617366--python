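"""Multi-classifier behaviour recognition scored with per-class
sensitivity and precision.

Six standard classifiers (KNN, Gaussian naive Bayes, MLP, RBF-kernel SVM,
a single binary classification tree, random forest) are trained on the
windowed feature matrix and evaluated with grouped cross-validation — folds
split by animal so no individual contributes to both training and test.
Per class *c*:

    sensitivity = TP / (TP + FN)        precision = TP / (TP + FP)

reported as percentages, with macro ("Average") rows formed as the
unweighted mean over the classes present.  A class that is never predicted
has undefined precision and is excluded from the macro precision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix


class ClassifierKind(str, enum.Enum):
    KNN = "knn"
    NAIVE_BAYES = "naive_bayes"
    MLP = "mlp"
    SVM = "svm"
    BCT = "bct"
    RF = "rf"


#: Kinds whose inputs are z-scored by default (scale-sensitive models).
_SCALED_KINDS = {ClassifierKind.KNN, ClassifierKind.SVM, ClassifierKind.MLP}


@dataclass
class ConfusionCounts:
    """One-vs-rest counts per class for single-label multiclass predictions."""

    classes: list[str]
    tp: dict[str, int]
    fn: dict[str, int]
    fp: dict[str, int]

    def support(self, c: str) -> int:
        return self.tp[c] + self.fn[c]


@dataclass
class ClassReport:
    """Per-class sensitivity/precision (percent) plus macro averages."""

    classifier: Optional[ClassifierKind]
    sensitivity_pct: dict[str, float]
    precision_pct: dict[str, Optional[float]]
    macro_sensitivity_pct: float
    macro_precision_pct: float
    counts: Optional[ConfusionCounts] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier.value if self.classifier else None,
            "per_class": {
                c: {
                    "sensitivity_pct": self.sensitivity_pct[c],
                    "precision_pct": self.precision_pct[c],
                }
                for c in sorted(self.sensitivity_pct)
            },
            "macro_sensitivity_pct": self.macro_sensitivity_pct,
            "macro_precision_pct": self.macro_precision_pct,
        }


def macro_average(values: Sequence[float]) -> float:
    """Unweighted mean of per-class percentages — the report's 'Average' row."""
    vals = [v for v in values if v is not None]
    if not vals:
        raise ValueError("no defined per-class values to average")
    return float(np.mean(vals))


def make_estimator(
    kind: ClassifierKind | str,
    hyperparams: Optional[Mapping] = None,
    seed: int = 0,
):
    """Build the sklearn estimator (wrapped in a z-score pipeline where the
    model is scale-sensitive).  Hyperparameters override the defaults."""
    kind = ClassifierKind(kind)
    hp = dict(hyperparams or {})
    standardize = hp.pop("standardize", kind in _SCALED_KINDS)
    if kind is ClassifierKind.KNN:
        model = KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), **hp)
    elif kind is ClassifierKind.NAIVE_BAYES:
        model = GaussianNB(**hp)
    elif kind is ClassifierKind.MLP:
        model = MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (64,)),
            max_iter=hp.pop("max_iter", 500),
            random_state=seed,
            **hp,
        )
    elif kind is ClassifierKind.SVM:
        model = SVC(
            kernel=hp.pop("kernel", "rbf"),
            C=hp.pop("C", 10.0),
            gamma=hp.pop("gamma", "scale"),
            random_state=seed,
            **hp,
        )
    elif kind is ClassifierKind.BCT:
        model = DecisionTreeClassifier(
            ccp_alpha=hp.pop("ccp_alpha", 1e-3), random_state=seed, **hp
        )
    elif kind is ClassifierKind.RF:
        model = RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 200), random_state=seed, **hp
        )
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown classifier kind: {kind}")
    if standardize:
        return Pipeline([("scale", StandardScaler()), ("model", model)])
    return model


def train_classifier(
    matrix: FeatureMatrix,
    kind: ClassifierKind | str,
    hyperparams: Optional[Mapping] = None,
    seed: int = 0,
):
    """Fit one classifier on the whole feature matrix; deterministic per seed."""
    y = matrix.y
    if len(set(y)) < 2:
        raise ValueError("training set must contain at least 2 classes")
    if not np.all(np.isfinite(matrix.X)):
        raise ValueError("feature matrix contains non-finite values")
    est = make_estimator(kind, hyperparams, seed)
    est.fit(matrix.X, y)
    return est


def confusion_counts(
    true_labels: Sequence, predicted_labels: Sequence, classes: Optional[Sequence] = None
) -> ConfusionCounts:
    yt = [getattr(t, "value", t) for t in true_labels]
    yp = [getattr(p, "value", p) for p in predicted_labels]
    if len(yt) != len(yp):
        raise ValueError("true and predicted label lengths differ")
    if classes is None:
        cls = sorted(set(yt) | set(yp))
    else:
        cls = [getattr(c, "value", c) for c in classes]
        unknown = (set(yt) | set(yp)) - set(cls)
        if unknown:
            raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    tp = {c: 0 for c in cls}
    fn = {c: 0 for c in cls}
    fp = {c: 0 for c in cls}
    for t, p in zip(yt, yp):
        if t == p:
            tp[t] += 1
        else:
            fn[t] += 1
            fp[p] += 1
    return ConfusionCounts(classes=cls, tp=tp, fn=fn, fp=fp)


def evaluate(
    true_labels: Sequence,
    predicted_labels: Sequence,
    classes: Optional[Sequence] = None,
    classifier: Optional[ClassifierKind] = None,
) -> ClassReport:
    """Score predictions with per-class sensitivity/precision and macro rows.

    Classes without support are excluded from macro sensitivity; classes
    never predicted (TP+FP = 0) have ``None`` precision and are excluded
    from macro precision.
    """
    counts = confusion_counts(true_labels, predicted_labels, classes)
    sens: dict[str, float] = {}
    prec: dict[str, Optional[float]] = {}
    for c in counts.classes:
        sup = counts.tp[c] + counts.fn[c]
        sens[c] = 100.0 * counts.tp[c] / sup if sup > 0 else float("nan")
        npred = counts.tp[c] + counts.fp[c]
        prec[c] = 100.0 * counts.tp[c] / npred if npred > 0 else None
    sens_present = [v for v in sens.values() if not np.isnan(v)]
    return ClassReport(
        classifier=classifier,
        sensitivity_pct=sens,
        precision_pct=prec,
        macro_sensitivity_pct=macro_average(sens_present),
        macro_precision_pct=macro_average(list(prec.values())),
        counts=counts,
    )


def _grouped_folds(groups: np.ndarray, n_folds: Optional[int], seed: int):
    """Leave-one-animal-out by default; deterministic grouping otherwise."""
    uniq = np.unique(groups)
    if n_folds is not None and len(uniq) < n_folds:
        raise ValueError("fewer groups than folds")
    if n_folds is None or n_folds == len(uniq):
        splitter = LeaveOneGroupOut()
        yield from splitter.split(np.zeros(len(groups)), groups=groups)
    else:
        if n_folds < 2:
            raise ValueError("need at least 2 folds")
        # assign groups to folds round-robin in sorted order: seed-free,
        # so fold membership depends only on the group ids
        fold_of = {g: i % n_folds for i, g in enumerate(sorted(uniq))}
        fold_ids = np.array([fold_of[g] for g in groups])
        for k in range(n_folds):
            test = np.where(fold_ids == k)[0]
            train = np.where(fold_ids != k)[0]
            yield train, test


def cross_validate(
    matrix: FeatureMatrix,
    kind: ClassifierKind | str,
    n_folds: Optional[int] = None,
    hyperparams: Optional[Mapping] = None,
    seed: int = 0,
    classes: Optional[Sequence] = None,
) -> ClassReport:
    """Grouped-by-animal cross-validation; held-out predictions are pooled
    across folds before a single report is computed."""
    groups = np.asarray(matrix.animal_ids)
    if len(np.unique(groups)) < 2:
        raise ValueError("grouped cross-validation needs at least 2 animals")
    y = matrix.y
    y_pred = np.empty_like(y)
    for train_idx, test_idx in _grouped_folds(groups, n_folds, seed):
        est = make_estimator(kind, hyperparams, seed)
        est = clone(est)
        est.fit(matrix.X[train_idx], y[train_idx])
        y_pred[test_idx] = est.predict(matrix.X[test_idx])
    return evaluate(y, y_pred, classes=classes, classifier=ClassifierKind(kind))


def compare_classifiers(
    matrix: FeatureMatrix,
    kinds: Sequence[ClassifierKind | str] = tuple(ClassifierKind),
    n_folds: Optional[int] = None,
    hyperparams: Optional[Mapping[str, Mapping]] = None,
    seed: int = 0,
    classes: Optional[Sequence] = None,
) -> dict[ClassifierKind, ClassReport]:
    """Paired comparison: every kind is evaluated on identical grouped folds."""
    out: dict[ClassifierKind, ClassReport] = {}
    for kind in kinds:
        k = ClassifierKind(kind)
        hp = (hyperparams or {}).get(k.value)
        out[k] = cross_validate(
            matrix, k, n_folds=n_folds, hyperparams=hp, seed=seed, classes=classes
        )
    return out
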