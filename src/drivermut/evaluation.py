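"""Repeated stratified cross-validation and hold-out evaluation.

A cross-validation run pools the fold confusion counts within each repeat,
computes the metric bundle per repeat, and reports mean and variance
across repeats (the flag ``aggregate="per_fold"`` switches to averaging
per-fold metrics instead). ROC area is computed from out-of-fold positive
class probabilities by the rank statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .metrics import METRICS, metrics_from_confusion, roc_area
from .types import ConfusionMatrix, FeatureMatrix, ValidationError


def _positive_label(labels: np.ndarray, positive=None):
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(f"binary labels required, got {classes.size} classes")
    if positive is None:
        positive = "driver" if "driver" in classes else classes.max()
    if positive not in classes:
        raise ValidationError(f"positive label {positive!r} not among {classes}")
    return positive


def confusion_from_predictions(y_true, y_pred, positive) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionMatrix(
        tp=int((pos_t & pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
    )


@dataclass
class CvReport:
    """Mean/variance of every metric over CV repeats, plus bookkeeping."""

    metric_means: dict[str, float]
    metric_variances: dict[str, float]
    confusions: list[ConfusionMatrix]
    folds: int
    repeats: int
    seed: int
    aggregate: str
    classifier_id: str = ""
    feature_set_id: str = ""
    per_repeat_metrics: list[dict[str, float]] = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier_id,
            "feature_set": self.feature_set_id,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "aggregate": self.aggregate,
            "metrics": {
                name: {
                    "mean": self.metric_means[name],
                    "variance": self.metric_variances[name],
                }
                for name in self.metric_means
            },
            "confusions": [
                {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
                for c in self.confusions
            ],
        }


def cross_validate(
    fm,
    labels,
    trainer_factory: Callable[[], object],
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    positive=None,
    aggregate: str = "pool",
    classifier_id: str = "",
    feature_set_id: str = "",
) -> CvReport:
    """Repeated stratified k-fold CV of any fit/predict classifier.

    Each repeat draws fresh stratified folds from a seed-derived stream.
    With ``aggregate="pool"`` (default) the repeat's confusion counts are
    pooled before computing metrics; ``"per_fold"`` averages per-fold
    metrics. ROC area per repeat uses pooled out-of-fold scores.
    """
    if aggregate not in ("pool", "per_fold"):
        raise ValidationError(f"unknown aggregate mode {aggregate!r}")
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.size:
        raise ValidationError("labels do not match the sample count")
    positive = _positive_label(y, positive)
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValidationError(f"folds={folds} exceeds smallest class size")

    rng = np.random.default_rng(seed)
    per_repeat: list[dict[str, float]] = []
    repeat_confusions: list[ConfusionMatrix] = []
    for _r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        oof_scores = np.full(y.size, np.nan)
        fold_cms: list[ConfusionMatrix] = []
        for train_idx, test_idx in skf.split(X, y):
            model = trainer_factory()
            try:
                model.fit(X[train_idx], y[train_idx])
            except Exception as exc:
                raise ValidationError(
                    f"trainer failed on a fold of size {train_idx.size}: {exc}"
                ) from exc
            pred = np.asarray(model.predict(X[test_idx]))
            fold_cms.append(confusion_from_predictions(y[test_idx], pred, positive))
            scores = _positive_scores(model, X[test_idx], positive)
            oof_scores[test_idx] = scores if scores is not None else (
                pred == positive
            ).astype(float)
        assert sum(c.total for c in fold_cms) == y.size
        pooled = ConfusionMatrix(
            tp=sum(c.tp for c in fold_cms),
            fp=sum(c.fp for c in fold_cms),
            tn=sum(c.tn for c in fold_cms),
            fn=sum(c.fn for c in fold_cms),
        )
        repeat_confusions.append(pooled)
        if aggregate == "pool":
            bundle = metrics_from_confusion(pooled)
        else:
            fold_bundles = [metrics_from_confusion(c) for c in fold_cms]
            bundle = {
                name: float(np.nanmean([b[name] for b in fold_bundles]))
                for name in METRICS
            }
        bundle["roc_area"] = roc_area(oof_scores, y, positive)
        per_repeat.append(bundle)

    names = list(METRICS) + ["roc_area"]
    means = {n: float(np.nanmean([b[n] for b in per_repeat])) for n in names}
    variances = {n: float(np.nanvar([b[n] for b in per_repeat])) for n in names}
    return CvReport(
        metric_means=means,
        metric_variances=variances,
        confusions=repeat_confusions,
        folds=folds,
        repeats=repeats,
        seed=seed,
        aggregate=aggregate,
        classifier_id=classifier_id,
        feature_set_id=feature_set_id,
        per_repeat_metrics=per_repeat,
    )


def _positive_scores(model, X, positive):
    if hasattr(model, "decision_scores"):
        return np.asarray(model.decision_scores(X), dtype=float)
    if hasattr(model, "predict_proba"):
        proba = np.asarray(model.predict_proba(X), dtype=float)
        classes = list(getattr(model, "classes_", []))
        if positive in classes:
            return proba[:, classes.index(positive)]
    return None


def evaluate_on_holdout(
    model,
    test_fm: FeatureMatrix,
    test_labels,
    reducer=None,
    positive=None,
):
    """Confusion matrix + metric bundle of a fitted model on held-out data.

    When the PSS ``reducer`` is passed, any overlap between its fit samples
    and the test samples is refused — the reduction must never have seen
    the test partition.
    """
    y = np.asarray(test_labels)
    if y.size == 0 or len(test_fm.sample_ids) == 0:
        raise ValidationError("empty test set")
    if reducer is not None and reducer.fit_sample_ids:
        leaked = sorted(set(test_fm.sample_ids) & set(reducer.fit_sample_ids))
        if leaked:
            raise ValidationError(
                f"leakage: {len(leaked)} test sample(s) were used to fit the "
                f"PSS reducer (first: {leaked[0]})"
            )
    positive = _positive_label(y, positive)
    pred = np.asarray(model.predict(test_fm.values, feature_names=test_fm.feature_names))
    cm = confusion_from_predictions(y, pred, positive)
    return cm, metrics_from_confusion(cm)


def cross_validate_pipeline(
    ds,
    config,
    trainer_factory: Callable[[], object],
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    positive=None,
    audit_log: list | None = None,
):
    """Leak-free CV of the *whole* pipeline on a labeled MutationDataset.

    Unlike :func:`cross_validate` on a pre-assembled matrix, every fold
    refits the PSS reducer and the median imputer on its training mutations
    only, so feature selection never sees held-out samples. The reducer's
    recorded fit samples are checked against each test fold (and appended
    to ``audit_log`` when given), making the no-leakage property auditable.

    Returns a :class:`CvReport`.
    """
    from .features import MedianImputer, assemble_features, fit_reducer
    from .types import MutationDataset

    labels = np.array([m.label for m in ds.mutations])
    if (labels == None).any():  # noqa: E711 - object array comparison
        raise ValidationError("pipeline CV requires fully labeled mutations")
    positive = _positive_label(labels, positive)
    proteins = list(ds.proteins.values())
    rng = np.random.default_rng(seed)
    per_repeat, repeat_confusions = [], []
    import warnings as _warnings

    for _r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        oof_scores = np.full(labels.size, np.nan)
        fold_cms = []
        for train_idx, test_idx in skf.split(np.zeros(labels.size), labels):
            train_ds = MutationDataset(proteins, [ds.mutations[i] for i in train_idx])
            test_ds = MutationDataset(proteins, [ds.mutations[i] for i in test_idx])
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                reducer = fit_reducer(train_ds, config)
                train_fm = assemble_features(train_ds, config, reducer, False)
                test_fm = assemble_features(test_ds, config, reducer, False)
            leaked = set(test_fm.sample_ids) & set(reducer.fit_sample_ids)
            if audit_log is not None:
                audit_log.append(
                    {"fit_samples": len(reducer.fit_sample_ids),
                     "test_samples": len(test_fm.sample_ids),
                     "overlap": len(leaked)}
                )
            if leaked:
                raise ValidationError(
                    f"internal leakage: reducer saw {len(leaked)} test sample(s)"
                )
            imputer = MedianImputer().fit(train_fm.values)
            model = trainer_factory()
            model.fit(imputer.transform(train_fm.values), labels[train_idx])
            X_test = imputer.transform(test_fm.values)
            pred = np.asarray(model.predict(X_test))
            fold_cms.append(
                confusion_from_predictions(labels[test_idx], pred, positive)
            )
            scores = _positive_scores(model, X_test, positive)
            oof_scores[test_idx] = scores if scores is not None else (
                pred == positive
            ).astype(float)
        pooled = ConfusionMatrix(
            tp=sum(c.tp for c in fold_cms), fp=sum(c.fp for c in fold_cms),
            tn=sum(c.tn for c in fold_cms), fn=sum(c.fn for c in fold_cms),
        )
        repeat_confusions.append(pooled)
        bundle = metrics_from_confusion(pooled)
        bundle["roc_area"] = roc_area(oof_scores, labels, positive)
        per_repeat.append(bundle)

    names = list(METRICS) + ["roc_area"]
    return CvReport(
        metric_means={n: float(np.nanmean([b[n] for b in per_repeat])) for n in names},
        metric_variances={n: float(np.nanvar([b[n] for b in per_repeat])) for n in names},
        confusions=repeat_confusions,
        folds=folds,
        repeats=repeats,
        seed=seed,
        aggregate="pool",
        classifier_id="pipeline",
        per_repeat_metrics=per_repeat,
    )


def holdout_report(cm: ConfusionMatrix, dataset: str = "") -> dict:
    """Tabular row in the conventional column order TP, FP, TN, FN plus
    percentage-rendered metrics."""
    from .metrics import as_percentages

    pct = as_percentages(metrics_from_confusion(cm))
    return {
        "dataset": dataset,
        "TP": cm.tp,
        "FP": cm.fp,
        "TN": cm.tn,
        "FN": cm.fn,
        "accuracy": round(pct["accuracy"], 2),
        "recall": round(pct["recall"], 2),
        "precision": round(pct["precision"], 2),
        "f_measure": round(pct["f_measure"], 2),
        "mcc": round(pct["mcc"], 4),
    }
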