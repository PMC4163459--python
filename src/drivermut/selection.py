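"""Feature ranking (DX discriminant score, mRMR) and incremental selection.

The DX score of a feature is a Fisher-style discriminant ratio,

    DX = (mean_pos - mean_neg)^2 / (var_pos + var_neg),

large when the class means are far apart relative to the within-class
spread. mRMR (minimum redundancy, maximum relevance) ranks features
greedily by mutual information with the class label, penalizing mutual
information with already-selected features. Incremental feature selection
(IFS) then evaluates every top-k prefix of a ranking by repeated
stratified cross-validation and picks the best k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .types import FeatureMatrix, ValidationError

#: variance convention: sample (n-1) form, matching the oracle tests
VAR_DDOF = 1


def _class_split(values: np.ndarray, labels: np.ndarray):
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError(
            f"exactly two classes required, got {classes.size}"
        )
    a, b = (values[labels == c] for c in classes)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each class needs at least 2 samples")
    return a, b


def dx_score(values, labels, ddof: int = VAR_DDOF) -> float:
    """Discriminant ratio of one feature column against binary labels.

    Symmetric in the two classes. Degenerate cases: zero summed variance
    with differing means scores +inf (sorted above every finite score);
    zero variance *and* equal means scores 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos, neg = _class_split(values, labels)
    num = (pos.mean() - neg.mean()) ** 2
    den = pos.var(ddof=ddof) + neg.var(ddof=ddof)
    if den == 0:
        return float("inf") if num > 0 else 0.0
    return float(num / den)


@dataclass(frozen=True)
class FeatureRanking:
    """An ordered ranking of feature names with per-step scores (1-based rank)."""

    method: str
    feature_names: Sequence[str]
    scores: Sequence[float]

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(self.scores):
            raise ValidationError("names and scores differ in length")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("ranked feature names are not unique")

    def __len__(self) -> int:
        return len(self.feature_names)

    def top(self, k: int) -> list[str]:
        return list(self.feature_names[:k])


def rank_dx(fm: FeatureMatrix, labels) -> FeatureRanking:
    """All features scored by DX, sorted descending; ties keep column order.

    +inf scores (perfectly separated zero-variance features) sort before all
    finite scores, among themselves by column order.
    """
    labels = np.asarray(labels)
    scores = np.array([dx_score(fm.values[:, j], labels) for j in range(fm.shape[1])])
    if np.all(scores == 0):
        warnings.warn("all features score 0 (class-constant matrix); ranking is arbitrary")
    order = np.argsort(-scores, kind="stable")  # stable: ties keep lower index
    return FeatureRanking(
        method="dx",
        feature_names=[fm.feature_names[i] for i in order],
        scores=[float(scores[i]) for i in order],
    )


# ---------------------------------------------------------------------------
# mutual information & mRMR


def discretize(column, scheme: str = "mean_sigma") -> np.ndarray:
    """Map a numeric column to a small integer alphabet for MI estimation.

    Default scheme: 3 bins split at mean ± one (sample) standard deviation
    — below, within, above — the convention of the classical mRMR software
    lineage. Binary 0/1 columns pass through unchanged; a zero-variance
    column collapses to a single bin with a warning.
    """
    column = np.asarray(column, dtype=float)
    if scheme != "mean_sigma":
        raise ValidationError(f"unknown discretization scheme {scheme!r}")
    uniq = np.unique(column)
    if uniq.size <= 2 and set(uniq) <= {0.0, 1.0}:
        return column.astype(np.intp)
    sd = column.std(ddof=0)  # population form; the classical binning convention
    if sd == 0:
        warnings.warn("zero-variance column discretizes to a single bin")
        return np.full(column.shape, 2, dtype=np.intp)
    mean = column.mean()
    out = np.full(column.shape, 2, dtype=np.intp)
    out[column < mean - sd] = 1
    out[column > mean + sd] = 3
    return out


def mutual_information(x, y) -> float:
    """Plug-in mutual information (in nats) of two discrete columns.

    Estimated from the empirical joint distribution:
    I = Σ p(x,y) log[p(x,y) / (p(x) p(y))]. Nonnegative; zero iff the
    empirical joint factorizes. Rankings are invariant to the log base.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / (px @ py)[nz])))


def discretize_matrix(fm: FeatureMatrix, scheme: str = "mean_sigma") -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.column_stack(
            [discretize(fm.values[:, j], scheme) for j in range(fm.shape[1])]
        )


def rank_mrmr(
    fm: FeatureMatrix,
    labels,
    variant: str = "MID",
    scheme: str = "mean_sigma",
) -> FeatureRanking:
    """Greedy mRMR ranking over all N features (N selection rounds).

    The first feature maximizes relevance I(x; class). Each later round
    adds the candidate maximizing relevance minus mean redundancy (MID,
    default) or relevance divided by mean redundancy (MIQ; a floor of
    1e-12 on the redundancy keeps the quotient finite). Ties keep the
    lower column index. Scores are the per-round selection criteria.
    """
    if variant not in ("MID", "MIQ"):
        raise ValidationError(f"unknown mRMR variant {variant!r}")
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValidationError("exactly two classes required")
    disc = discretize_matrix(fm, scheme)
    n_feat = disc.shape[1]
    relevance = np.array([mutual_information(disc[:, j], labels) for j in range(n_feat)])
    # pairwise redundancy computed lazily, cached
    pair_mi = np.full((n_feat, n_feat), np.nan)

    def mi_pair(a: int, b: int) -> float:
        if np.isnan(pair_mi[a, b]):
            v = mutual_information(disc[:, a], disc[:, b])
            pair_mi[a, b] = pair_mi[b, a] = v
        return pair_mi[a, b]

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(n_feat))
    while remaining:
        best_j, best_score = None, -np.inf
        for j in remaining:
            if not selected:
                score = relevance[j]
            else:
                red = float(np.mean([mi_pair(j, s) for s in selected]))
                if variant == "MID":
                    score = relevance[j] - red
                else:
                    score = relevance[j] / max(red, 1e-12)
            if score > best_score:  # strict: ties keep the earlier (lower) index
                best_j, best_score = j, score
        selected.append(best_j)
        scores.append(float(best_score))
        remaining.remove(best_j)
    return FeatureRanking(
        method=f"mrmr-{variant.lower()}",
        feature_names=[fm.feature_names[j] for j in selected],
        scores=scores,
    )


# ---------------------------------------------------------------------------
# incremental feature selection


@dataclass
class IfsCurve:
    """Accuracy of every top-k prefix of a ranking under repeated CV."""

    ks: list[int]
    mean_accuracy: list[float]
    variance: list[float]
    best_k: int
    best_accuracy: float
    evaluated_prefixes: list[tuple[str, ...]] = field(default_factory=list, repr=False)


def ifs(
    fm: FeatureMatrix,
    labels,
    ranking: FeatureRanking,
    trainer_factory: Callable[[], object],
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    max_k: int | None = None,
) -> IfsCurve:
    """Evaluate every top-k prefix of ``ranking`` by repeated stratified CV.

    For each k the top-k ranked features are used to train a fresh
    classifier from ``trainer_factory`` (anything honoring fit/predict) on
    each CV fold; the reported accuracy of a repeat pools the fold
    confusion counts, and mean/variance are taken across repeats. Fold
    splits are generated once per repeat and shared by every k, so curves
    compare feature sets, not split luck. ``best_k`` is the smallest k
    attaining the maximum mean accuracy.
    """
    labels = np.asarray(labels)
    if set(ranking.feature_names) != set(fm.feature_names):
        raise ValidationError("ranking does not cover the feature matrix")
    _, counts = np.unique(labels, return_counts=True)
    if folds > counts.min():
        raise ValidationError(
            f"folds={folds} exceeds smallest class size {counts.min()}"
        )
    n = fm.shape[0]
    order = [fm.feature_names.index(name) for name in ranking.feature_names]
    X_ranked = fm.values[:, order]
    n_feat = len(order) if max_k is None else min(max_k, len(order))

    rng = np.random.default_rng(seed)
    splits_per_repeat = []
    for _ in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        splits_per_repeat.append(list(skf.split(np.zeros(n), labels)))

    ks = list(range(1, n_feat + 1))
    means, variances = [], []
    prefixes: list[tuple[str, ...]] = []
    for k in ks:
        prefixes.append(tuple(ranking.feature_names[:k]))
        Xk = X_ranked[:, :k]
        repeat_acc = []
        for splits in splits_per_repeat:
            correct = 0
            for train_idx, test_idx in splits:
                model = trainer_factory()
                model.fit(Xk[train_idx], labels[train_idx])
                pred = np.asarray(model.predict(Xk[test_idx]))
                correct += int((pred == labels[test_idx]).sum())
            repeat_acc.append(correct / n)
        means.append(float(np.mean(repeat_acc)))
        variances.append(float(np.var(repeat_acc)))
    best_idx = int(np.argmax(means))  # argmax returns the first (smallest k) on ties
    return IfsCurve(
        ks=ks,
        mean_accuracy=means,
        variance=variances,
        best_k=ks[best_idx],
        best_accuracy=means[best_idx],
        evaluated_prefixes=prefixes,
    )
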