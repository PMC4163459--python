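"""Rotation-forest ensemble classifier, built from scratch.

Each base tree sees the training data through its own rotation: the
features are randomly partitioned into small groups; for every group a
principal-axis transform is fitted on a random class subset of the
instances, bootstrapped after removing a fraction of them; the per-group
axes are assembled into a block rotation of the full feature space; and an
ordinary decision tree is grown on the rotated data. Averaging the trees'
leaf class distributions gives the ensemble probability. The rotations
diversify the trees while each one still trains on *all* instances and
*all* (rotated) features — the trait that distinguishes the method from
bagging and random subspaces.

Defaults mirror the canonical published algorithm: 10 trees, feature
groups of 3, 50% of instances removed before each per-group principal-axis
fit, all components retained, and an unpruned Gini decision tree as the
base learner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .types import ConfigError, FeatureMatrix, ValidationError

FORMAT_VERSION = 1


@dataclass(frozen=True)
class RotationSpec:
    """Hyperparameters of the ensemble."""

    n_trees: int = 10
    subset_size: int = 3
    sample_fraction: float = 0.5  # fraction *retained* for each PCA fit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.subset_size < 1:
            raise ConfigError("subset_size must be >= 1")
        if not 0 < self.sample_fraction <= 1:
            raise ConfigError("sample_fraction must be in (0, 1]")


def _principal_axes(slice_: np.ndarray) -> np.ndarray:
    """Square orthonormal axes (rows) of a data slice via SVD.

    ``full_matrices=True`` guarantees a p x p orthonormal basis even when
    the slice has fewer samples than features (trailing axes then span the
    null space) — every group block is a genuine rotation.
    """
    centered = slice_ - slice_.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    return vt


class RotationForest:
    """fit/predict/predict_proba classifier over a binary label set.

    ``positive_label`` names the class reported first in probabilities and
    preferred on exact probability ties (default ``"driver"`` when present).
    """

    def __init__(self, spec: RotationSpec | None = None, positive_label=None):
        self.spec = spec or RotationSpec()
        self.positive_label = positive_label
        self.trees_: list[DecisionTreeClassifier] = []
        self.rotations_: list[np.ndarray] = []
        self.groups_: list[list[np.ndarray]] = []
        self.feature_names_: list[str] | None = None
        self.classes_: np.ndarray | None = None

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _as_array(X, feature_names=None):
        if isinstance(X, FeatureMatrix):
            return X.values, list(X.feature_names)
        return np.asarray(X, dtype=float), feature_names

    def _fit_group_block(self, X, y, group, rng) -> np.ndarray:
        """Principal axes for one feature group, on a random class subset
        and bootstrap of the instances; falls back to identity if even a
        resample yields fewer than 2 usable rows."""
        classes = self.classes_
        for _attempt in range(2):
            n_classes = rng.integers(1, len(classes) + 1)
            chosen = rng.choice(len(classes), size=n_classes, replace=False)
            mask = np.isin(y, classes[chosen])
            pool = np.flatnonzero(mask)
            n_keep = max(int(round(self.spec.sample_fraction * pool.size)), 0)
            if n_keep >= 2:
                rows = rng.choice(pool, size=n_keep, replace=True)
                return _principal_axes(X[np.ix_(rows, group)])
        import warnings

        warnings.warn("PCA slice with < 2 samples twice; using identity block")
        return np.eye(len(group))

    def _build_rotation(self, X, y, rng) -> tuple[np.ndarray, list[np.ndarray]]:
        n_features = X.shape[1]
        perm = rng.permutation(n_features)
        groups = [
            perm[i : i + self.spec.subset_size]
            for i in range(0, n_features, self.spec.subset_size)
        ]
        rotation = np.zeros((n_features, n_features))
        for group in groups:
            block = self._fit_group_block(X, y, group, rng)
            # block rows are axes in group-local coordinates; place the
            # transposed block so that X @ R projects onto them
            rotation[np.ix_(group, group)] = block.T
        return rotation, groups

    # -- API ---------------------------------------------------------------

    def fit(self, X, y, feature_names: Sequence[str] | None = None) -> "RotationForest":
        X, names = self._as_array(X, feature_names)
        y = np.asarray(y)
        if np.isnan(X).any():
            raise ValidationError("rotation forest requires complete data; impute first")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2 or counts.min() < 2:
            raise ValidationError("need two classes with >= 2 samples each")
        # groups are permutation chunks, so a feature space narrower than
        # subset_size simply yields one smaller group
        # put the positive class first in classes_ (probability column 0)
        pos = self.positive_label
        if pos is None:
            pos = "driver" if "driver" in classes else classes.max()
        if pos not in classes:
            raise ValidationError(f"positive label {pos!r} not among classes {classes}")
        self.classes_ = np.array([pos] + [c for c in classes if c != pos])
        self.feature_names_ = list(names) if names is not None else None

        rng = np.random.default_rng(self.spec.seed)
        self.trees_, self.rotations_, self.groups_ = [], [], []
        for _t in range(self.spec.n_trees):
            rotation, groups = self._build_rotation(X, y, rng)
            tree = DecisionTreeClassifier(
                criterion="gini", random_state=int(rng.integers(2**31))
            )
            tree.fit(X @ rotation, y)
            self.trees_.append(tree)
            self.rotations_.append(rotation)
            self.groups_.append(groups)
        return self

    def _check_features(self, X, names):
        if self.feature_names_ is not None and names is not None:
            for i, (got, want) in enumerate(zip(names, self.feature_names_)):
                if got != want:
                    raise ValidationError(
                        f"feature name mismatch at column {i}: {got!r} != {want!r}"
                    )
            if len(names) != len(self.feature_names_):
                raise ValidationError(
                    f"expected {len(self.feature_names_)} features, got {len(names)}"
                )
        if X.shape[1] != self.rotations_[0].shape[0]:
            raise ValidationError(
                f"expected {self.rotations_[0].shape[0]} features, got {X.shape[1]}"
            )

    def predict_proba(self, X, feature_names: Sequence[str] | None = None) -> np.ndarray:
        """Mean of per-tree leaf class distributions; columns follow
        ``classes_`` (positive class first); each row sums to 1."""
        if not self.trees_:
            raise ValidationError("model not fitted")
        X, names = self._as_array(X, feature_names)
        self._check_features(X, names)
        total = np.zeros((X.shape[0], 2))
        for tree, rotation in zip(self.trees_, self.rotations_):
            proba = tree.predict_proba(X @ rotation)
            # align sklearn's lexicographic class order to ours
            col = {c: i for i, c in enumerate(tree.classes_)}
            total += proba[:, [col[self.classes_[0]], col[self.classes_[1]]]]
        return total / len(self.trees_)

    def predict(self, X, feature_names: Sequence[str] | None = None) -> np.ndarray:
        """Argmax of predict_proba; exact ties go to the positive class."""
        proba = self.predict_proba(X, feature_names)
        return np.where(proba[:, 0] >= proba[:, 1], self.classes_[0], self.classes_[1])

    def decision_scores(self, X, feature_names=None) -> np.ndarray:
        """Probability of the positive class (for ROC ranking)."""
        return self.predict_proba(X, feature_names)[:, 0]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "format_version": FORMAT_VERSION,
            "spec": self.spec,
            "positive_label": self.positive_label,
            "trees": self.trees_,
            "rotations": self.rotations_,
            "groups": self.groups_,
            "feature_names": self.feature_names_,
            "classes": self.classes_,
        }
        joblib.dump(payload, Path(path))

    @classmethod
    def load(cls, path) -> "RotationForest":
        payload = joblib.load(Path(path))
        version = payload.get("format_version")
        if version != FORMAT_VERSION:
            raise ConfigError(
                f"model format version {version!r} incompatible with {FORMAT_VERSION}"
            )
        model = cls(spec=payload["spec"], positive_label=payload["positive_label"])
        model.trees_ = payload["trees"]
        model.rotations_ = payload["rotations"]
        model.groups_ = payload["groups"]
        model.feature_names_ = payload["feature_names"]
        model.classes_ = payload["classes"]
        return model
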