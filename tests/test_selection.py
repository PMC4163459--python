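"""DX score, mutual information, mRMR greedy ranking, and IFS."""

import math

import numpy as np
import pytest

import drivermut as dm
from drivermut.selection import discretize_matrix
from drivermut.types import FeatureMatrix

from conftest import forest_factory


def _fm(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{j}" for j in range(values.shape[1])]
    return FeatureMatrix(
        [f"s{i}" for i in range(values.shape[0])], names, values,
        {n: "AF" for n in names},
    )


LAB4 = np.array(["driver", "driver", "passenger", "passenger"])


# ---------------------------------------------------------------------------
# DX score


def test_dx_score_identical_classes_is_zero():
    assert dm.dx_score([2, 2, 2, 2, 2, 2],
                       ["driver"] * 3 + ["passenger"] * 3) == 0.0


def test_dx_score_direct_evaluation():
    # pos {1,3}: mean 2, sample var 2; neg {-1,1}: mean 0, var 2 -> 4/4 = 1
    assert dm.dx_score([1, 3, -1, 1], LAB4) == pytest.approx(1.0)


def test_dx_score_matches_brute_force_oracle(rng):
    labels = np.array(["driver"] * 30 + ["passenger"] * 20)
    for _ in range(100):
        col = rng.normal(size=50)
        pos, neg = col[:30], col[30:]
        oracle = (pos.mean() - neg.mean()) ** 2 / (
            pos.var(ddof=1) + neg.var(ddof=1)
        )
        assert dm.dx_score(col, labels) == pytest.approx(oracle, abs=1e-12)


def test_dx_score_degenerate_sentinels():
    assert dm.dx_score([1, 1, 0, 0], LAB4) == math.inf
    assert dm.dx_score([1, 1, 1, 1], LAB4) == 0.0
    with pytest.raises(dm.ValidationError):
        dm.dx_score([1, 2, 3], ["driver"] * 3)


# ---------------------------------------------------------------------------
# rank_dx


def test_rank_dx_recovers_planted_features(tabular):
    fm, labels, truth = tabular
    ranking = dm.rank_dx(fm, labels)
    assert sorted(ranking.top(5)) == truth["informative_features"]
    assert ranking.scores == sorted(ranking.scores, reverse=True)


def test_rank_dx_permutation_equivariance_and_duplicates(rng):
    values = rng.normal(size=(40, 6))
    labels = np.array(["driver"] * 20 + ["passenger"] * 20)
    values[:20, 2] += 2.0
    base = dm.rank_dx(_fm(values), labels)
    perm = [3, 0, 5, 2, 1, 4]
    permuted = dm.rank_dx(
        _fm(values[:, perm], names=[f"f{j}" for j in perm]), labels
    )
    assert permuted.feature_names == base.feature_names
    dup = np.column_stack([values, values[:, 2]])
    r = dm.rank_dx(_fm(dup, names=[f"f{j}" for j in range(6)] + ["dup"]), labels)
    assert r.feature_names[:2] in (["f2", "dup"], ["dup", "f2"])
    assert r.scores[0] == r.scores[1]


def test_rank_dx_infinite_scores_sort_first(rng):
    values = rng.normal(size=(20, 3))
    labels = np.array(["driver"] * 10 + ["passenger"] * 10)
    values[:, 1] = np.where(labels == "driver", 1.0, 0.0)  # zero-variance split
    ranking = dm.rank_dx(_fm(values), labels)
    assert ranking.feature_names[0] == "f1" and ranking.scores[0] == math.inf


# ---------------------------------------------------------------------------
# discretization & MI


def test_discretize_mean_sigma_thresholds():
    assert dm.discretize([-10.0, 0.0, 10.0]).tolist() == [1, 2, 3]


def test_discretize_passthrough_and_constant():
    assert dm.discretize([0.0, 1.0, 0.0, 1.0]).tolist() == [0, 1, 0, 1]
    with pytest.warns(UserWarning, match="zero-variance"):
        assert len(set(dm.discretize([3.0, 3.0, 3.0]))) == 1


def test_mutual_information_identity_channel():
    x = np.repeat([0, 1, 2], 4)
    assert dm.mutual_information(x, x) == pytest.approx(math.log(3), abs=1e-12)
    assert dm.mutual_information(x, np.zeros_like(x)) == pytest.approx(0.0, abs=1e-12)


def test_mutual_information_matches_contingency_oracle(rng):
    for _ in range(100):
        x = rng.integers(0, 3, size=60)
        y = rng.integers(0, 3, size=60)
        # independent oracle: explicit double sum over the 3x3 joint table
        oracle = 0.0
        n = len(x)
        for a in range(3):
            for b in range(3):
                pxy = np.mean((x == a) & (y == b))
                px, py = np.mean(x == a), np.mean(y == b)
                if pxy > 0:
                    oracle += pxy * math.log(pxy / (px * py))
        assert dm.mutual_information(x, y) == pytest.approx(oracle, abs=1e-12)
        assert dm.mutual_information(x, y) >= -1e-15


def test_mutual_information_agrees_with_sklearn(rng):
    from sklearn.metrics import mutual_info_score

    x = rng.integers(0, 4, size=200)
    y = rng.integers(0, 3, size=200)
    assert dm.mutual_information(x, y) == pytest.approx(
        mutual_info_score(x, y), abs=1e-12
    )


# ---------------------------------------------------------------------------
# mRMR


def _greedy_oracle(disc, labels, variant):
    """Independently coded exhaustive greedy mRMR on a small matrix."""
    n_feat = disc.shape[1]
    rel = [dm.mutual_information(disc[:, j], labels) for j in range(n_feat)]
    selected, remaining = [], list(range(n_feat))
    while remaining:
        best, best_score = None, -np.inf
        for j in remaining:
            if selected:
                red = np.mean(
                    [dm.mutual_information(disc[:, j], disc[:, s]) for s in selected]
                )
                score = rel[j] - red if variant == "MID" else rel[j] / max(red, 1e-12)
            else:
                score = rel[j]
            if score > best_score:
                best, best_score = j, score
        selected.append(best)
        remaining.remove(best)
    return selected


@pytest.mark.parametrize("variant", ["MID", "MIQ"])
def test_rank_mrmr_equals_exhaustive_greedy_oracle(rng, variant):
    for trial in range(5):
        values = rng.normal(size=(60, 6))
        labels = np.array(["driver"] * 30 + ["passenger"] * 30)
        values[:30, 0] += 2.0
        values[:, 3] = values[:, 0]  # redundant twin
        fm = _fm(values)
        ranking = dm.rank_mrmr(fm, labels, variant=variant)
        oracle = _greedy_oracle(discretize_matrix(fm), labels, variant)
        assert ranking.feature_names == [f"f{j}" for j in oracle]


def test_rank_mrmr_demotes_redundant_duplicate(rng):
    """An identical twin of the most relevant feature falls below an
    independent weakly relevant feature."""
    n = 200
    labels = np.array(["driver"] * 100 + ["passenger"] * 100)
    signs = np.where(labels == "driver", 1.0, -1.0)
    strong = signs * 2 + rng.normal(0, 0.2, n)
    weak = signs * 0.8 + rng.normal(size=n)
    fm = _fm(np.column_stack([strong, strong.copy(), weak]),
             names=["strong", "twin", "weak"])
    ranking = dm.rank_mrmr(fm, labels)
    assert ranking.feature_names[0] in ("strong", "twin")
    assert ranking.feature_names[1] == "weak"


def test_rank_mrmr_single_feature(rng):
    labels = np.array(["driver"] * 10 + ["passenger"] * 10)
    fm = _fm(rng.normal(size=(20, 1)))
    ranking = dm.rank_mrmr(fm, labels)
    disc = discretize_matrix(fm)
    assert len(ranking) == 1
    assert ranking.scores[0] == pytest.approx(
        dm.mutual_information(disc[:, 0], labels)
    )


# ---------------------------------------------------------------------------
# IFS


@pytest.fixture(scope="module")
def small_tabular():
    return dm.simulate_feature_table(
        n_samples=120, n_features=12, n_informative=4, effect_size=3.0, seed=5
    )


def test_ifs_curve_structure_and_prefix_audit(small_tabular):
    fm, labels, _ = small_tabular
    ranking = dm.rank_dx(fm, labels)
    calls = []

    class SpyTree:
        def __init__(self):
            from sklearn.tree import DecisionTreeClassifier

            self.t = DecisionTreeClassifier(random_state=0)

        def fit(self, X, y):
            calls.append(X.shape[1])
            self.t.fit(X, y)

        def predict(self, X):
            return self.t.predict(X)

    curve = dm.ifs(fm, labels, ranking, SpyTree, folds=5, repeats=2, seed=3)
    assert curve.ks == list(range(1, 13))
    assert all(v >= 0 for v in curve.variance)
    assert curve.best_accuracy == max(curve.mean_accuracy)
    # smallest k attains the max on ties
    assert curve.best_k == curve.ks[curve.mean_accuracy.index(curve.best_accuracy)]
    # every evaluated feature set is a prefix of the ranking
    for prefix in curve.evaluated_prefixes:
        assert list(prefix) == ranking.feature_names[: len(prefix)]
    # trainer only ever saw prefix-sized feature sets
    assert set(calls) <= set(curve.ks)


def test_ifs_determinism_same_seed(small_tabular):
    fm, labels, _ = small_tabular
    ranking = dm.rank_dx(fm, labels)
    factory = forest_factory(seed=9, n_trees=3)
    a = dm.ifs(fm, labels, ranking, factory, repeats=2, seed=11, max_k=6)
    b = dm.ifs(fm, labels, ranking, factory, repeats=2, seed=11, max_k=6)
    assert a.mean_accuracy == b.mean_accuracy
    assert a.best_k == b.best_k


def test_ifs_full_k_equals_plain_repeated_cv(small_tabular):
    fm, labels, _ = small_tabular
    ranking = dm.rank_dx(fm, labels)
    factory = forest_factory(seed=2, n_trees=3)
    curve = dm.ifs(fm, labels, ranking, factory, folds=5, repeats=2, seed=17)
    ranked_fm = fm.select(ranking.feature_names)
    report = dm.cross_validate(ranked_fm, labels, factory, folds=5, repeats=2, seed=17)
    assert curve.mean_accuracy[-1] == pytest.approx(
        report.metric_means["accuracy"], abs=1e-12
    )


def test_ifs_rejects_incomplete_ranking(small_tabular):
    fm, labels, _ = small_tabular
    bad = dm.FeatureRanking("dx", fm.feature_names[:-1], [0.0] * (len(fm.feature_names) - 1))
    with pytest.raises(dm.ValidationError, match="cover"):
        dm.ifs(fm, labels, bad, forest_factory(), repeats=1)
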