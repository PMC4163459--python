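"""Encoder families: residue-change, matrix lookup, 2-grams, LCC, AF, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import drivermut as dm
from drivermut.features import (
    GRAM_LABELS,
    N_GRAMS,
    SIX_LETTER_GROUPS,
    dataset_grams,
    mutated_sequence,
)
from drivermut.tables import PropertyScale, SubstitutionMatrix
from drivermut.types import AMINO_ACIDS

residues = st.sampled_from(AMINO_ACIDS)
sequences = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=60)


def _toy_scale(name="toy", **vals):
    base = {aa: 0.0 for aa in AMINO_ACIDS}
    base.update(vals)
    return PropertyScale(name, base)


def _mut(wild="A", mutant="V"):
    return dm.MutationRecord("p1", 1, wild, mutant)


# ---------------------------------------------------------------------------
# six-letter alphabet


def test_six_letter_groups_match_published_partition():
    groups = {g: sorted(aa for aa, gg in SIX_LETTER_GROUPS.items() if gg == g)
              for g in range(1, 7)}
    assert groups == {
        1: ["D", "E", "N", "Q"], 2: ["H", "K", "R"], 3: ["C"],
        4: ["A", "G", "P", "S", "T"], 5: ["I", "L", "M", "V"],
        6: ["F", "W", "Y"],
    }
    assert sorted(len(v) for v in groups.values()) == [1, 3, 3, 4, 4, 5]


# ---------------------------------------------------------------------------
# AARC / SSM


def test_encode_aarc_is_wild_minus_mutant():
    scale = _toy_scale(A=2.0, V=5.0)
    assert dm.encode_aarc(_mut("A", "V"), [scale]) == pytest.approx([-3.0])
    assert dm.encode_aarc(_mut("A", "V"), [_toy_scale(A=1.0, V=1.0)]) == [0.0]


def test_encode_aarc_default_width_is_15(default_cfg):
    vec = dm.encode_aarc(_mut(), default_cfg.scales)
    assert vec.shape == (15,)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(wild=residues, mutant=residues)
def test_encode_aarc_antisymmetric_under_residue_swap(default_cfg, wild, mutant):
    if wild == mutant:
        return
    fwd = dm.encode_aarc(_mut(wild, mutant), default_cfg.scales)
    rev = dm.encode_aarc(_mut(mutant, wild), default_cfg.scales)
    assert np.allclose(fwd, -rev)


def test_encode_ssm_looks_up_ordered_element(default_cfg):
    grid = -np.ones((20, 20))
    grid[dm.AMINO_ACIDS.index("D"), dm.AMINO_ACIDS.index("E")] = 7.0
    mat = SubstitutionMatrix("toy", grid)
    assert dm.encode_ssm(_mut("D", "E"), [mat]) == [7.0]
    assert dm.encode_ssm(_mut("E", "D"), [mat]) == [-1.0]
    assert dm.encode_ssm(_mut(), default_cfg.matrices).shape == (51,)


def test_scale_missing_residue_is_config_error():
    with pytest.raises(dm.ConfigError, match="toy"):
        PropertyScale("toy", {"A": 1.0})


# ---------------------------------------------------------------------------
# 2-grams


def test_gram_counts_hand_counted_example():
    g = dm.gram_counts("AAG")
    labels = dict(zip(GRAM_LABELS, g))
    assert labels["AA"] == 1 and labels["AG"] == 1
    assert g[:400].sum() == 2
    # A, A, G all map to group 4 -> the (4,4) group gram counts both pairs
    assert labels["g44"] == 2
    assert g.size == N_GRAMS == 436


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seq=sequences)
def test_gram_conservation_both_halves_sum_to_len_minus_1(seq):
    g = dm.gram_counts(seq)
    assert g[:400].sum() == len(seq) - 1
    assert g[400:].sum() == len(seq) - 1


def test_gram_counts_rejects_short_or_nonstandard():
    with pytest.raises(dm.ValidationError):
        dm.gram_counts("A")
    with pytest.raises(dm.ValidationError, match="X"):
        dm.gram_counts("AXA")


# ---------------------------------------------------------------------------
# LCC


def test_lcc_self_and_anti_correlation(rng):
    x = rng.normal(size=436)
    assert dm.lcc(x, x) == pytest.approx(1.0, abs=1e-12)
    assert dm.lcc(x, -x + 3.0) == pytest.approx(-1.0, abs=1e-12)


def test_lcc_matches_brute_force_pearson(rng):
    for _ in range(100):
        x = rng.normal(size=436)
        m = rng.normal(size=436)
        # independent oracle: textbook centered-moment Pearson formula
        xc, mc = x - x.mean(), m - m.mean()
        oracle = (xc * mc).sum() / np.sqrt((xc**2).sum() * (mc**2).sum())
        assert dm.lcc(x, m) == pytest.approx(oracle, abs=1e-12)


def test_lcc_zero_variance_is_missing_with_warning():
    with pytest.warns(UserWarning, match="zero variance"):
        assert np.isnan(dm.lcc(np.ones(436), np.arange(436.0)))


# ---------------------------------------------------------------------------
# PSS reduction


def test_fit_pss_reducer_recovers_planted_column(rng):
    n = 100
    grams = rng.poisson(3.0, size=(n, 436)).astype(float)
    labels = np.array(["driver"] * 50 + ["passenger"] * 50)
    sd = grams[:, 7].std()
    grams[:50, 7] += 5 * sd  # planted separation on column 7
    reducer = dm.fit_pss_reducer(grams, labels, top_k=30)
    assert reducer.selected_indices[0] == 7
    assert reducer.top_k == 30 and len(reducer.selected_indices) == 30


def test_fit_pss_reducer_errors(rng):
    grams = rng.poisson(3.0, size=(10, 436)).astype(float)
    with pytest.raises(dm.ValidationError, match="two classes"):
        dm.fit_pss_reducer(grams, ["driver"] * 10)
    with pytest.raises(dm.ValidationError, match="degenerate"):
        dm.fit_pss_reducer(
            np.ones((10, 436)), ["driver"] * 5 + ["passenger"] * 5
        )
    # flag-controlled fallback: zero scores, index-order tie-break
    reducer = dm.fit_pss_reducer(
        np.ones((10, 436)), ["driver"] * 5 + ["passenger"] * 5,
        on_constant="zero",
    )
    assert reducer.selected_indices == tuple(range(30))


def test_encode_pss_is_sequence_level(small_dataset, default_cfg):
    ds, _ = small_dataset
    reducer = dm.fit_reducer(ds, default_cfg)
    grams = dataset_grams(ds, default_cfg)
    by_protein = {}
    for mut, row in zip(ds.mutations, grams):
        vec = reducer.transform(row)
        assert vec.shape == (31,)
        prev = by_protein.setdefault(mut.protein_id, vec)
        assert np.allclose(prev, vec)  # same protein -> same PSS vector


def test_mutant_sequence_differs_in_one_position():
    prot = dm.ProteinRecord("p1", "ACDE")
    mut = dm.MutationRecord("p1", 3, "D", "W")
    assert mutated_sequence(prot, mut) == "ACWE"


# ---------------------------------------------------------------------------
# annotated features


def test_encode_af_schema_order_imputation_and_log():
    schema = dm.AfSchema((("b1", "binary"), ("n1", "numeric"), ("b2", "binary")))
    mut = dm.MutationRecord("p1", 1, "A", "V", {"b1": 1.0, "n1": None})
    log = {}
    vec = dm.encode_af(mut, schema, log)
    assert vec[0] == 1.0 and np.isnan(vec[1]) and vec[2] == 0.0
    assert log == {"n1": 1, "b2": 1}


def test_encode_af_rejects_nonbinary_value():
    schema = dm.AfSchema((("b1", "binary"),))
    mut = dm.MutationRecord("p1", 1, "A", "V", {"b1": 2.0})
    with pytest.raises(dm.ValidationError, match="b1"):
        dm.encode_af(mut, schema)


def test_bundled_af_schema_is_29_with_14_binary():
    schema = dm.bundled_af_schema()
    kinds = [k for _, k in schema.entries]
    assert len(schema) == 29
    assert kinds.count("binary") == 14 and kinds.count("numeric") == 15


# ---------------------------------------------------------------------------
# assembly


def test_assemble_default_width_126_and_provenance(small_dataset, default_cfg):
    ds, _ = small_dataset
    reducer = dm.fit_reducer(ds, default_cfg)
    fm = dm.assemble_features(ds, default_cfg, reducer, warn_imputations=False)
    assert fm.shape == (len(ds), 126)
    assert fm.family_counts() == {"AARC": 15, "SSM": 51, "PSS": 31, "AF": 29}
    assert len(set(fm.feature_names)) == 126


def test_assemble_without_af_gives_97(small_dataset):
    ds, _ = small_dataset
    cfg = dm.default_config(af_schema=dm.AfSchema(()))
    reducer = dm.fit_reducer(ds, cfg)
    fm = dm.assemble_features(ds, cfg, reducer, warn_imputations=False)
    assert fm.shape[1] == 97


def test_assemble_is_deterministic(small_dataset, default_cfg):
    ds, _ = small_dataset
    reducer = dm.fit_reducer(ds, default_cfg)
    a = dm.assemble_features(ds, default_cfg, reducer, warn_imputations=False)
    b = dm.assemble_features(ds, default_cfg, reducer, warn_imputations=False)
    assert a.feature_names == b.feature_names
    assert np.array_equal(a.values, b.values, equal_nan=True)


def test_reducer_refit_on_train_plus_test_changes_selection(default_cfg):
    """Leakage changes the fitted reduction on adversarial data: the test
    half carries its signal on different gram components than the train
    half, so fitting on train+test shifts the selected indices."""
    rng = np.random.default_rng(0)
    labels = np.array(["driver"] * 30 + ["passenger"] * 30)
    train = rng.poisson(3.0, (60, 436)).astype(float)
    test = rng.poisson(3.0, (60, 436)).astype(float)
    train[:30, :15] += 6.0   # train signal on grams 0..14
    test[:30, 100:130] += 12.0  # adversarial test signal elsewhere
    fit_train = dm.fit_pss_reducer(train, labels, top_k=30)
    fit_both = dm.fit_pss_reducer(
        np.vstack([train, test]), np.concatenate([labels, labels]), top_k=30
    )
    assert set(fit_train.selected_indices) != set(fit_both.selected_indices)
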