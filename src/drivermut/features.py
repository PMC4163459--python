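"""The four feature-encoder families and the 126-feature assembler.

A missense mutation is described by four families of numeric features:

* **AARC** — amino-acid residue change: for each physicochemical property
  scale, ``scale(wild) - scale(mutant)``; one feature per scale (default 15).
* **SSM** — substitution scoring matrices: the (wild, mutant) element of
  each matrix; one feature per matrix (default 51).
* **PSS** — protein-sequence-specific: dipeptide (2-gram) counts of the
  source protein over the 20-letter alphabet (400 components) and over a
  reduced 6-letter physicochemical alphabet (36 components), 436 raw
  components in total. A discriminant-score (DX) reduction fitted on
  training data keeps the 30 most class-separating components, and a linear
  correlation coefficient (LCC) between the sample's 436-vector and the
  training mean profile is appended — 31 features by default.
* **AF** — annotated features: database-derived binary flags and numeric
  scores attached to the mutation table (default schema: 29 features,
  14 binary + 15 numeric).

With the default configuration the assembled space is
15 + 51 + 31 + 29 = 126 features per mutation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .types import (
    AA_INDEX,
    AMINO_ACIDS,
    ConfigError,
    FeatureMatrix,
    MutationDataset,
    MutationRecord,
    ProteinRecord,
    ValidationError,
)
from .tables import PropertyScale, SubstitutionMatrix

#: Reduced 6-letter alphabet: physicochemical groups of the 20 residues.
#: Group 1 acidic/amide, 2 basic, 3 cysteine, 4 small/hydroxyl, 5 aliphatic,
#: 6 aromatic.
SIX_LETTER_GROUPS: dict[str, int] = {}
for _group, _members in enumerate(["DENQ", "HRK", "C", "STPAG", "MILV", "FYW"], 1):
    for _aa in _members:
        SIX_LETTER_GROUPS[_aa] = _group

N_GRAMS_20 = 400
N_GRAMS_6 = 36
N_GRAMS = N_GRAMS_20 + N_GRAMS_6  # 436


def gram_labels() -> list[str]:
    """Component labels of the 436-gram vector, in storage order.

    First the 400 ordered residue pairs (index = 20*i + j over the
    alphabetical 20-letter alphabet), then the 36 ordered group pairs
    (index = 400 + 6*(g1-1) + (g2-1)).
    """
    labels = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
    labels += [f"g{g1}{g2}" for g1 in range(1, 7) for g2 in range(1, 7)]
    return labels


GRAM_LABELS = gram_labels()


def gram_counts(sequence: str, normalize: bool = False) -> np.ndarray:
    """436-vector of 2-gram counts of a protein sequence.

    Components 0..399 count each ordered pair of consecutive residues over
    the 20-letter alphabet; components 400..435 count ordered pairs after
    mapping residues through the 6-letter alphabet. Each half sums to L-1.
    With ``normalize=True`` counts are divided by L-1 (frequencies).
    """
    if len(sequence) < 2:
        raise ValidationError("2-gram extraction needs sequence length >= 2")
    counts = np.zeros(N_GRAMS)
    try:
        idx = np.fromiter((AA_INDEX[aa] for aa in sequence), dtype=np.intp)
    except KeyError as exc:
        raise ValidationError(f"nonstandard residue {exc.args[0]!r}") from None
    pair20 = idx[:-1] * 20 + idx[1:]
    np.add.at(counts, pair20, 1.0)
    groups = np.fromiter(
        (SIX_LETTER_GROUPS[aa] - 1 for aa in sequence), dtype=np.intp
    )
    pair6 = N_GRAMS_20 + groups[:-1] * 6 + groups[1:]
    np.add.at(counts, pair6, 1.0)
    if normalize:
        counts /= len(sequence) - 1
    return counts


def encode_aarc(
    mut: MutationRecord, scales: Sequence[PropertyScale]
) -> np.ndarray:
    """Residue-change vector: component i = scale_i(wild) - scale_i(mutant)."""
    return np.array([s[mut.wild] - s[mut.mutant] for s in scales])


def encode_ssm(
    mut: MutationRecord, matrices: Sequence[SubstitutionMatrix]
) -> np.ndarray:
    """Matrix-lookup vector: component k = matrix_k[wild, mutant]."""
    return np.array([m[mut.wild, mut.mutant] for m in matrices])


def lcc(x: np.ndarray, mean_profile: np.ndarray) -> float:
    """Linear correlation coefficient between a gram vector and a profile.

    The Pearson product-moment correlation computed *across the 436
    components* in its population (n-weighted) closed form:

        LCC = (n Σ x x̄ - Σx Σx̄) / sqrt((n Σx² - (Σx)²)(n Σx̄² - (Σx̄)²))

    Returns NaN (with a warning) when either vector has zero variance
    across its components.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(mean_profile, dtype=float)
    if x.shape != m.shape or x.ndim != 1:
        raise ValidationError(
            f"LCC needs two equal-length vectors, got {x.shape} vs {m.shape}"
        )
    n = x.size
    sx, sm = x.sum(), m.sum()
    var_x = n * (x * x).sum() - sx * sx
    var_m = n * (m * m).sum() - sm * sm
    if var_x <= 0 or var_m <= 0:
        warnings.warn("LCC undefined: zero variance across gram components")
        return float("nan")
    return float((n * (x * m).sum() - sx * sm) / np.sqrt(var_x * var_m))


@dataclass(frozen=True)
class PssReducer:
    """Fitted reduction of the 436 raw gram components to top-k + LCC.

    ``selected_indices`` are the ``top_k`` gram components with the highest
    DX discriminant score on the training data (ties broken toward the lower
    component index); ``mean_profile`` is the per-component training mean
    used by the LCC. ``fit_sample_ids`` records which samples the reducer
    saw, so evaluation can refuse test matrices that leaked into fitting.
    """

    selected_indices: tuple[int, ...]
    mean_profile: np.ndarray
    fit_tag: str
    fit_sample_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        idx = self.selected_indices
        if len(set(idx)) != len(idx):
            raise ConfigError("duplicate selected gram indices")
        if any(i < 0 or i >= N_GRAMS for i in idx):
            raise ConfigError(f"gram index out of range [0, {N_GRAMS})")
        profile = np.asarray(self.mean_profile, dtype=float)
        if profile.shape != (N_GRAMS,):
            raise ConfigError(f"mean profile shape {profile.shape} != ({N_GRAMS},)")
        object.__setattr__(self, "mean_profile", profile)

    @property
    def top_k(self) -> int:
        return len(self.selected_indices)

    @property
    def feature_names(self) -> list[str]:
        return [f"pss_{GRAM_LABELS[i]}" for i in self.selected_indices] + ["pss_lcc"]

    def transform(self, grams: np.ndarray) -> np.ndarray:
        """Reduce one 436-gram vector to (top-k selected grams, LCC)."""
        grams = np.asarray(grams, dtype=float)
        if grams.shape != (N_GRAMS,):
            raise ValidationError(f"expected a {N_GRAMS}-vector, got {grams.shape}")
        return np.append(grams[list(self.selected_indices)], lcc(grams, self.mean_profile))


def fit_pss_reducer(
    train_grams: np.ndarray,
    labels: Sequence[str],
    top_k: int = 30,
    domain: int = N_GRAMS,
    class_conditional_profile: bool = False,
    sample_ids: Sequence[str] | None = None,
    on_constant: str = "error",
) -> PssReducer:
    """Rank gram components by DX score on training data and keep the top k.

    ``domain`` restricts the ranking to the first ``domain`` components
    (436 = both alphabets, the default; 400 = 20-letter grams only). The
    mean profile is the per-component mean over all training samples, or the
    average of the two class means when ``class_conditional_profile`` is
    set. ``on_constant`` controls the degenerate all-constant case:
    ``"error"`` raises, ``"zero"`` keeps zero scores with index-order ties.
    """
    from .selection import dx_score

    grams = np.asarray(train_grams, dtype=float)
    if grams.ndim != 2 or grams.shape[1] != N_GRAMS:
        raise ValidationError(f"train grams must be n x {N_GRAMS}")
    labels = np.asarray(labels)
    if grams.shape[0] < 4:
        raise ValidationError("need at least 4 training samples to fit the reducer")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError("DX undefined without two classes")
    if domain not in (N_GRAMS_20, N_GRAMS):
        raise ConfigError(f"ranking domain must be {N_GRAMS_20} or {N_GRAMS}")
    if not 1 <= top_k <= domain:
        raise ConfigError(f"top_k={top_k} outside [1, {domain}]")

    scores = np.array(
        [dx_score(grams[:, j], labels) for j in range(domain)]
    )
    if np.all(scores == 0):
        if on_constant == "error":
            raise ValidationError(
                "all gram components are class-constant; DX ranking is degenerate"
            )
        if on_constant != "zero":
            raise ConfigError(f"unknown on_constant policy {on_constant!r}")
    # stable sort on negated scores: ties keep the lower component index
    order = np.argsort(-scores, kind="stable")
    selected = tuple(int(i) for i in order[:top_k])

    if class_conditional_profile:
        profile = np.mean(
            [grams[labels == c].mean(axis=0) for c in classes], axis=0
        )
    else:
        profile = grams.mean(axis=0)
    return PssReducer(
        selected_indices=selected,
        mean_profile=profile,
        fit_tag="class-mean profile" if class_conditional_profile else "train-mean profile",
        fit_sample_ids=frozenset(sample_ids or ()),
    )


# ---------------------------------------------------------------------------
# annotated features


@dataclass(frozen=True)
class AfSchema:
    """Expected annotated features: ordered (name, kind) with kind binary|numeric."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate annotated feature names in schema")
        bad = [(n, k) for n, k in self.entries if k not in ("binary", "numeric")]
        if bad:
            raise ConfigError(f"unknown annotated feature kind(s): {bad}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_json(cls, path) -> "AfSchema":
        raw = json.loads(Path(path).read_text())
        return cls(tuple((e["name"], e["kind"]) for e in raw))

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps([{"name": n, "kind": k} for n, k in self.entries], indent=1)
            + "\n"
        )


def encode_af(
    mut: MutationRecord,
    schema: AfSchema,
    missing_log: dict[str, int] | None = None,
) -> np.ndarray:
    """Annotated-feature vector in schema order.

    Missing binary values impute to 0 (absence-coded); missing numeric
    values stay NaN so a training-median imputer can fill them downstream.
    Each imputation increments ``missing_log`` when given. Binary values
    outside {0, 1} are rejected.
    """
    out = np.empty(len(schema))
    for i, (name, kind) in enumerate(schema.entries):
        value = mut.annotated.get(name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            if missing_log is not None:
                missing_log[name] = missing_log.get(name, 0) + 1
            out[i] = 0.0 if kind == "binary" else np.nan
        else:
            v = float(value)
            if kind == "binary" and v not in (0.0, 1.0):
                raise ValidationError(
                    f"{mut.sample_id}: binary annotated feature {name!r} "
                    f"has non-binary value {value!r}"
                )
            out[i] = v
    return out


class MedianImputer:
    """Training-median fill for NaN cells; principal-axis fits and trees
    require complete data, so imputation happens before any model fit."""

    def __init__(self) -> None:
        self.medians_: np.ndarray | None = None

    def fit(self, values: np.ndarray) -> "MedianImputer":
        values = np.asarray(values, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            med = np.nanmedian(values, axis=0)
        self.medians_ = np.where(np.isnan(med), 0.0, med)
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self.medians_ is None:
            raise ValidationError("imputer not fitted")
        values = np.asarray(values, dtype=float).copy()
        nan_r, nan_c = np.nonzero(np.isnan(values))
        values[nan_r, nan_c] = self.medians_[nan_c]
        return values

    def fit_transform(self, values: np.ndarray) -> np.ndarray:
        return self.fit(values).transform(values)


# ---------------------------------------------------------------------------
# assembly


def mutated_sequence(prot: ProteinRecord, mut: MutationRecord) -> str:
    seq = prot.sequence
    return seq[: mut.position - 1] + mut.mutant + seq[mut.position :]


@dataclass
class FeatureConfig:
    """Everything needed to turn a MutationDataset into a FeatureMatrix."""

    scales: Sequence[PropertyScale]
    matrices: Sequence[SubstitutionMatrix]
    af_schema: AfSchema
    pss_top_k: int = 30
    pss_sequence: str = "wild"  # or "mutant"
    pss_domain: int = N_GRAMS  # 436, or 400 to rank 20-letter grams only
    pss_class_conditional_profile: bool = False
    normalize_grams: bool = False

    def __post_init__(self) -> None:
        if self.pss_sequence not in ("wild", "mutant"):
            raise ConfigError(f"pss_sequence must be wild|mutant, got {self.pss_sequence!r}")

    @property
    def width(self) -> int:
        return (
            len(self.scales) + len(self.matrices) + (self.pss_top_k + 1) + len(self.af_schema)
        )


def default_config(**overrides) -> FeatureConfig:
    """The bundled 15-scale / 51-matrix / 29-AF configuration (126 features)."""
    from .tables import bundled_af_schema, bundled_matrices, bundled_scales

    kwargs = dict(
        scales=bundled_scales(),
        matrices=bundled_matrices(),
        af_schema=bundled_af_schema(),
    )
    kwargs.update(overrides)
    return FeatureConfig(**kwargs)


def dataset_grams(ds: MutationDataset, config: FeatureConfig) -> np.ndarray:
    """Per-mutation 436-gram vectors of each mutation's source sequence.

    With the default ``pss_sequence="wild"`` the vector depends only on the
    protein, so two mutations on one protein share a row; gram vectors are
    cached per protein accordingly.
    """
    cache: dict[str, np.ndarray] = {}
    rows = np.empty((len(ds), N_GRAMS))
    for i, mut in enumerate(ds.mutations):
        prot = ds.protein_of(mut)
        if config.pss_sequence == "wild":
            if prot.id not in cache:
                cache[prot.id] = gram_counts(prot.sequence, config.normalize_grams)
            rows[i] = cache[prot.id]
        else:
            rows[i] = gram_counts(mutated_sequence(prot, mut), config.normalize_grams)
    return rows


def fit_reducer(
    ds: MutationDataset, config: FeatureConfig, labels: Sequence[str] | None = None
) -> PssReducer:
    """Fit the PSS reduction on a *training* dataset (labels required)."""
    labels = list(labels) if labels is not None else [m.label for m in ds.mutations]
    if any(l is None for l in labels):
        raise ValidationError("fitting the PSS reducer requires labeled mutations")
    return fit_pss_reducer(
        dataset_grams(ds, config),
        labels,
        top_k=config.pss_top_k,
        domain=config.pss_domain,
        class_conditional_profile=config.pss_class_conditional_profile,
        sample_ids=ds.sample_ids,
    )


def assemble_features(
    ds: MutationDataset,
    config: FeatureConfig,
    reducer: PssReducer,
    warn_imputations: bool = True,
) -> FeatureMatrix:
    """Concatenate AARC ‖ SSM ‖ PSS ‖ AF for every mutation.

    The reducer must have been fitted on the training partition only; fit it
    with :func:`fit_reducer` before calling, and never on test samples.
    Feature names are globally unique and stable across runs.
    """
    if reducer.top_k != config.pss_top_k:
        raise ConfigError(
            f"reducer keeps {reducer.top_k} grams but config expects {config.pss_top_k}"
        )
    names = (
        [f"aarc_{s.name}" for s in config.scales]
        + [f"ssm_{m.name}" for m in config.matrices]
        + reducer.feature_names
        + [f"af_{n}" for n in config.af_schema.names]
    )
    provenance = {}
    for n in names:
        provenance[n] = n.split("_", 1)[0].upper()
    grams = dataset_grams(ds, config)
    missing_log: dict[str, int] = {}
    rows = []
    for i, mut in enumerate(ds.mutations):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # LCC NaN warnings surface per-matrix below
            pss = reducer.transform(grams[i])
        rows.append(
            np.concatenate(
                [
                    encode_aarc(mut, config.scales),
                    encode_ssm(mut, config.matrices),
                    pss,
                    encode_af(mut, config.af_schema, missing_log),
                ]
            )
        )
    values = np.vstack(rows) if rows else np.empty((0, len(names)))
    if values.shape[1] != config.width:
        raise ConfigError(
            f"assembled width {values.shape[1]} != configured width {config.width}"
        )
    if missing_log and warn_imputations:
        total = sum(missing_log.values())
        warnings.warn(
            f"annotated features: {total} missing value(s) across "
            f"{len(missing_log)} feature(s) imputed/deferred"
        )
    return FeatureMatrix(ds.sample_ids, names, values, provenance)
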