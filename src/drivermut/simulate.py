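"""Synthetic driver/passenger mutation datasets with planted class signal.

The generator emulates a labeled missense-mutation study: random protein
sequences, mutations with driver/passenger labels, and class-informative
structure planted *mechanistically* in any subset of the four feature
channels, so the encoders themselves — not just downstream models — are
exercised:

* ``aarc``/``ssm`` — drivers preferentially pick substitutions with a
  large hydropathy change, so property-difference and matrix-lookup
  features separate the classes;
* ``pss`` — driver mutations sit on proteins whose sequences carry a
  dipeptide bias (a first-order preference for staying within the same
  physicochemical group), separating 2-gram counts;
* ``af`` — a fixed subset of annotated features is drawn with
  class-shifted parameters (Bernoulli rates / Gaussian means).

``effect_size`` is the *aggregate* class separation of a planted feature
block, in units of feature standard deviation: when a channel plants m
features directly, each contributes effect_size/sqrt(m), so the
Mahalanobis distance between the classes is effect_size regardless of m
and adding planted features never trivializes the problem. 0 produces a
pure null dataset. A fast "direct tabular" mode
(:func:`simulate_feature_table`) writes feature values directly for
selection/classifier unit tests where the encoders are not under test.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as _KD  # Kyte-Doolittle hydropathy

from .types import (
    AMINO_ACIDS,
    ConfigError,
    DRIVER,
    FeatureMatrix,
    MutationDataset,
    MutationRecord,
    PASSENGER,
    ProteinRecord,
)
from .features import SIX_LETTER_GROUPS

CHANNELS = ("aarc", "ssm", "pss", "af")

#: annotated features that carry signal when the ``af`` channel is informative
INFORMATIVE_AF_BINARY = ("in_catalytic_site", "in_binding_site", "ptm_site")
INFORMATIVE_AF_NUMERIC = (
    "conservation_score",
    "disorder_score",
    "interaction_partners",
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one synthetic dataset."""

    n_proteins: int = 24
    length_range: tuple[int, int] = (80, 200)
    n_driver: int = 100
    n_passenger: int = 100
    informative_channels: tuple[str, ...] = ("aarc", "ssm", "af")
    effect_size: float = 2.0
    af_missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_proteins, self.n_driver, self.n_passenger) <= 0:
            raise ConfigError("counts must be positive")
        lo, hi = self.length_range
        if not 2 <= lo <= hi:
            raise ConfigError(f"bad length range {self.length_range}")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if not 0 <= self.af_missing_rate <= 1:
            raise ConfigError("af_missing_rate must be in [0, 1]")
        unknown = set(self.informative_channels) - set(CHANNELS)
        if unknown:
            raise ConfigError(f"unknown channel(s) {sorted(unknown)}")
        if self.effect_size > 0 and not self.informative_channels:
            raise ConfigError(
                "effect_size > 0 requires at least one informative channel"
            )


def _random_sequence(rng, length: int, within_group_bias: float) -> str:
    """Residues drawn iid, or via a first-order chain that prefers staying
    inside the current 6-letter group with strength ``within_group_bias``."""
    alphabet = np.array(list(AMINO_ACIDS))
    if within_group_bias == 0:
        return "".join(rng.choice(alphabet, size=length))
    groups = np.array([SIX_LETTER_GROUPS[aa] for aa in AMINO_ACIDS])
    seq = [rng.choice(alphabet)]
    for _ in range(length - 1):
        prev_group = SIX_LETTER_GROUPS[seq[-1]]
        weights = np.exp(within_group_bias * (groups == prev_group))
        seq.append(rng.choice(alphabet, p=weights / weights.sum()))
    return "".join(seq)


def _mutant_for(rng, wild: str, driver: bool, delta_bias: float) -> str:
    """Pick the mutant residue; drivers lean toward large |Δhydropathy|."""
    others = [aa for aa in AMINO_ACIDS if aa != wild]
    if not driver or delta_bias == 0:
        return others[rng.integers(len(others))]
    deltas = np.array([abs(_KD[wild] - _KD[aa]) for aa in others])
    weights = np.exp(delta_bias * deltas / deltas.std())
    return others[rng.choice(len(others), p=weights / weights.sum())]


def _annotated_for(rng, cfg: SimConfig, driver: bool, schema) -> dict:
    informative = "af" in cfg.informative_channels
    m = len(INFORMATIVE_AF_BINARY) + len(INFORMATIVE_AF_NUMERIC)
    eff = cfg.effect_size / np.sqrt(m)  # per-feature share of the separation
    values: dict[str, float | None] = {}
    for name, kind in schema.entries:
        if kind == "binary":
            p = 0.5
            if informative and name in INFORMATIVE_AF_BINARY:
                shift = min(0.45, 0.25 * eff)
                p = 0.5 + shift if driver else 0.5 - shift
            v = float(rng.random() < p)
        else:
            mu = 0.0
            if informative and name in INFORMATIVE_AF_NUMERIC:
                mu = (eff / 2.0) if driver else -(eff / 2.0)
            v = float(rng.normal(mu, 1.0))
        if rng.random() < cfg.af_missing_rate:
            values[name] = None
        else:
            values[name] = v
    return values


def simulate_dataset(cfg: SimConfig):
    """Generate a :class:`MutationDataset` plus a ground-truth record.

    Deterministic given ``cfg.seed``. The ground truth lists the planted
    channels and the annotated features that carry signal.
    """
    from .tables import bundled_af_schema

    rng = np.random.default_rng(cfg.seed)
    schema = bundled_af_schema()
    pss_on = "pss" in cfg.informative_channels and cfg.effect_size > 0
    sub_on = (
        ("aarc" in cfg.informative_channels or "ssm" in cfg.informative_channels)
        and cfg.effect_size > 0
    )

    lo, hi = cfg.length_range
    proteins: list[ProteinRecord] = []
    latent: list[bool] = []  # True = driver-pool protein (pss signal only)
    for i in range(cfg.n_proteins):
        is_driver_pool = i % 2 == 0
        bias = (0.35 * cfg.effect_size) if (pss_on and is_driver_pool) else 0.0
        seq = _random_sequence(rng, int(rng.integers(lo, hi + 1)), bias)
        proteins.append(ProteinRecord(f"prot{i:03d}", seq))
        latent.append(is_driver_pool)

    mutations: list[MutationRecord] = []
    seen: set[tuple] = set()
    for label, count in ((DRIVER, cfg.n_driver), (PASSENGER, cfg.n_passenger)):
        driver = label == DRIVER
        if pss_on:
            pool = [p for p, d in zip(proteins, latent) if d == driver]
        else:
            pool = proteins
        made = 0
        attempts = 0
        while made < count:
            attempts += 1
            if attempts > 200 * count:
                raise ConfigError(
                    "could not place enough unique mutations; enlarge proteins"
                )
            prot = pool[rng.integers(len(pool))]
            position = int(rng.integers(1, len(prot) + 1))
            wild = prot.sequence[position - 1]
            mutant = _mutant_for(rng, wild, driver, cfg.effect_size if sub_on else 0.0)
            key = (prot.id, position, wild, mutant)
            if key in seen:
                continue
            seen.add(key)
            mutations.append(
                MutationRecord(
                    protein_id=prot.id,
                    position=position,
                    wild=wild,
                    mutant=mutant,
                    annotated=_annotated_for(rng, cfg, driver, schema),
                    label=label,
                )
            )
            made += 1
    # interleave classes so file order carries no label information
    order = rng.permutation(len(mutations))
    mutations = [mutations[i] for i in order]

    ground_truth = {
        "channels": sorted(cfg.informative_channels) if cfg.effect_size > 0 else [],
        "effect_size": cfg.effect_size,
        "informative_af_features": (
            [f"af_{n}" for n in INFORMATIVE_AF_BINARY + INFORMATIVE_AF_NUMERIC]
            if ("af" in cfg.informative_channels and cfg.effect_size > 0)
            else []
        ),
        "signal_property": "hydropathy (Kyte-Doolittle)" if sub_on else None,
        "seed": cfg.seed,
        "n_driver": cfg.n_driver,
        "n_passenger": cfg.n_passenger,
    }
    return MutationDataset(proteins, mutations), ground_truth


def write_fixture(ds: MutationDataset, directory, ground_truth=None, force=False):
    """Emit sequences.fasta + mutations.tsv (+ ground_truth.json) to a dir."""
    from .io import write_fasta, write_mutations

    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()):
        if not force:
            raise ConfigError(f"{directory} exists and is not empty (use force)")
        shutil.rmtree(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.proteins.values(), directory / "sequences.fasta")
    write_mutations(ds.mutations, directory / "mutations.tsv")
    if ground_truth is not None:
        (directory / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=1) + "\n"
        )
    return directory


# ---------------------------------------------------------------------------
# direct tabular mode


def simulate_feature_table(
    n_samples: int = 200,
    n_features: int = 100,
    n_informative: int = 5,
    effect_size: float = 4.0,
    seed: int = 0,
    shuffle_columns: bool = True,
):
    """Write feature values directly: ``n_informative`` unit-variance Gaussian
    columns whose class means differ by effect_size/sqrt(n_informative)
    each (aggregate separation = effect_size), the rest pure noise.

    Returns (FeatureMatrix, labels, ground_truth). Fast path for selection
    and classifier tests where the sequence encoders are not under test.
    """
    if not 0 <= n_informative <= n_features:
        raise ConfigError("n_informative outside [0, n_features]")
    rng = np.random.default_rng(seed)
    half = n_samples // 2
    labels = np.array([DRIVER] * half + [PASSENGER] * (n_samples - half))
    values = rng.normal(0.0, 1.0, size=(n_samples, n_features))
    signs = np.where(labels == DRIVER, 1.0, -1.0)
    cols = np.arange(n_features)
    if shuffle_columns:
        cols = rng.permutation(n_features)
    informative_cols = cols[:n_informative]
    per_feature = effect_size / np.sqrt(max(n_informative, 1))
    for j in informative_cols:
        values[:, j] += signs * per_feature / 2.0
    names = [f"f{j:03d}" for j in range(n_features)]
    fm = FeatureMatrix(
        sample_ids=[f"s{i:04d}" for i in range(n_samples)],
        feature_names=names,
        values=values,
        provenance={n: "AF" for n in names},
    )
    truth = {"informative_features": sorted(names[j] for j in informative_cols)}
    return fm, labels, truth
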