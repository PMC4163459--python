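"""Domain types shared by every stage of the pipeline.

A *missense mutation* is a single-residue substitution in a protein. The
package classifies such mutations into *drivers* (cancer-promoting, the
positive class) and *passengers* (selectively neutral, the negative class).
Positions are 1-based everywhere a user can see them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: The 20 standard amino-acid one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Ambiguity / nonstandard letters that may appear in real FASTA files.
NONSTANDARD_RESIDUES = frozenset("BZXUO")

DRIVER = "driver"
PASSENGER = "passenger"
LABELS = (DRIVER, PASSENGER)

#: Feature provenance families.
FAMILIES = ("AARC", "SSM", "PSS", "AF")


class DrivermutError(Exception):
    """Base class for all package errors."""


class FormatError(DrivermutError):
    """Malformed input file (FASTA / TSV / schema)."""


class ValidationError(DrivermutError):
    """Structurally valid input that violates a domain invariant."""


class ConfigError(DrivermutError):
    """Inconsistent or incomplete configuration."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 standard residues."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValidationError(
                f"protein {self.id!r}: sequence length {len(self.sequence)} < 2 "
                "(2-gram extraction needs at least one residue pair)"
            )
        bad = sorted(set(self.sequence) - set(AMINO_ACIDS))
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: nonstandard residue(s) {''.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MutationRecord:
    """One missense mutation: ``wild`` at 1-based ``position`` becomes ``mutant``.

    ``annotated`` carries database-derived attributes of the mutation
    (binary flags and numeric scores); values may be missing (``None``).
    ``label`` is ``"driver"``, ``"passenger"`` or ``None`` for unlabeled data.
    """

    protein_id: str
    position: int
    wild: str
    mutant: str
    annotated: Mapping[str, float | None] = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"{self.protein_id}: position {self.position} is not 1-based positive"
            )
        for role, res in (("wild", self.wild), ("mutant", self.mutant)):
            if res not in AA_INDEX:
                raise ValidationError(
                    f"{self.protein_id}:{self.position}: {role} residue {res!r} "
                    "is not a standard amino acid"
                )
        if self.wild == self.mutant:
            raise ValidationError(
                f"{self.protein_id}:{self.position}: {self.wild}->{self.mutant} "
                "is not missense (wild == mutant)"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(
                f"{self.protein_id}:{self.position}: label {self.label!r} "
                f"not in {LABELS}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.protein_id, self.position, self.wild, self.mutant)

    @property
    def sample_id(self) -> str:
        """Stable identifier, e.g. ``p1:D3E`` (the field's mutation notation)."""
        return f"{self.protein_id}:{self.wild}{self.position}{self.mutant}"


class MutationDataset:
    """Proteins plus an ordered collection of mutations resolved against them.

    Every mutation must reference a known protein, its wild residue must match
    the sequence at its position, and duplicate (protein, position, wild,
    mutant) tuples are rejected.
    """

    def __init__(
        self,
        proteins: Sequence[ProteinRecord],
        mutations: Sequence[MutationRecord],
    ) -> None:
        self.proteins: dict[str, ProteinRecord] = {}
        for prot in proteins:
            if prot.id in self.proteins:
                raise ValidationError(f"duplicate protein id {prot.id!r}")
            self.proteins[prot.id] = prot
        self.mutations: list[MutationRecord] = []
        seen: set[tuple] = set()
        for mut in mutations:
            prot = self.proteins.get(mut.protein_id)
            if prot is None:
                raise ValidationError(
                    f"mutation {mut.sample_id}: unknown protein {mut.protein_id!r}"
                )
            if mut.position > len(prot):
                raise ValidationError(
                    f"mutation {mut.sample_id}: position beyond sequence "
                    f"length {len(prot)}"
                )
            if prot.sequence[mut.position - 1] != mut.wild:
                raise ValidationError(
                    f"mutation {mut.sample_id}: wild residue {mut.wild} does not "
                    f"match sequence ({prot.sequence[mut.position - 1]} at "
                    f"position {mut.position})"
                )
            if mut.key in seen:
                raise ValidationError(f"duplicate mutation {mut.sample_id}")
            seen.add(mut.key)
            self.mutations.append(mut)

    def __len__(self) -> int:
        return len(self.mutations)

    def protein_of(self, mut: MutationRecord) -> ProteinRecord:
        return self.proteins[mut.protein_id]

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.mutations]

    @property
    def labels(self) -> list[str | None]:
        return [m.label for m in self.mutations]

    @property
    def annotated_feature_names(self) -> list[str]:
        names: list[str] = []
        for mut in self.mutations:
            for name in mut.annotated:
                if name not in names:
                    names.append(name)
        return names


class FeatureMatrix:
    """Samples x named features, with per-feature provenance (AARC/SSM/PSS/AF).

    Missing values are ``NaN``. Feature names are unique and provenance covers
    every feature.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        feature_names: Sequence[str],
        values: np.ndarray,
        provenance: Mapping[str, str],
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (len(sample_ids), len(feature_names)):
            raise ValidationError(
                f"value grid {values.shape} does not match "
                f"{len(sample_ids)} samples x {len(feature_names)} features"
            )
        if len(set(feature_names)) != len(feature_names):
            raise ValidationError("feature names are not unique")
        missing_prov = [n for n in feature_names if n not in provenance]
        if missing_prov:
            raise ValidationError(
                f"provenance missing for feature(s): {missing_prov[:5]}"
            )
        bad_fam = {f: p for f, p in provenance.items() if p not in FAMILIES}
        if bad_fam:
            raise ValidationError(f"unknown provenance families: {bad_fam}")
        self.sample_ids = list(sample_ids)
        self.feature_names = list(feature_names)
        self.values = values
        self.provenance = dict(provenance)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given order (used by IFS prefixes)."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            self.sample_ids,
            list(names),
            self.values[:, idx],
            {n: self.provenance[n] for n in names},
        )

    def family_counts(self) -> dict[str, int]:
        counts = {fam: 0 for fam in FAMILIES}
        for name in self.feature_names:
            counts[self.provenance[name]] += 1
        return counts


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/TN/FN counts; positives are driver mutations."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"{name}={v} is not a nonnegative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def scaled(self, k: int) -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp * k, self.fp * k, self.tn * k, self.fn * k)


def is_missing(value: float | None) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))
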