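"""Amino-acid property scales and substitution matrices.

Both kinds of table are read from residue-labelled TSV files, one file per
table, mirroring the flat layout of the AAindex database: a property scale
is a single residue -> value column; a substitution matrix is a full 20x20
grid indexed (wild row, mutant column). Symmetry of matrices is *not*
assumed — features look up the ordered (wild, mutant) element.

The package bundles a documented default set of 15 scales and 51 matrices
(see ``data/``); both are fully swappable via directories of TSVs, since the
pipeline's structure depends on the counts, not the identities.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .types import AA_INDEX, AMINO_ACIDS, ConfigError, FormatError


@dataclass(frozen=True)
class PropertyScale:
    """A physicochemical property: one finite value per standard residue."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [aa for aa in AMINO_ACIDS if aa not in self.values]
        if missing:
            raise ConfigError(
                f"scale {self.name!r} is missing residue(s) {''.join(missing)}"
            )
        extra = [aa for aa in self.values if aa not in AA_INDEX]
        if extra:
            raise ConfigError(f"scale {self.name!r} has unknown residue(s) {extra}")
        bad = [aa for aa, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ConfigError(f"scale {self.name!r} has non-finite value(s) at {bad}")

    def __getitem__(self, residue: str) -> float:
        try:
            return float(self.values[residue])
        except KeyError:
            raise ConfigError(
                f"scale {self.name!r} has no value for residue {residue!r}"
            ) from None


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A 20x20 scoring grid; entry (wild, mutant) scores that substitution."""

    name: str
    grid: np.ndarray  # indexed by AA_INDEX on both axes

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        if grid.shape != (20, 20):
            raise ConfigError(f"matrix {self.name!r}: grid shape {grid.shape} != 20x20")
        if not np.all(np.isfinite(grid)):
            raise ConfigError(f"matrix {self.name!r}: non-finite entries")
        object.__setattr__(self, "grid", grid)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        wild, mutant = pair
        try:
            return float(self.grid[AA_INDEX[wild], AA_INDEX[mutant]])
        except KeyError:
            raise ConfigError(
                f"matrix {self.name!r} has no entry for {wild!r}->{mutant!r}"
            ) from None


# ---------------------------------------------------------------------------
# TSV round-trip


def read_scale_tsv(path) -> PropertyScale:
    path = Path(path)
    values: dict[str, float] = {}
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and ln[0] != "#"
    ]
    if not lines or lines[0].split("\t")[0] != "residue":
        raise FormatError(f"{path}: expected header 'residue\\tvalue'")
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: bad row {ln!r}")
        values[parts[0]] = float(parts[1])
    return PropertyScale(path.stem, values)


def write_scale_tsv(scale: PropertyScale, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("residue\tvalue\n")
        for aa in AMINO_ACIDS:
            fh.write(f"{aa}\t{scale.values[aa]:.6g}\n")


def read_matrix_tsv(path) -> SubstitutionMatrix:
    path = Path(path)
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and ln[0] != "#"
    ]
    header = lines[0].split("\t")
    if header[0] != "wild" or header[1:] != list(AMINO_ACIDS):
        raise FormatError(f"{path}: header must be 'wild' + the 20 residues")
    grid = np.full((20, 20), np.nan)
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 21 or parts[0] not in AA_INDEX:
            raise FormatError(f"{path}: bad row {ln!r}")
        grid[AA_INDEX[parts[0]], :] = [float(x) for x in parts[1:]]
    if np.isnan(grid).any():
        raise FormatError(f"{path}: incomplete grid")
    return SubstitutionMatrix(path.stem, grid)


def write_matrix_tsv(matrix: SubstitutionMatrix, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("wild\t" + "\t".join(AMINO_ACIDS) + "\n")
        for i, aa in enumerate(AMINO_ACIDS):
            fh.write(
                aa + "\t" + "\t".join(f"{float(v):.6g}" for v in matrix.grid[i]) + "\n"
            )


def load_scales(directory) -> list[PropertyScale]:
    """All ``*.tsv`` scales in a directory, sorted by file name."""
    paths = sorted(Path(directory).glob("*.tsv"))
    if not paths:
        raise ConfigError(f"no scale TSVs found in {directory}")
    return [read_scale_tsv(p) for p in paths]


def load_matrices(directory) -> list[SubstitutionMatrix]:
    paths = sorted(Path(directory).glob("*.tsv"))
    if not paths:
        raise ConfigError(f"no matrix TSVs found in {directory}")
    return [read_matrix_tsv(p) for p in paths]


# ---------------------------------------------------------------------------
# bundled defaults


def _data_dir(sub: str) -> Path:
    return Path(resources.files("drivermut")) / "data" / sub


def bundled_scales() -> list[PropertyScale]:
    """The 15 default property scales shipped with the package."""
    return load_scales(_data_dir("scales"))


def bundled_matrices() -> list[SubstitutionMatrix]:
    """The 51 default substitution matrices shipped with the package."""
    return load_matrices(_data_dir("matrices"))


def bundled_af_schema():
    from .features import AfSchema

    return AfSchema.from_json(Path(resources.files("drivermut")) / "data" / "af_schema.json")
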