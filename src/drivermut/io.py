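"""Readers and writers for the plain-text formats the pipeline exchanges.

Sequences travel as FASTA, mutation tables as TSV with a header, feature
matrices as TSV plus a JSON provenance sidecar, rankings and evaluation
reports as TSV/JSON. Positions are 1-based in every file.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    AMINO_ACIDS,
    FeatureMatrix,
    FormatError,
    MutationDataset,
    MutationRecord,
    NONSTANDARD_RESIDUES,
    ProteinRecord,
    ValidationError,
    is_missing,
)

REQUIRED_MUTATION_COLUMNS = ("protein_id", "position", "wild", "mutant")


def read_fasta(path, nonstandard: str = "reject") -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The record id is the first whitespace-delimited token of the header;
    wrapped sequence lines are joined; order is preserved. ``nonstandard``
    controls handling of ambiguity letters (B, Z, X, U, O): ``"reject"``
    (default) raises; ``"drop"`` skips the offending sequence with a warning.
    """
    if nonstandard not in ("reject", "drop"):
        raise ValueError(f"unknown nonstandard-residue policy {nonstandard!r}")
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Bio raises assorted parse errors
        raise FormatError(f"{path}: not valid FASTA ({exc})") from exc
    if not entries:
        raise FormatError(f"{path}: empty or headerless FASTA file")
    for entry in entries:
        rid = entry.id
        if rid in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rid!r}")
        seen.add(rid)
        seq = str(entry.seq).upper()
        odd = set(seq) - set(AMINO_ACIDS)
        if odd:
            if nonstandard == "drop" and odd <= NONSTANDARD_RESIDUES:
                import warnings

                warnings.warn(
                    f"{path}: dropping {rid!r} (nonstandard residue(s) "
                    f"{''.join(sorted(odd))})",
                    stacklevel=2,
                )
                continue
            raise FormatError(
                f"{path}: sequence {rid!r} contains nonstandard residue(s) "
                f"{''.join(sorted(odd))}"
            )
        records.append(ProteinRecord(rid, seq))
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for prot in proteins:
            fh.write(f">{prot.id}\n")
            for i in range(0, len(prot.sequence), width):
                fh.write(prot.sequence[i : i + width] + "\n")


def read_mutations(path) -> list[MutationRecord]:
    """Parse a mutation TSV into records (in file order).

    Required columns: protein_id, position (1-based), wild, mutant. An
    optional ``label`` column holds driver/passenger. Every remaining column
    is an annotated feature; empty cells become missing values.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty mutation table") from exc
    missing = [c for c in REQUIRED_MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    af_columns = [
        c for c in df.columns if c not in REQUIRED_MUTATION_COLUMNS and c != "label"
    ]
    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        row = row._asdict()
        raw_pos = row["position"]
        try:
            position = int(raw_pos)
        except ValueError:
            raise FormatError(
                f"{path}: line {i}: position {raw_pos!r} is not an integer"
            ) from None
        label = row.get("label") or None
        annotated: dict[str, float | None] = {}
        for col in af_columns:
            cell = row[col].strip()
            annotated[col] = float(cell) if cell != "" else None
        try:
            records.append(
                MutationRecord(
                    protein_id=row["protein_id"],
                    position=position,
                    wild=row["wild"],
                    mutant=row["mutant"],
                    annotated=annotated,
                    label=label,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from None
    return records


def write_mutations(mutations: Sequence[MutationRecord], path) -> None:
    """Inverse of :func:`read_mutations`; missing annotated values emit as ''."""
    path = Path(path)
    af_names: list[str] = []
    for mut in mutations:
        for name in mut.annotated:
            if name not in af_names:
                af_names.append(name)
    has_label = any(m.label is not None for m in mutations)
    cols = list(REQUIRED_MUTATION_COLUMNS) + (["label"] if has_label else []) + af_names
    with path.open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for mut in mutations:
            row = [mut.protein_id, str(mut.position), mut.wild, mut.mutant]
            if has_label:
                row.append(mut.label or "")
            for name in af_names:
                v = mut.annotated.get(name)
                row.append("" if is_missing(v) else format_number(v))
            fh.write("\t".join(row) + "\n")


def format_number(v: float) -> str:
    """Render floats compactly; integral values without a trailing .0."""
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


def build_dataset(proteins, mutations) -> MutationDataset:
    return MutationDataset(proteins, mutations)


# ---------------------------------------------------------------------------
# feature matrices, rankings, reports


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """TSV with sample_id + feature columns, plus `<path>.provenance.json`."""
    path = Path(path)
    df = pd.DataFrame(fm.values, columns=fm.feature_names)
    df.insert(0, "sample_id", fm.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(fm.provenance, indent=1) + "\n")


def read_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing sample_id column")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    if not sidecar.exists():
        raise FormatError(f"{path}: provenance sidecar {sidecar.name} not found")
    provenance = json.loads(sidecar.read_text())
    sample_ids = df["sample_id"].astype(str).tolist()
    names = [c for c in df.columns if c != "sample_id"]
    return FeatureMatrix(sample_ids, names, df[names].to_numpy(float), provenance)


def write_ranking(ranking, path) -> None:
    """Ranking TSV: rank, feature_name, score, method."""
    with Path(path).open("w") as fh:
        fh.write("rank\tfeature_name\tscore\tmethod\n")
        for rank, (name, score) in enumerate(
            zip(ranking.feature_names, ranking.scores), start=1
        ):
            score_s = "inf" if math.isinf(score) else repr(float(score))
            fh.write(f"{rank}\t{name}\t{score_s}\t{ranking.method}\n")


def read_ranking(path):
    from .selection import FeatureRanking

    df = pd.read_csv(path, sep="\t")
    for col in ("rank", "feature_name", "score", "method"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    return FeatureRanking(
        method=str(df["method"].iloc[0]),
        feature_names=df["feature_name"].astype(str).tolist(),
        scores=[float(s) for s in df["score"]],
    )


def write_ifs_curve(curve, path) -> None:
    """IFS curve TSV: k, mean_accuracy, variance."""
    with Path(path).open("w") as fh:
        fh.write("k\tmean_accuracy\tvariance\n")
        for k, mean, var in zip(curve.ks, curve.mean_accuracy, curve.variance):
            fh.write(f"{k}\t{mean!r}\t{var!r}\n")


def write_report_json(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(report, indent=1, default=_default) + "\n")


def write_metrics_tsv(rows: Sequence[dict], path) -> None:
    """One metric bundle per row; column order follows the first row."""
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to write")
    cols = list(rows[0].keys())
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    "" if is_missing(row[c]) else str(row[c]) for c in cols
                )
                + "\n"
            )
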