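"""Regenerate the bundled default property scales and substitution matrices.

The pipeline needs 15 amino-acid property scales and 51 substitution
matrices; their identities are configuration, not load-bearing structure.
The bundled defaults are:

* 15 scales — 11 published tables shipped with Biopython's ProtParam data
  (hydropathy, hydrophilicity, surface accessibility, flexibility, four
  hydrophobicity consensus/transfer scales, membrane propensity, residue
  mass) plus Grantham's (1974) composition/polarity/volume and residue
  isoelectric points, typed in below;
* 51 matrices — the 24 protein 20x20 matrices shipped with
  Bio.Align.substitution_matrices (BLOSUM/PAM families and friends), plus
  27 property-derived matrices: for each scale, the negated absolute
  property step -|s(i)-s(j)| ("step" matrices, 15) and for the first 12
  scales the negated squared step ("sqstep" matrices), so conservative
  substitutions score high — the same construction as classical
  physicochemical distance matrices.

Run from the repository root:  python scripts/make_default_tables.py
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils import ProtParamData

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from drivermut.types import AMINO_ACIDS, AA_INDEX
from drivermut.tables import (
    PropertyScale,
    SubstitutionMatrix,
    write_matrix_tsv,
    write_scale_tsv,
)

DATA = Path(__file__).resolve().parents[1] / "src" / "drivermut" / "data"

# Grantham R. (1974) Science 185:862-864 — composition, polarity, volume.
GRANTHAM_COMPOSITION = {
    "A": 0.0, "R": 0.65, "N": 1.33, "D": 1.38, "C": 2.75, "Q": 0.89, "E": 0.92,
    "G": 0.74, "H": 0.58, "I": 0.0, "L": 0.0, "K": 0.33, "M": 0.0, "F": 0.0,
    "P": 0.39, "S": 1.42, "T": 0.71, "W": 0.13, "Y": 0.20, "V": 0.0,
}
GRANTHAM_POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5, "E": 12.3,
    "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2,
    "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}
GRANTHAM_VOLUME = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
    "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
    "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
    "Y": 136.0, "V": 84.0,
}
ISOELECTRIC_POINT = {
    "A": 6.00, "R": 10.76, "N": 5.41, "D": 2.77, "C": 5.07, "Q": 5.65,
    "E": 3.22, "G": 5.97, "H": 7.59, "I": 6.02, "L": 5.98, "K": 9.74,
    "M": 5.74, "F": 5.48, "P": 6.30, "S": 5.68, "T": 5.60, "W": 5.89,
    "Y": 5.66, "V": 5.96,
}


def default_scales() -> list[PropertyScale]:
    g = ProtParamData.gravy_scales
    raw = {
        "hydropathy_kyte_doolittle": ProtParamData.kd,
        "hydrophilicity_hopp_woods": ProtParamData.hw,
        "surface_accessibility_emini": ProtParamData.em,
        "flexibility_vihinen": ProtParamData.Flex,
        "transfer_energy_janin": ProtParamData.ja,
        "hydrophobicity_eisenberg": g["Eisenberg"],
        "hydrophobicity_fauchere_pliska": g["Fauchere"],
        "membrane_propensity_engelman": g["Engelman"],
        "hydrophobicity_rose": g["Rose"],
        "hydrophobicity_tanford": g["Tanford"],
        "residue_mass": {aa: protein_weights[aa] for aa in AMINO_ACIDS},
        "grantham_composition": GRANTHAM_COMPOSITION,
        "grantham_polarity": GRANTHAM_POLARITY,
        "grantham_volume": GRANTHAM_VOLUME,
        "isoelectric_point": ISOELECTRIC_POINT,
    }
    return [PropertyScale(name, values) for name, values in raw.items()]


#: the 24 protein 20x20 matrices available in Bio.Align.substitution_matrices
BIOPYTHON_MATRICES = (
    "BENNER22", "BENNER6", "BENNER74", "BLASTP", "BLOSUM45", "BLOSUM50",
    "BLOSUM62", "BLOSUM80", "BLOSUM90", "DAYHOFF", "FENG", "GENETIC",
    "GONNET1992", "JOHNSON", "JONES", "LEVIN", "MCLACHLAN", "MDM78",
    "PAM250", "PAM30", "PAM70", "RAO", "RISLER", "STR",
)

#: scales whose squared-step matrix is also bundled (12, to reach 51 total)
SQSTEP_SCALES = (
    "hydropathy_kyte_doolittle", "hydrophilicity_hopp_woods",
    "surface_accessibility_emini", "flexibility_vihinen",
    "transfer_energy_janin", "hydrophobicity_eisenberg",
    "hydrophobicity_fauchere_pliska", "membrane_propensity_engelman",
    "hydrophobicity_rose", "hydrophobicity_tanford",
    "grantham_polarity", "grantham_volume",
)


def default_matrices(scales: list[PropertyScale]) -> list[SubstitutionMatrix]:
    out = []
    for name in BIOPYTHON_MATRICES:
        mat = substitution_matrices.load(name)
        grid = np.zeros((20, 20))
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                grid[AA_INDEX[a], AA_INDEX[b]] = mat[a, b]
        out.append(SubstitutionMatrix(name.lower(), grid))
    by_name = {s.name: s for s in scales}
    for scale in scales:
        vec = np.array([scale.values[aa] for aa in AMINO_ACIDS])
        step = -np.abs(vec[:, None] - vec[None, :])
        out.append(SubstitutionMatrix(f"step_{scale.name}", step))
    for name in SQSTEP_SCALES:
        vec = np.array([by_name[name].values[aa] for aa in AMINO_ACIDS])
        out.append(
            SubstitutionMatrix(f"sqstep_{name}", -((vec[:, None] - vec[None, :]) ** 2))
        )
    return out


#: default annotated-feature schema: 14 binary flags + 15 numeric scores = 29
AF_SCHEMA = [
    ("in_catalytic_site", "binary"),
    ("in_binding_site", "binary"),
    ("ptm_site", "binary"),
    ("disulfide_bond", "binary"),
    ("glycosylation_site", "binary"),
    ("transmembrane_region", "binary"),
    ("signal_peptide", "binary"),
    ("coiled_coil", "binary"),
    ("zinc_finger", "binary"),
    ("dna_binding_region", "binary"),
    ("repeat_region", "binary"),
    ("sequence_motif", "binary"),
    ("metal_binding", "binary"),
    ("propeptide", "binary"),
    ("conservation_score", "numeric"),
    ("disorder_score", "numeric"),
    ("interaction_partners", "numeric"),
    ("expression_level", "numeric"),
    ("gene_mutation_count", "numeric"),
    ("paralog_count", "numeric"),
    ("isoform_count", "numeric"),
    ("domain_count", "numeric"),
    ("relative_position", "numeric"),
    ("local_hydrophobicity", "numeric"),
    ("surface_accessibility", "numeric"),
    ("helix_fraction", "numeric"),
    ("sheet_fraction", "numeric"),
    ("alignment_depth", "numeric"),
    ("pfam_domain_length", "numeric"),
]


def main() -> None:
    scales = default_scales()
    matrices = default_matrices(scales)
    assert len(scales) == 15, len(scales)
    assert len(matrices) == 51, len(matrices)

    scale_dir = DATA / "scales"
    matrix_dir = DATA / "matrices"
    scale_dir.mkdir(parents=True, exist_ok=True)
    matrix_dir.mkdir(parents=True, exist_ok=True)
    for old in list(scale_dir.glob("*.tsv")) + list(matrix_dir.glob("*.tsv")):
        old.unlink()
    for scale in scales:
        write_scale_tsv(scale, scale_dir / f"{scale.name}.tsv")
    for matrix in matrices:
        write_matrix_tsv(matrix, matrix_dir / f"{matrix.name}.tsv")
    (DATA / "af_schema.json").write_text(
        json.dumps([{"name": n, "kind": k} for n, k in AF_SCHEMA], indent=1) + "\n"
    )
    print(f"wrote {len(scales)} scales, {len(matrices)} matrices, "
          f"{len(AF_SCHEMA)} annotated-feature schema entries under {DATA}")


if __name__ == "__main__":
    main()
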