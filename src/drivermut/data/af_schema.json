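[
 {
  "name": "in_catalytic_site",
  "kind": "binary"
 },
 {
  "name": "in_binding_site",
  "kind": "binary"
 },
 {
  "name": "ptm_site",
  "kind": "binary"
 },
 {
  "name": "disulfide_bond",
  "kind": "binary"
 },
 {
  "name": "glycosylation_site",
  "kind": "binary"
 },
 {
  "name": "transmembrane_region",
  "kind": "binary"
 },
 {
  "name": "signal_peptide",
  "kind": "binary"
 },
 {
  "name": "coiled_coil",
  "kind": "binary"
 },
 {
  "name": "zinc_finger",
  "kind": "binary"
 },
 {
  "name": "dna_binding_region",
  "kind": "binary"
 },
 {
  "name": "repeat_region",
  "kind": "binary"
 },
 {
  "name": "sequence_motif",
  "kind": "binary"
 },
 {
  "name": "metal_binding",
  "kind": "binary"
 },
 {
  "name": "propeptide",
  "kind": "binary"
 },
 {
  "name": "conservation_score",
  "kind": "numeric"
 },
 {
  "name": "disorder_score",
  "kind": "numeric"
 },
 {
  "name": "interaction_partners",
  "kind": "numeric"
 },
 {
  "name": "expression_level",
  "kind": "numeric"
 },
 {
  "name": "gene_mutation_count",
  "kind": "numeric"
 },
 {
  "name": "paralog_count",
  "kind": "numeric"
 },
 {
  "name": "isoform_count",
  "kind": "numeric"
 },
 {
  "name": "domain_count",
  "kind": "numeric"
 },
 {
  "name": "relative_position",
  "kind": "numeric"
 },
 {
  "name": "local_hydrophobicity",
  "kind": "numeric"
 },
 {
  "name": "surface_accessibility",
  "kind": "numeric"
 },
 {
  "name": "helix_fraction",
  "kind": "numeric"
 },
 {
  "name": "sheet_fraction",
  "kind": "numeric"
 },
 {
  "name": "alignment_depth",
  "kind": "numeric"
 },
 {
  "name": "pfam_domain_length",
  "kind": "numeric"
 }
]
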