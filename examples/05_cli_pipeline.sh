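#!/usr/bin/env bash
# Full pipeline through the command-line surface on a synthetic fixture.
# Every stage writes TSV/JSON artifacts plus a *.run.json provenance sidecar.
set -euo pipefail
out=$(mktemp -d)

drivermut simulate --out "$out/fixture" --n-driver 60 --n-passenger 60 \
    --effect-size 2.5 --seed 5
drivermut extract --sequences "$out/fixture/sequences.fasta" \
    --mutations "$out/fixture/mutations.tsv" --out "$out/features"
drivermut rank --features "$out/features/features.tsv" \
    --labels "$out/features/labels.tsv" --method dx --out "$out/dx.tsv"
drivermut ifs --features "$out/features/features.tsv" \
    --labels "$out/features/labels.tsv" --ranking "$out/dx.tsv" \
    --repeats 1 --max-k 15 --seed 3 --out "$out/curve.tsv"
drivermut train --features "$out/features/features.tsv" \
    --labels "$out/features/labels.tsv" --ranking "$out/dx.tsv" \
    --top-k best --curve "$out/curve.best.json" --seed 4 \
    --out "$out/model.joblib"
drivermut evaluate --features "$out/features/features.tsv" \
    --labels "$out/features/labels.tsv" --repeats 1 --seed 6 \
    --out "$out/cv"

echo
echo "=== CV report ==="
cat "$out/cv/report.tsv"
echo "artifacts under: $out"
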