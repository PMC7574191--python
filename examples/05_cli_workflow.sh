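#!/usr/bin/env bash
# Full shell workflow: simulate fixtures, search, annotate, compose.
set -euo pipefail
workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT

patternscan simulate --seed 11 --out-dir "$workdir/sim"

patternscan search \
  --pattern "$workdir/sim/pattern.json" \
  --track markA="$workdir/sim/markA.bed" \
  --track markB="$workdir/sim/markB.bed" \
  --track cofactor1="$workdir/sim/cofactor1.bed" \
  --track cofactor2="$workdir/sim/cofactor2.bed" \
  --min-score 0.5 \
  --out-prefix "$workdir/run"

echo "--- run log ---"
cat "$workdir/run.log"
echo "--- top 5 matchings (BED: span + 1000*score) ---"
head -5 "$workdir/run.bed"

patternscan compose --results "$workdir/run"
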