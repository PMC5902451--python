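#!/bin/sh
# The same pipeline from the shell: simulate a benchmark, calibrate the
# weight model, score and rank the SAP table, cross-validate, and run the
# burden survival comparison.  Every step writes a provenance.json that
# reproduces it bit-identically.
set -e
OUT=${1:-/tmp/sapnet_demo}

sapnet simulate --seed 0 --n-nodes 300 --n-deleterious 120 \
    --n-neutral 360 --outdir "$OUT/bench"

COMMON="--network $OUT/bench/edges.tsv \
        --cancer-genes $OUT/bench/cancer_genes.txt \
        --interfaces $OUT/bench/interfaces.tsv \
        --saps $OUT/bench/saps.tsv --sift $OUT/bench/sift.tsv"

sapnet calibrate $COMMON --outdir "$OUT/model"
sapnet score $COMMON --model "$OUT/model/calibration.json" --outdir "$OUT/scores"
sapnet evaluate $COMMON --k-folds 10 --seed 0 --outdir "$OUT/eval"
sapnet survival --scores "$OUT/scores/scores.tsv" \
    --saps "$OUT/bench/saps.tsv" --survival "$OUT/bench/survival.tsv" \
    --outdir "$OUT/prognosis"

echo "outputs under $OUT"
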