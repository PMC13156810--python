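#!/usr/bin/env bash
# End-to-end desk-scale run: cohort -> train both stages -> predict ->
# quantify -> evaluate, all seeded. Takes a few minutes on one CPU.
set -euo pipefail

OUT=${1:-desk_run}
SEED=${2:-7}

caroseg cohort    --profile desk --seed "$SEED" --n-lesions 8 --out "$OUT/cohort"
caroseg train-loc --profile desk --seed "$SEED" --manifest "$OUT/cohort/manifest.csv" --out "$OUT/models"
caroseg train-seg --profile desk --seed "$SEED" --manifest "$OUT/cohort/manifest.csv" \
                  --locnet-ckpt "$OUT/models/locnet.npz" --out "$OUT/models"
caroseg predict   --profile desk --seed "$SEED" --image "$OUT/cohort/lesion_000_image.nii.gz" \
                  --model-dir "$OUT/models" --out "$OUT/pred"
caroseg quantify  --profile desk --seed "$SEED" --mask "$OUT/pred/prediction.nii.gz" --out "$OUT/pred" --plot
caroseg evaluate  --profile desk --pred "$OUT/pred/prediction.nii.gz" \
                  --truth "$OUT/cohort/lesion_000_label.nii.gz" --out "$OUT/eval"

echo "reports in $OUT/{pred,eval}"
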