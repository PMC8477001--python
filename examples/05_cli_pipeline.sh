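#!/usr/bin/env bash
# The same analysis as a shell pipeline: simulate a study, run the full
# filter -> cluster -> annotate -> test chain, then summarise it.
set -euo pipefail

apa3t simulate --seed 1 -o sim_cli --n-genes 100 --n-traps 10
apa3t run -c sim_cli/config.json
apa3t report sim_cli/run

echo
echo "== shift summary =="
cat sim_cli/run/report_shift_summary.tsv
echo
echo "== genomic categories =="
cat sim_cli/run/report_categories.tsv
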