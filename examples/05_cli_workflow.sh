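#!/bin/sh
# The same pipeline from the shell: simulate -> train -> sort -> evaluate.
# Writes a synthetic session (SpikeGLX-style .bin/.meta + probe.tsv),
# learns a template bank, stream-sorts the recording into phy-style
# output, and summarizes matches/decoding between two sorted outputs.
set -e

livesort simulate --out session/ --seed 1
livesort train --rec session/ --out session/bank.npz --train-seconds 60
livesort sort --rec session/ --bank session/bank.npz --batch-ms 1000 --out session/sorted/
livesort evaluate --sorted session/sorted/ --trials session/trials.csv --out session/report/
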