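#!/usr/bin/env python
"""Simulate the full synthetic study: allele-resolved counts with
class-shifted burst kinetics, a decay time course, and a cell-cycle dataset.

Writes counts, annotation and ground truth under results/run/. Downstream
drivers (02-07) read from there, mirroring the pipeline's stage order.
"""

from burstlnc.cli import run_stage

from study_config import OUT, config

if __name__ == "__main__":
    cfg = config()
    run_stage("simulate", cfg, OUT)
    print(f"simulated dataset written to {OUT}/ (400 genes x 200 cells, "
          "60 decay genes, 300 cell-cycle cells; seed 1)")
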