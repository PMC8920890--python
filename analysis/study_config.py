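"""Shared configuration for the numbered analysis drivers.

The QC preset thresholds default to the published full-scale values; the
count-depth screens are rescaled here to the simulated library depth
(~4,500 molecules per cell over 400 genes) so the same machinery runs
meaningfully at desk scale.
"""

from burstlnc.config import PipelineConfig

OUT = "results/run"

SETTINGS = {
    "seed": 1,
    "qc": {
        "threshold_overrides": {
            "min_reads": 1_000,
            "min_genes": 100,
        },
    },
}


def config(**extra) -> PipelineConfig:
    merged = {**SETTINGS}
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key] = {**merged[key], **value}
        else:
            merged[key] = value
    return PipelineConfig(settings=merged)
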