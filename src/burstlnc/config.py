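"""Pipeline configuration: every threshold used by a stage, with its default.

Defaults mirror the published analysis settings (QC presets, locus windows,
kinetic filters, permutation sizes). A config can be loaded from / dumped to
YAML; seeds are carried into all output metadata so stage outputs are
reproducible byte for byte.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["PipelineConfig", "QC_PRESETS", "ConfigError"]


class ConfigError(ValueError):
    pass


# Cell-level QC presets. Thresholds are minima unless the key says otherwise.
QC_PRESETS: dict[str, dict[str, Any]] = {
    # Smart-seq2 primary fibroblasts: read-count data with allelic-balance
    # and imprinted-X screens.
    "smartseq2_fibro": {
        "min_reads": 500_000,
        "min_genes": 4_000,
        "gene_detect_count": 5,
        "allelic_balance_low": -0.10,
        "allelic_balance_high": 0.10,
        "max_imprinted_x_fraction": 0.20,
    },
    # Smart-seq3 fibroblasts treated with siRNAs.
    "smartseq3_fibro": {
        "min_exon_reads": 100_000,
        "min_umis": 50_000,
        "min_genes": 5_000,
        "gene_detect_count": 1,
    },
    "hek_ss3": {
        "min_exon_reads": 500_000,
        "min_genes": 7_500,
        "gene_detect_count": 1,
    },
    "mesc_ss2": {
        "min_exon_reads": 400_000,
        "min_genes": 8_000,
        "gene_detect_count": 5,
    },
}

_DEFAULTS: dict[str, Any] = {
    "simulate": {
        "n_mrna": 200,
        "n_lnc": 200,
        "n_cells": 200,
        "n_decay_genes": 60,
        "snp_capture_prob": 1.0,
    },
    "qc": {
        "preset": "smartseq2_fibro",
        # preset thresholds are the published values; overrides rescale
        # individual screens (e.g. count depth on desk-scale simulations)
        "threshold_overrides": None,
        "gene_min_count": 5,
        "gene_min_cells": 2,
    },
    "windows": {
        # base pairs
        "divergent_max_tss": 500,
        "convergent_max_tss": 2_000,
        "separated_min_tss": 4_000,
        "unidirectional_min_tss": 10_000,
        "cis_window": 500_000,
    },
    "variability": {
        "n_matched": 10,
        "n_perm": 10_000,
        "rank_pool": 100,
        "n_top_lnc": 50,
        "subsample_sizes": [10, 200],
        "subsample_reps": 100,
    },
    "kinetics": {
        "min_umi": 1,
        "min_cells": 5,
        "size_low": 0.2,
        "size_high": 50.0,
        "freq_low": 0.01,
        "freq_high": 30.0,
        "mean_low": 0.01,
        "mean_high": 100.0,
        "ci_ratio_max": 10 ** 1.5,
        "n_boot": 1_000,
        "max_genes": None,
        "lrt_critical_one_sided": 3.84,
        "lrt_critical_two_sided": 7.68,
        "quad_nodes": 50,
    },
    "decay": {
        "time_points": [0.0, 2.0, 4.0, 7.0, 10.0],
        "control_half_life_low": 1.0,
        "control_half_life_high": 8.0,
        "late_exclude_half_life": 2.0,
        "late_time_points": [7.0, 10.0],
        "max_half_life": 10.0,
        "max_burst_duration": 72.0,
        "min_t0_counts": 10,
        "min_control_t0_counts": 50,
    },
    "cis": {
        "min_allelic_reads": 3,
        "min_cells": 20,
        "n_locations": 1_000,
        "score_alpha": 0.05,
        "fisher_alpha": 0.01,
        "background_fraction": 0.01,
        "min_neighbour_genes": 2,
    },
    "state": {
        "scale_factor": 10_000,
        "n_variable_genes": 50,
        "n_pcs": 3,
        "rolling_window": 15,
        "anova_alpha": 0.01,
        "apoptosis_n_top": 75,
        "apoptosis_k": 3,
        "spearman_threshold": 0.1,
    },
    "seed": 0,
    "paths": {"input": ".", "output": "results"},
}


def _deep_update(base: dict, upd: dict) -> dict:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


@dataclass
class PipelineConfig:
    """Validated bundle of all stage settings."""

    settings: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(_DEFAULTS))

    def __post_init__(self) -> None:
        if self.settings is None:
            self.settings = copy.deepcopy(_DEFAULTS)
        merged = copy.deepcopy(_DEFAULTS)
        _deep_update(merged, self.settings)
        self.settings = merged
        if self.settings["qc"]["preset"] not in QC_PRESETS:
            raise ConfigError(
                f"unknown QC preset {self.settings['qc']['preset']!r}; "
                f"known: {sorted(QC_PRESETS)}"
            )
        for key in ("n_perm", "rank_pool", "subsample_reps"):
            if self.settings["variability"][key] <= 0:
                raise ConfigError(f"variability.{key} must be positive")
        for key, value in self.settings["windows"].items():
            if not isinstance(value, int) or value < 0:
                raise ConfigError(f"windows.{key} must be a non-negative integer")

    def __getitem__(self, key: str) -> Any:
        return self.settings[key]

    @property
    def seed(self) -> int:
        return int(self.settings["seed"])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(settings=data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.settings, fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the resolved settings, recorded in output metadata."""
        import hashlib

        blob = yaml.safe_dump(self.settings, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
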