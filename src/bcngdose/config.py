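"""Configuration objects for the synthetic cohort and the downstream analysis.

``SimulationConfig`` pins down every stochastic ingredient of the synthetic
study: cohort composition, per-region aberration frequencies, the
negative-binomial expression model and the multiplicative gene-dosage model
in which a transcript with copy number CN and sensitivity exponent ``s``
scales its expected expression by ``(CN / 2) ** s``.  A single integer seed
drives one generator stream, so identical configs reproduce identical
cohorts bit for bit.

``AnalysisConfig`` carries the downstream thresholds: the FDR cut-off that
defines variable transcripts, the linear FC2 threshold that defines
overexpressed transcripts, and the TPM bin edges.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value or layout id is invalid."""


# Default aberration frequencies for the human-42 layout, mirroring the
# recurrent colorectal pattern: frequent broad gains on chromosomes 20, 13,
# 7 and 8q (as whole-chromosome gains, isochromosomes and single-arm
# events), frequent broad losses on 18, 8p, 17p, 14, 15, 4, 21, 22 and 1p.
DEFAULT_WHOLE_GAIN_FREQ: dict[str, float] = {
    "20": 0.18, "8": 0.08, "7": 0.20,
}
DEFAULT_GAIN_FREQ: dict[str, float] = {
    "20p": 0.05, "20q": 0.12, "13": 0.30, "8q": 0.08, "7p": 0.05, "7q": 0.05,
}
DEFAULT_LOSS_FREQ: dict[str, float] = {
    "18p": 0.35, "18q": 0.35, "8p": 0.12, "17p": 0.25, "14": 0.20, "15": 0.20,
    "4p": 0.20, "4q": 0.20, "21": 0.20, "22": 0.20, "1p": 0.20,
}
DEFAULT_ISO_FREQ: dict[str, float] = {
    "8": 0.24, "20": 0.13, "17": 0.09, "1": 0.07, "5": 0.05,
}


@dataclass
class SimulationConfig:
    """Ground-truth generating model for a synthetic aneuploid cohort."""

    seed: int = 0
    # cohort composition (tumours split into CIN / MSI / other)
    n_tumour: int = 120
    n_normal: int = 41
    n_cin: int = 62
    n_msi: int = 17
    # genome model
    region_layout: str = "human-42"
    n_transcripts_per_region: int = 40
    # copy-number event model
    per_region_gain_freq: dict[str, float] = field(default_factory=dict)
    per_chromosome_whole_gain_freq: dict[str, float] = field(default_factory=dict)
    per_region_loss_freq: dict[str, float] = field(default_factory=dict)
    iso_freq: dict[str, float] = field(default_factory=dict)
    background_gain_freq: float = 0.05
    background_loss_freq: float = 0.05
    msi_event_scale: float = 0.15
    # expression model
    frac_upregulated: float = 0.15
    frac_downregulated: float = 0.15
    tumour_effect_fc: float = 2.0
    dosage_exponent_up: float = 0.9
    dosage_exponent_down: float = 0.25
    dosage_exponent_null: float = 0.55
    nb_dispersion: float = 0.1
    mean_log_expression: float = 4.0
    sd_log_expression: float = 1.2
    library_size_sd: float = 0.15
    # synthetic gene sets
    geneset_enrichment_factor: float = 3.0
    geneset_size: int = 100

    @classmethod
    def with_default_frequencies(cls, **overrides) -> "SimulationConfig":
        """Config preloaded with the recurrent colorectal frequency pattern."""
        base = dict(
            per_region_gain_freq=dict(DEFAULT_GAIN_FREQ),
            per_region_loss_freq=dict(DEFAULT_LOSS_FREQ),
            iso_freq=dict(DEFAULT_ISO_FREQ),
            per_chromosome_whole_gain_freq=dict(DEFAULT_WHOLE_GAIN_FREQ),
        )
        base.update(overrides)
        return cls(**base)

    def gain_freq(self, region_id: str) -> float:
        return self.per_region_gain_freq.get(region_id, self.background_gain_freq)

    def loss_freq(self, region_id: str) -> float:
        return self.per_region_loss_freq.get(region_id, self.background_loss_freq)

    def validate(self) -> None:
        if self.n_tumour < 0 or self.n_normal < 0:
            raise ConfigurationError("sample counts must be non-negative")
        if self.n_cin + self.n_msi > self.n_tumour:
            raise ConfigurationError("n_cin + n_msi exceeds n_tumour")
        if self.n_transcripts_per_region < 1:
            raise ConfigurationError("n_transcripts_per_region must be >= 1")
        for name, mapping in (
            ("per_region_gain_freq", self.per_region_gain_freq),
            ("per_region_loss_freq", self.per_region_loss_freq),
            ("per_chromosome_whole_gain_freq", self.per_chromosome_whole_gain_freq),
            ("iso_freq", self.iso_freq),
        ):
            for key, p in mapping.items():
                if not 0.0 <= float(p) <= 1.0:
                    raise ConfigurationError(f"{name}[{key}] = {p} outside [0, 1]")
        for name in ("background_gain_freq", "background_loss_freq", "msi_event_scale",
                     "frac_upregulated", "frac_downregulated"):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ConfigurationError(f"{name} = {v} outside [0, 1]")
        if self.frac_upregulated + self.frac_downregulated > 1.0:
            raise ConfigurationError("frac_upregulated + frac_downregulated > 1")
        if self.tumour_effect_fc < 1.0:
            raise ConfigurationError("tumour_effect_fc must be >= 1 (reciprocal applied to down-regulated)")
        for name in ("dosage_exponent_up", "dosage_exponent_down", "dosage_exponent_null"):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.5:
                raise ConfigurationError(f"{name} = {v} outside [0, 1.5]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.sd_log_expression < 0 or self.library_size_sd < 0:
            raise ConfigurationError("scale parameters must be non-negative")
        if self.geneset_enrichment_factor < 1.0:
            raise ConfigurationError("geneset_enrichment_factor must be >= 1")
        if self.geneset_size < 0:
            raise ConfigurationError("geneset_size must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class AnalysisConfig:
    """Thresholds of the downstream transcript-class analysis."""

    fdr_threshold: float = 0.05
    overt_fc2_threshold: float = 1.3
    tpm_bin_edges: list[float] = field(default_factory=lambda: [0.0, 1.0, 4.0, 16.0, 64.0, 256.0, float("inf")])
    min_cpm: float = 1.0
    tpm_summary: str = "mean"  # or "median"

    def validate(self) -> None:
        if self.fdr_threshold <= 0 or self.overt_fc2_threshold <= 0:
            raise ConfigurationError("thresholds must be positive")
        edges = list(self.tpm_bin_edges)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigurationError("tpm_bin_edges must be strictly increasing with >= 2 edges")
        if self.tpm_summary not in ("mean", "median"):
            raise ConfigurationError("tpm_summary must be 'mean' or 'median'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown analysis config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    return data


def config_hash(data: dict) -> str:
    """Stable hash of a configuration mapping (key order irrelevant)."""
    canonical = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
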