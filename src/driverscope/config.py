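"""Typed pipeline configuration with the screening defaults baked in.

Every threshold the stages use lives here; the defaults are the screen's
standard operating point (binomial and concordance alpha 0.05,
prevalence 0.75, variation frequency 0.1, DE fdr 0.05 with p 0.01,
survival alpha 0.05, network fdr 0.05, drug alpha 0.05, k_max 10).
Unknown keys are rejected so a typo cannot silently fall back to a
default.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

_PROVENANCE = {
    "dominant_alpha": "dominant CNA type: exact binomial test, p <= 0.05",
    "prevalence": "expressed (raw > 0) in more than 75% of tumour samples",
    "concordance_alpha": "CNA-expression concordance: two-sided rank-sum, p <= 0.05",
    "frequency": "genomic-variation frequency must exceed 0.1",
    "de_fdr": "differential expression called at FDR <= 0.05",
    "de_p": "differential expression also requires p <= 0.01",
    "survival_alpha": "KD call: min(p_OS, p_DFS) < 0.05 by log-rank test",
    "network_fdr": "regulator edges kept at BH-adjusted p <= 0.05 (miRNAs also r < 0)",
    "drug_alpha": "drug association labeled at raw p <= 0.05",
    "k_max": "elbow scan over 1..10 candidate patient groups",
}


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dominant_alpha: float = 0.05
    prevalence: float = 0.75
    concordance_alpha: float = 0.05
    frequency: float = 0.1
    de_fdr: float = 0.05
    de_p: float = 0.01
    survival_alpha: float = 0.05
    min_group_size: int = 5
    network_fdr: float = 0.05
    drug_alpha: float = 0.05
    k_max: int = 10

    @field_validator(
        "dominant_alpha",
        "prevalence",
        "concordance_alpha",
        "frequency",
        "de_fdr",
        "de_p",
        "survival_alpha",
        "network_fdr",
        "drug_alpha",
    )
    @classmethod
    def _in_open_unit_interval(cls, v: float, info):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{info.field_name}={v} must lie in (0, 1)")
        return v

    @field_validator("k_max")
    @classmethod
    def _k_max_ge_2(cls, v: int):
        if v < 2:
            raise ValueError(f"k_max={v} must be >= 2")
        return v


class InputPaths(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cna: str
    maf: str
    expression: dict[str, str]  # mrna required; mirna/tf optional
    clinical: str
    interactions: list[dict[str, str]] = Field(default_factory=list)  # {path, class}
    external_de: list[str] = Field(default_factory=list)
    ic50: Optional[str] = None
    cell_line_expression: Optional[str] = None
    control_expression: Optional[str] = None
    barcode_length: Optional[int] = None
    expression_scale: str = "log2p1"


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")

    screen: bool = True
    de: bool = True
    kd: bool = True
    network: bool = True
    drugs: bool = False
    signature: bool = False


class SimulationConfig(BaseModel):
    """Overrides for the synthetic-cohort generator (None = defaults)."""

    model_config = ConfigDict(extra="forbid")

    n_samples: Optional[int] = None
    n_genes: Optional[int] = None
    n_drivers: Optional[int] = None
    freq_range: Optional[tuple[float, float]] = None
    expression_shift: Optional[float] = None
    hazard_ratio: Optional[float] = None
    frac_prognostic: Optional[float] = None
    event_rate: Optional[float] = None


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    thresholds: Thresholds = Field(default_factory=Thresholds)
    stages: StageToggles = Field(default_factory=StageToggles)
    inputs: Optional[InputPaths] = None  # None -> simulate a cohort
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    k_override: Optional[int] = None
    de_combine: str = "union"
    linkage: str = "average"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON config; empty file means all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return PipelineConfig.model_validate(data)


def explain_defaults() -> str:
    """Human-readable provenance of every threshold default."""
    th = Thresholds()
    lines = []
    for key, why in _PROVENANCE.items():
        lines.append(f"{key} = {getattr(th, key)}  # {why}")
    return "\n".join(lines)
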