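"""Run configuration: analysis parameters, paths, seeds and TSV dialects.

Defaults mirror the analysis constants used throughout the package: IQR
outlier multiplier k = 1.5, correlated-set threshold r^2 = 0.6, QC
thresholds MAF >= 0.01 and imputation INFO >= 0.5.  Unknown keys are
rejected outright so a typo in a config file fails before any work is done.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class ColumnMap(BaseModel):
    """Column-name mapping for externally produced TSV dialects."""

    model_config = ConfigDict(extra="forbid")

    protein_id: str = "protein_id"
    intensity_c: str = "intensity_c"
    intensity_g: str = "intensity_g"
    sample_id: str = "sample_id"
    phenotype: str = "phenotype"


class AnalysisParams(BaseModel):
    model_config = ConfigDict(extra="forbid")

    iqr_k: float = Field(1.5, gt=0)
    r2_threshold: float = Field(0.6, ge=0, le=1)
    maf_min: float = Field(0.01, ge=0, le=0.5)
    info_min: float = Field(0.5, ge=0, le=1)
    input_dilution_factor: float = Field(1.0, gt=0)


class RunConfig(BaseModel):
    """Umbrella configuration for the pipeline and CLI."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "allelics_out"
    genotypes: Optional[str] = None
    variants: Optional[str] = None
    phenotypes: Optional[str] = None
    pulldown_forward: Optional[str] = None
    pulldown_reverse: Optional[str] = None
    ct_table: Optional[str] = None
    condition_on: list[str] = Field(default_factory=list)
    params: AnalysisParams = Field(default_factory=AnalysisParams)
    columns: ColumnMap = Field(default_factory=ColumnMap)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)
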