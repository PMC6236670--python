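"""Pipeline configuration: a validated, YAML-round-trippable model.

Unknown keys are rejected (``extra="forbid"``), so a typo in a config file
fails loudly with the offending key named.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "load_config"]


class AslConstantsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    v_d: float = Field(0.95, gt=0, description="water distribution volume, mL/mL")
    t1_arterial: float = Field(2.0, gt=0, description="arterial water T1, s")


class PipelineConfig(BaseModel):
    """Everything the end-to-end pipeline needs besides the data."""

    model_config = ConfigDict(extra="forbid")

    input_dir: str | None = None
    output_dir: str = "neuroquant_out"
    modalities: list[str] = ["SUV", "ADC", "K1"]
    exclude_regions: dict[str, list[str]] = {}
    adc_method: str = "loglinear"  # or "nls"
    fair_magnitude: bool = False
    asl_constants: AslConstantsConfig = AslConstantsConfig()
    rng_seed: int = 0
    # synthetic-cohort knobs (demo / simulate)
    phantom_shape: tuple[int, int, int] = (32, 32, 16)
    subjects_per_dose: int = 6
    sigma_mri: float = 25.0
    sigma_pet: float = 20.0
    verbosity: int = 1

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)
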