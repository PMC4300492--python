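"""JSON run-configuration schema, validation and deterministic I/O.

Configs are plain JSON; validation is strict (unknown keys are
rejected, errors name the offending key) and defaults are filled
deterministically, so a saved config round-trips to itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .physiology import GENOTYPES, PhysiologyParams

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "atomic_write_text",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_default=True)


class CycleTimeSection(_Strict):
    T_min: float = Field(2.0, gt=0)
    T_max: float = Field(4.0, gt=0)
    v_half: float = 0.0
    width: float = Field(1.0, gt=0)


class NoiseSection(_Strict):
    sigma_lam: float = Field(0.0, ge=0)
    sigma_T: float = Field(0.0, ge=0)
    sigma_n: float = Field(0.0, ge=0)


class CheckpointSection(_Strict):
    v_crit: float = 0.0
    T_G1_min: float = Field(0.0, ge=0)
    T_budded: float = Field(1.0, gt=0)
    tau_max: Optional[float] = Field(None, gt=0)


class ModelSection(_Strict):
    lam: float = Field(0.2, gt=0)
    n: float = Field(2.0, gt=1)
    cycle_time: CycleTimeSection = CycleTimeSection()
    noise: NoiseSection = NoiseSection()
    checkpoint: Optional[CheckpointSection] = None


class SimulationSection(_Strict):
    t_max: float = Field(24.0, gt=0)
    max_cells: int = Field(1000, ge=1)
    T_const: float = Field(2.0, gt=0)
    T_cap: float = Field(20.0, gt=0)
    v0: float = 3.4012
    n_founders: int = Field(1, ge=1)
    mechanism: Literal["none", "gradual", "checkpoint"] = "none"


class PhysiologySection(_Strict):
    genotype: str = "WT"
    glucose_pct: float = Field(2.0, ge=0)
    dox_ng_ml: float = Field(0.0, ge=0)
    Km_mM: float = Field(10.0, gt=0)
    duration_h: float = Field(30.0, gt=0)
    n_positions: int = Field(3, ge=1)
    max_cells_per_colony: int = Field(400, ge=1)
    params: dict[str, float] = {}

    @field_validator("genotype")
    @classmethod
    def _known_genotype(cls, v: str) -> str:
        if v not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        return v

    @field_validator("params")
    @classmethod
    def _known_params(cls, v: dict) -> dict:
        valid = {f.name for f in dataclasses.fields(PhysiologyParams)}
        unknown = set(v) - valid
        if unknown:
            raise ValueError(f"unknown physiology params: {sorted(unknown)}")
        return v


class PhaseDiagramSection(_Strict):
    lam_grid: list[float] = [0.1, 0.2, 0.3, 0.4]
    T_pairs: list[tuple[float, float]] = [(2.0, 4.0)]
    v_half: float = 0.0
    width: float = 1.0
    n: float = Field(2.0, gt=1)


class QuantifySection(_Strict):
    steady_window_h: float = Field(4.0, ge=4.0)
    arrest_window_h: float = Field(5.0, gt=0)
    theta_I: float = Field(0.7, gt=0)
    theta_II: float = Field(1.5, gt=0)


class RunConfig(_Strict):
    seed: int = 0
    log_level: str = "INFO"
    model: ModelSection = ModelSection()
    simulation: SimulationSection = SimulationSection()
    physiology: PhysiologySection = PhysiologySection()
    phase_diagram: PhaseDiagramSection = PhaseDiagramSection()
    quantify: QuantifySection = QuantifySection()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON config; defaults are filled in."""
    with open(path) as fh:
        data = json.load(fh)
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    atomic_write_text(path, config.model_dump_json(indent=2) + "\n")


def config_hash(config: RunConfig) -> str:
    """Stable sha256 over the fully-resolved config."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file + rename so readers never see partial output."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
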