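"""Validated run configuration for the workbench commands.

Configs are YAML files validated against pydantic models before any
computation runs; unknown keys are rejected so a typo cannot silently
change an analysis.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpotEntry(_Strict):
    x_mm: float
    y_mm: float
    dwell_time_s: float = Field(gt=0)
    beam_current_nA: float = Field(gt=0)


class LayerEntry(_Strict):
    material: str
    thickness_cm: float = Field(ge=0)


class PlanConfig(_Strict):
    spots: list[SpotEntry] = []
    grid_n: int | None = None            # alternative: centred n×n grid
    grid_pitch_mm: float = 1.2
    dwell_time_s: float = 10.0
    beam_current_nA: float = 6.0
    entry_energy_MeV: float = 8.0
    layers: list[LayerEntry] = [
        LayerEntry(material="kapton", thickness_cm=8e-4),
        LayerEntry(material="air", thickness_cm=7.5),
    ]
    sigma_x_mm: float = 0.78
    sigma_y_mm: float = 0.89
    map_pitch_mm: float = 0.05
    map_half_extent_mm: float = 5.0
    slab_um: float = 100.0
    material: str = "water"


class WindowConfig(_Strict):
    centre_keV: float = 511.0
    frac_half_width: float = 0.10
    convention: str = "half"  # "half": ±10 %; "total": 10 % total width


class ExvivoConfig(_Strict):
    pre_events: str | None = None
    post_events: str | None = None
    pre_series: str | None = None
    post_series: str | None = None
    bin_width_s: float = 10.0
    background_rate_cps: float = 0.0
    background_rate_sd_cps: float = 0.0
    window: WindowConfig = WindowConfig()
    constraint: str = "ratio"      # "ratio" | "none"
    f18O_iterations: int = 3
    composition: str = "squamous_cell_carcinoma"
    reference_time_min: float = 0.0
    weighting: str = "neyman"


class InvivoConfig(_Strict):
    tac: str
    frame_averaging: str = "integral"


class RunConfig(_Strict):
    """Top-level workbench config; exactly one section is used per command."""

    seed: int = 0
    outdir: str = "."
    plan: PlanConfig | None = None
    exvivo: ExvivoConfig | None = None
    invivo: InvivoConfig | None = None


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
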