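"""Validated pipeline configuration (YAML-backed, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["PipelineConfig", "load_config"]

_ALL_STAGES = (
    "simulate", "segment-merge", "qc", "boundaries", "depth",
    "layers", "displacement", "transfer", "impute", "regions",
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_sections: int = Field(1, ge=1)
    orientation: str = "dorsal-ventral"
    density_scale: float = Field(1.0, gt=0)
    target_total: float = Field(80.0, gt=0)
    n_genes: int = Field(400, ge=10)
    n_panel: int = Field(200, ge=10)
    reference_cells: int = Field(4000, ge=100)


class SegmentationConfig(_Strict):
    overlap_threshold: float = Field(0.001, ge=0.0, le=1.0)
    pool_size: int = Field(10, ge=1)


class QCConfig(_Strict):
    dapi_min: float = 80.0
    mec_radius_min: float = Field(10.0, ge=0)
    mec_radius_max: float = Field(80.0, gt=0)
    area_min: float = Field(500.0, ge=0)
    area_max: float = Field(10_000.0, gt=0)
    perimeter_min: float = Field(50.0, ge=0)
    perimeter_max: float = Field(400.0, gt=0)
    transcripts_min: int = Field(10, ge=0)


class BoundaryConfig(_Strict):
    alpha: float = Field(100.0, gt=0)
    lateral_fraction: float = Field(0.025, ge=0.0, lt=0.5)
    layer: str = "INL"
    apical_reference: bool = True
    fringe_margin: float = Field(15.0, ge=0)  # µm, basal re-anchoring pass


class DisplacementConfig(_Strict):
    n_perm: int = Field(1000, ge=1)
    alpha_level: float = Field(0.05, gt=0.0, lt=1.0)
    min_cells: int = Field(10, ge=1)


class TransferConfig(_Strict):
    k: int = Field(3, ge=1)


class ImputeConfig(_Strict):
    k: int = Field(30, ge=1)
    mode: str = "kernel"


class RegionsConfig(_Strict):
    normalization: str = "within_major"
    rotation: float = 0.0


class PipelineConfig(_Strict):
    """Every knob of the end-to-end run; ``seed`` is mandatory."""

    seed: int
    out_dir: str = "run"
    stages: list[str] = Field(default_factory=lambda: list(_ALL_STAGES))
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    boundaries: BoundaryConfig = Field(default_factory=BoundaryConfig)
    displacement: DisplacementConfig = Field(default_factory=DisplacementConfig)
    transfer: TransferConfig = Field(default_factory=TransferConfig)
    impute: ImputeConfig = Field(default_factory=ImputeConfig)
    regions: RegionsConfig = Field(default_factory=RegionsConfig)

    def model_post_init(self, _ctx) -> None:
        unknown = [s for s in self.stages if s not in _ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(), sort_keys=True), encoding="utf-8"
        )


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return PipelineConfig(**data)
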