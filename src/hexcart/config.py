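"""Pipeline configuration: schema-validated, hashable, file-loadable."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .params import BlendParams, MeshParams, SweepParams
from .volume import DEFAULT_TISSUE_CODES


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ReconstructConfig(_Strict):
    decimation_fraction: float = 0.8
    smoothing_iterations: int = 9
    antialias_sigma: float = 0.8


class BoneRemeshConfig(_Strict):
    target_edge_mm: float = 3.0


class SweepConfig(_Strict):
    target_edge_mm: float = 1.0
    layers: int = 4
    sj_stage1: float = 0.0
    sj_stage2: float = 0.5
    max_iterations: int = 200
    tibial_bbox_scale: float = 0.9
    min_valid_fraction: float = 0.6


class BlendConfig(_Strict):
    enabled: bool = True
    slope_deg: float = 45.0
    bone_share: float = 0.8
    min_feature_angle_deg: float = 35.0
    joint_stop_angle_deg: float = 30.0
    relax_step: float = 0.1
    sg_degree: int = 3
    sg_window: int = 7


class PipelineConfig(_Strict):
    """Validated configuration for :func:`hexcart.pipeline.run_pipeline`.

    Unknown keys are rejected. Worker counts mirror the reference
    operating point: a pool of three for bones, four for cartilage.
    """

    tissue_codes: dict[str, int] = Field(
        default_factory=lambda: dict(DEFAULT_TISSUE_CODES)
    )
    seed: int = 0
    bone_workers: int = 3
    cartilage_workers: int = 4
    output_dir: str = "hexcart_output"
    fuse_to_bone: bool = True
    reconstruct: ReconstructConfig = Field(default_factory=ReconstructConfig)
    bone_remesh: BoneRemeshConfig = Field(default_factory=BoneRemeshConfig)
    sweep: SweepConfig = Field(default_factory=SweepConfig)
    blend: BlendConfig = Field(default_factory=BlendConfig)
    atlas_surface: str | None = None
    atlas_sites: str | None = None

    @field_validator("bone_workers", "cartilage_workers")
    @classmethod
    def _positive(cls, v):
        if v < 1:
            raise ValueError("worker counts must be >= 1")
        return v

    # -- conversion --------------------------------------------------------
    def mesh_params(self) -> MeshParams:
        sweep = SweepParams(
            target_edge_mm=self.sweep.target_edge_mm,
            layers=self.sweep.layers,
            sj_stage1=self.sweep.sj_stage1,
            sj_stage2=self.sweep.sj_stage2,
            max_iterations=self.sweep.max_iterations,
            tibial_bbox_scale=self.sweep.tibial_bbox_scale,
            min_valid_fraction=self.sweep.min_valid_fraction,
        )
        blend = BlendParams(
            enabled=self.blend.enabled,
            slope_deg=self.blend.slope_deg,
            bone_share=self.blend.bone_share,
            min_feature_angle_deg=self.blend.min_feature_angle_deg,
            joint_stop_angle_deg=self.blend.joint_stop_angle_deg,
            relax_step=self.blend.relax_step,
            sg_degree=self.blend.sg_degree,
            sg_window=self.blend.sg_window,
        )
        return MeshParams(sweep=sweep, blend=blend, fuse_to_bone=self.fuse_to_bone)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data or {})
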