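"""Tunable parameters for sweeping, blending and meshing.

Defaults reproduce the reference operating point: ~1 mm final in-plane
element edges (grid pitch is twice the target so the single in-plane
2x2 subdivision lands on target), four linearly spaced depth layers,
stage-1/stage-2 scaled-Jacobian gates of 0 and 0.5, a 45 deg blend ramp
with the bone side carrying 80% of the displacement, and a hard
iteration guard on every optimization loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SweepParams:
    target_edge_mm: float = 1.0        # final in-plane edge after subdivision
    layers: int = 4                    # depth-wise element layers
    sj_stage1: float = 0.0             # gate after degenerate repair
    sj_stage2: float = 0.5             # gate after in-plane subdivision
    max_iterations: int = 200          # per optimization stage (loop guard)
    tibial_bbox_scale: float = 0.9     # scaled bounding box for sector grid
    min_valid_fraction: float = 0.6    # coverage below this -> strategy failure
    depth_filter: tuple = (0.25, 4.0)  # valid hit-pair depth, x median
    femoral_axis_margin_mm: float = 0.5
    max_fit_radius_mm: float = 500.0   # cylinder-fit cap; beyond -> quasi-planar

    @property
    def grid_pitch_mm(self) -> float:
        return 2.0 * self.target_edge_mm


@dataclass
class BlendParams:
    enabled: bool = True
    slope_deg: float = 45.0            # target edge ramp slope
    bone_share: float = 0.8            # fraction of displacement on bone side
    min_feature_angle_deg: float = 35.0
    joint_stop_angle_deg: float = 30.0
    relax_step: float = 0.1            # feature-angle relaxation decrement
    intersect_relax_factor: float = 0.9  # global magnitude factor per retry
    sg_degree: int = 3
    sg_window: int = 7
    smoothing_iter_scale: float = 550.0
    smoothing_iter_cap: int = 2000
    fusion_search_factor: float = 2.0  # x local depth fusion distance cap
    bone_front_depths: tuple = (2, 3, 4, 5)
    joint_front_depth: int = 2
    max_moving_node_depth: int = 5     # only edge-adjacent layers may move


@dataclass
class MeshParams:
    sweep: SweepParams = field(default_factory=SweepParams)
    blend: BlendParams = field(default_factory=BlendParams)
    fuse_to_bone: bool = True
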