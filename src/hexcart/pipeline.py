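"""End-to-end orchestration: label volume -> simulation-ready mesh bundle.

Reconstruction feeds a pool of bone remeshing workers and a pool of
cartilage meshing workers (serial and pooled execution produce
identical outputs — the workers run pure functions; pools are purely a
throughput device). Per-tissue failures are isolated and reported in
the bundle; every bundle carries the config hash and seed. Timings go
to a separate log file so mesh outputs stay byte-reproducible.
"""

from __future__ import annotations

import json
import time
import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from . import attach as attach_mod
from . import bone_remesh, fileio, reconstruct
from .config import PipelineConfig
from .hexsweep import mesh_cartilage
from .volume import BONE_TISSUES, LabelVolume

#: cartilage tissue -> (sweep site, paired bone)
CARTILAGE_SITES = {
    "femoral_cartilage": ("femoral", "femur"),
    "tibial_cartilage_medial": ("tibial", "tibia"),
    "tibial_cartilage_lateral": ("tibial", "tibia"),
    "patellar_cartilage": ("patellar", "patella"),
    "cartilage": ("tibial", "bone"),
}


@dataclass
class PipelineBundle:
    output_dir: Path
    results: dict = field(default_factory=dict)   # tissue -> status record
    sites: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def succeeded(self):
        return [k for k, v in self.results.items() if v["status"] == "ok"]

    @property
    def failed(self):
        return [k for k, v in self.results.items() if v["status"] == "failed"]


def _reconstruct_job(args):
    volume, tissue, cfg = args
    surf = reconstruct.reconstruct_tissue(
        volume, tissue,
        decimation_fraction=cfg.reconstruct.decimation_fraction,
        smoothing_iterations=cfg.reconstruct.smoothing_iterations,
    )
    return tissue, surf.vertices.view(np.ndarray), surf.faces.view(np.ndarray)


def _bone_job(args):
    name, V, F, target, seed = args
    out = bone_remesh.remesh_uniform(
        trimesh.Trimesh(V, F, process=False), target, seed=seed
    )
    return name, out.vertices.view(np.ndarray), out.faces.view(np.ndarray)


def _cart_job(args):
    name, V, F, site, bone_VF, params = args
    bone = (
        trimesh.Trimesh(bone_VF[0], bone_VF[1], process=False)
        if bone_VF is not None
        else None
    )
    mesh = mesh_cartilage(
        trimesh.Trimesh(V, F, process=False), site, bone, params=params
    )
    return name, mesh.nodes, mesh.hexes, mesh.layer_count, mesh.layer_of, mesh.provenance


def _pool_map(fn, jobs, workers):
    if workers <= 1 or len(jobs) <= 1:
        return [fn(j) for j in jobs]
    with ProcessPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(fn, jobs))


def run_pipeline(labels, config: PipelineConfig | None = None) -> PipelineBundle:
    """Run reconstruct -> bone remesh -> cartilage mesh -> attach -> export.

    ``labels`` is a :class:`LabelVolume`, a path to one, or a
    :class:`~hexcart.phantoms.Phantom` (its label volume is used). The
    bundle directory receives STL bone meshes, VTU cartilage meshes, a
    mapped-sites JSON (when an atlas is configured), an INP deck, and
    provenance/log JSON files.
    """
    config = config or PipelineConfig()
    if hasattr(labels, "label_volume"):
        volume = labels.label_volume
    elif isinstance(labels, (str, Path)):
        volume = LabelVolume.load(labels)
    else:
        volume = labels
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = PipelineBundle(out_dir)
    timings = {}

    tissues = sorted(volume.tissue_map.values())
    bones = [t for t in tissues if t in BONE_TISSUES or t == "bone"]
    cartilages = [t for t in tissues if t not in bones]

    # --- reconstruction (serial; cheap compared to meshing) --------------
    surfaces = {}
    for tissue in tissues:
        t0 = time.perf_counter()
        try:
            _, V, F = _reconstruct_job((volume, tissue, config))
            surfaces[tissue] = trimesh.Trimesh(V, F, process=False)
            bundle.results[tissue] = {"status": "reconstructed"}
        except Exception as err:  # isolate per-tissue failures
            bundle.results[tissue] = {
                "status": "failed",
                "stage": "reconstruct",
                "error": f"{type(err).__name__}: {err}",
                "trace": traceback.format_exc(limit=3),
            }
        timings[f"reconstruct/{tissue}"] = time.perf_counter() - t0

    # --- bone remeshing pool ---------------------------------------------
    bone_meshes = {}
    jobs = [
        (b, surfaces[b].vertices.view(np.ndarray), surfaces[b].faces.view(np.ndarray),
         config.bone_remesh.target_edge_mm, config.seed)
        for b in bones
        if b in surfaces
    ]
    t0 = time.perf_counter()
    try:
        for name, V, F in _pool_map(_bone_job, jobs, config.bone_workers):
            bone_meshes[name] = trimesh.Trimesh(V, F, process=False)
            path = out_dir / f"{name}.stl"
            fileio.write_mesh(bone_meshes[name], path)
            bundle.results[name] = {"status": "ok", "path": str(path)}
    except Exception as err:
        for b in bones:
            if b not in bone_meshes and b in surfaces:
                bundle.results[b] = {
                    "status": "failed",
                    "stage": "bone_remesh",
                    "error": f"{type(err).__name__}: {err}",
                }
    timings["bone_remesh"] = time.perf_counter() - t0

    # --- cartilage meshing pool ------------------------------------------
    params = config.mesh_params()
    jobs = []
    for c in cartilages:
        if c not in surfaces:
            continue
        site, bone_name = CARTILAGE_SITES.get(c, ("tibial", None))
        bone = bone_meshes.get(bone_name)
        bone_VF = (
            (bone.vertices.view(np.ndarray), bone.faces.view(np.ndarray))
            if bone is not None
            else None
        )
        jobs.append(
            (c, surfaces[c].vertices.view(np.ndarray),
             surfaces[c].faces.view(np.ndarray), site, bone_VF, params)
        )
    hex_meshes = {}
    t0 = time.perf_counter()
    try:
        results = _pool_map(_cart_job, jobs, config.cartilage_workers)
    except Exception:
        # pool-level failure: degrade to serial with per-job isolation
        results = []
        for job in jobs:
            try:
                results.append(_cart_job(job))
            except Exception as err:
                bundle.results[job[0]] = {
                    "status": "failed",
                    "stage": "cartilage_mesh",
                    "error": f"{type(err).__name__}: {err}",
                }
    from .hexsweep import HexMesh

    for name, nodes, hexes, layers, layer_of, prov in results:
        mesh = HexMesh(nodes, hexes, layers, layer_of, prov)
        hex_meshes[name] = mesh
        path = out_dir / f"{name}.vtu"
        fileio.write_mesh(mesh, path)
        sj = mesh.scaled_jacobians()
        layer_summary = {
            int(l): {
                "min_sj": float(sj[mesh.layer_of == l].min()),
                "mean_sj": float(sj[mesh.layer_of == l].mean()),
            }
            for l in np.unique(mesh.layer_of)
        }
        bundle.results[name] = {
            "status": "ok",
            "path": str(path),
            "provenance": prov,
            "layer_quality": layer_summary,
        }
    timings["cartilage_mesh"] = time.perf_counter() - t0

    # --- attachment sites -------------------------------------------------
    if config.atlas_surface and config.atlas_sites and "femur" in bone_meshes:
        t0 = time.perf_counter()
        try:
            atlas = fileio.load_atlas(config.atlas_surface, config.atlas_sites)
            transform = attach_mod.register_icp(bone_meshes["femur"], atlas.femur_surface)
            subject = dict(bone_meshes)
            bundle.sites = attach_mod.map_attachment_sites(transform, atlas, subject)
            (out_dir / "attachment_sites.json").write_text(
                json.dumps(bundle.sites, indent=1)
            )
        except Exception as err:
            bundle.results["attachment_sites"] = {
                "status": "failed",
                "stage": "attach",
                "error": f"{type(err).__name__}: {err}",
            }
        timings["attach"] = time.perf_counter() - t0

    # --- FE deck ----------------------------------------------------------
    deck_meshes = {**bone_meshes, **hex_meshes}
    if deck_meshes:
        fileio.export_fe_deck(deck_meshes, bundle.sites, out_dir / "deck.inp")

    bundle.provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "tissues": {
            k: {kk: vv for kk, vv in v.items() if kk != "trace"}
            for k, v in bundle.results.items()
        },
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(bundle.provenance, indent=1, sort_keys=True)
    )
    (out_dir / "log.json").write_text(json.dumps({"timings_s": timings}, indent=1))
    return bundle
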