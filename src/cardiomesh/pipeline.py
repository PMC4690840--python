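"""End-to-end model generation: segmentation image to tagged, fibered mesh.

Orchestrates extract -> smooth -> rasterize -> mesh -> tag surfaces ->
fibers with a single config object (expressible as YAML), per-stage
logging, artifact writing and a manifest.  Apart from providing the tagged
segmentation (or a phantom spec), no interactive input is required; given
identical config and seed the CARP outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fibers import FiberConfig, FiberField, assign_fibers
from .label_io import LabelImage, read_label_image, write_label_image
from .meshing import TetMesh, mesh_from_label_image, mesh_quality, write_carp
from .phantom import PhantomSpec, make_biventricular_phantom
from .rasterization import rasterize_surfaces
from .smoothing import SmoothingConfig, SmoothingReport, smooth_surface
from .surface_extraction import (
    TaggedSurface,
    extract_tag_surface,
    merge_tag_surfaces,
    write_surface_vtk,
)
from .surface_tagging import BCSurfaces, derive_bc_surfaces, write_surf

__all__ = ["PipelineConfig", "ModelBundle", "run_pipeline", "load_config"]

log = logging.getLogger("cardiomesh")

_REQUIRED_ROLES = ("LV_myo", "RV_myo", "LV_pool", "RV_pool")


@dataclass
class PipelineConfig:
    """Full workflow configuration.

    Exactly one of ``input_path`` / ``phantom`` provides the tagged
    segmentation.  ``tag_roles`` maps anatomical roles to labels; by
    default roles are resolved by name from the image tag table.
    """

    input_path: str | None = None
    phantom: PhantomSpec | None = None
    tag_roles: dict[str, int] | None = None
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    target_spacing: float = 0.5
    mesh_tags: list[int] | None = None
    fibers: FiberConfig = field(default_factory=FiberConfig)
    output_dir: str = "cardiomesh_out"
    seed: int = 0
    log_level: str = "INFO"
    extraction_mode: str = "marching"
    # drop satellite voxel islands per tag after rasterization (standard
    # segmentation post-processing; islands carry no boundary-condition
    # information for the fiber rule)
    keep_largest_component: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "phantom" in raw and raw["phantom"] is not None:
        ph = dict(raw["phantom"])
        for key in ("lv_outer_radii", "rv_outer_radii", "rv_center_offset"):
            if key in ph:
                ph[key] = tuple(ph[key])
        raw["phantom"] = PhantomSpec(**ph)
    if "smoothing" in raw and raw["smoothing"] is not None:
        raw["smoothing"] = SmoothingConfig(**raw["smoothing"])
    if "fibers" in raw and raw["fibers"] is not None:
        fb = dict(raw["fibers"])
        if "myocardium_names" in fb:
            fb["myocardium_names"] = tuple(fb["myocardium_names"])
        raw["fibers"] = FiberConfig(**fb)
    return PipelineConfig(**raw)


@dataclass
class ModelBundle:
    """All artifacts of one pipeline run."""

    image_src: LabelImage
    surface: TaggedSurface
    smoothed: TaggedSurface
    smoothing_report: SmoothingReport
    image_hi: LabelImage
    mesh: TetMesh
    bc_surfaces: BCSurfaces
    fiber_field: FiberField
    manifest: dict


def _resolve_roles(image: LabelImage, config: PipelineConfig) -> dict[str, int]:
    roles = dict(config.tag_roles) if config.tag_roles else {}
    for role in _REQUIRED_ROLES:
        if role in roles:
            continue
        try:
            roles[role] = image.label_for(role)
        except KeyError:
            raise ValueError(
                f"tag-role map is missing {role!r}, required by derive_bc_surfaces"
            ) from None
    return roles


def _drop_satellite_components(image: LabelImage) -> LabelImage:
    """Keep only the largest 6-connected component of every tag."""
    from scipy import ndimage

    structure = ndimage.generate_binary_structure(3, 1)
    vox = image.voxels.copy()
    for tag in sorted(set(np.unique(vox).tolist()) - {0}):
        labelled, n = ndimage.label(vox == tag, structure=structure)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labelled), labelled, range(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
        dropped = (labelled > 0) & (labelled != keep)
        vox[dropped] = 0
        log.info("tag %d: removed %d satellite component(s), %d voxels",
                 tag, n - 1, int(dropped.sum()))
    return LabelImage(vox, image.spacing.copy(), image.origin.copy(),
                      dict(image.tag_table))


def run_pipeline(config: PipelineConfig) -> ModelBundle:
    """Execute the full automatic workflow and write all artifacts."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": {
            "cardiomesh": __version__,
            "numpy": np.__version__,
        },
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            dt = time.perf_counter() - t0
            manifest["stages"][name] = {"seconds": round(dt, 3), **info}
            log.info("stage %-14s %6.2fs %s", name, dt, info)

        return done

    try:
        # -- input -------------------------------------------------------
        done = stage("input")
        if config.phantom is not None:
            spec = config.phantom
            if spec.seed != config.seed:
                spec = PhantomSpec(**{**asdict(spec), "seed": config.seed})
            image, _ = make_biventricular_phantom(spec)
        elif config.input_path:
            image = read_label_image(config.input_path)
        else:
            raise ValueError("config must provide input_path or phantom")
        roles = _resolve_roles(image, config)
        if config.target_spacing > float(np.min(image.spacing)):
            log.warning(
                "target_spacing %.3g coarser than source %.3g: downsampling",
                config.target_spacing, float(np.min(image.spacing)),
            )
        write_label_image(image, out / "00_source.nii.gz")
        done(dims=list(image.dims))

        # -- surface extraction -------------------------------------------
        done = stage("extract")
        tags = sorted(set(np.unique(image.voxels).tolist()) - {0})
        surfaces = [
            extract_tag_surface(image, t, mode=config.extraction_mode) for t in tags
        ]
        surface = merge_tag_surfaces(surfaces, image)
        write_surface_vtk(surface, out / "01_surface.vtk")
        done(vertices=surface.n_vertices, faces=surface.n_faces)

        # -- smoothing ----------------------------------------------------
        done = stage("smooth")
        smoothed, report = smooth_surface(surface, image.spacing, config.smoothing)
        write_surface_vtk(smoothed, out / "02_smoothed.vtk")
        done(
            objective=report.final_objective,
            max_displacement_voxels=round(report.max_displacement_voxels, 6),
            iterations=report.iterations_used,
        )

        # -- rasterization ------------------------------------------------
        done = stage("rasterize")
        image_hi = rasterize_surfaces(smoothed, config.target_spacing, bounds=image)
        if config.keep_largest_component:
            image_hi = _drop_satellite_components(image_hi)
        write_label_image(image_hi, out / "03_upsampled.nii.gz")
        done(dims=list(image_hi.dims))

        # -- meshing ------------------------------------------------------
        done = stage("mesh")
        mesh = mesh_from_label_image(image_hi, tags=config.mesh_tags)
        quality = mesh_quality(mesh)
        done(nodes=mesh.n_nodes, elements=mesh.n_elements,
             mean_edge_mm=round(quality["mean_edge_mm"], 4))
        manifest["mesh_quality"] = quality

        # -- surface tagging ----------------------------------------------
        done = stage("tag-surfaces")
        base_band = 0.5 * float(np.max(image.spacing)) + 1.5 * config.target_spacing
        bc = derive_bc_surfaces(mesh, roles={r: roles[r] for r in roles},
                                base_band=base_band)
        for nm, fs in bc.as_dict().items():
            write_surf(fs, out / f"{nm}.surf")
        (out / "apex.txt").write_text(f"{bc.apex_node}\n")
        done(**{nm: len(fs) for nm, fs in bc.as_dict().items()})

        # -- fibers -------------------------------------------------------
        done = stage("fibers")
        fiber_field = assign_fibers(mesh, bc, config.fibers)
        write_carp(mesh, out / "model")
        done(myocardial_elements=int(fiber_field.myocardial.sum()))
    except Exception as exc:
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return ModelBundle(
        image_src=image,
        surface=surface,
        smoothed=smoothed,
        smoothing_report=report,
        image_hi=image_hi,
        mesh=mesh,
        bc_surfaces=bc,
        fiber_field=fiber_field,
        manifest=manifest,
    )
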