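"""Texture substitution and assembly of the matched 3D/2D stimulus datasets.

A cue-conflict stimulus pairs the *shape* of one category with the *texture*
of another.  Both substitution operators work in image space: the texture is
tiled over the frame and multiplied pixelwise into the render.  For the 3D
condition the multiplier is the shaded grayscale image (so shading and
attached shadows survive inside the silhouette); for the 2D condition it is
the binary silhouette itself (figure = 1, background = 0), leaving a flat
texture fill.  The two conditions therefore share the exact figure mask and
differ only in shading/attached-shadow content.

``build_dataset`` enumerates mesh x viewpoint x texture x condition, labels
each record's viewpoint canonicality, and returns a manifest; pixel
materialization is optional so full-size combinatorics can be checked
without rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .render import Camera, LightSpec, ShadedRender, render_shaded
from .shapes import Mesh, TextureImage, label_canonicality

__all__ = [
    "MANIFEST_COLUMNS",
    "Manifest",
    "tile_texture",
    "retexture_3d",
    "retexture_2d",
    "build_dataset",
]

MANIFEST_COLUMNS = [
    "stimulus_id",
    "shape_category",
    "shape_model_id",
    "texture_category",
    "texture_id",
    "viewpoint_index",
    "condition",
    "canonicality",
    "congruent",
    "image_path",
]


@dataclass
class Manifest:
    """Stimulus records plus the configuration snapshot that produced them."""

    records: pd.DataFrame
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(MANIFEST_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        key = self.records[["shape_category", "shape_model_id", "texture_category",
                            "texture_id", "viewpoint_index", "condition"]]
        if key.duplicated().any():
            raise ValueError("duplicate (shape, texture, viewpoint, condition) records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def totals(self) -> dict:
        """Record counts per condition and per canonicality."""
        return {
            "n_records": len(self.records),
            "per_condition": self.records["condition"].value_counts().to_dict(),
            "per_canonicality": self.records["canonicality"].value_counts().to_dict(),
        }

    def save(self, path) -> None:
        path = Path(path)
        self.records.to_csv(path, index=False)
        with open(path.with_suffix(".config.json"), "w") as fh:
            json.dump(self.config, fh, indent=2, default=str)

    @classmethod
    def load(cls, path) -> "Manifest":
        path = Path(path)
        records = pd.read_csv(path, keep_default_na=False)
        cfg = path.with_suffix(".config.json")
        config = json.loads(cfg.read_text()) if cfg.exists() else {}
        return cls(records=records, config=config)


def tile_texture(texture: TextureImage, resolution: int) -> np.ndarray:
    """Tile (and center-crop) a texture patch to a square frame."""
    px = texture.pixels
    if texture.tileable:
        # drop the duplicated wrap row/column so tiles join seamlessly
        px = px[:-1, :-1]
    reps = (int(np.ceil(resolution / px.shape[0])),
            int(np.ceil(resolution / px.shape[1])), 1)
    tiled = np.tile(px, reps)
    oy = (tiled.shape[0] - resolution) // 2
    ox = (tiled.shape[1] - resolution) // 2
    return tiled[oy:oy + resolution, ox:ox + resolution]


def retexture_3d(shaded: ShadedRender, texture: TextureImage) -> np.ndarray:
    """Shaded grayscale x texture RGB, pixelwise; background stays black."""
    res = shaded.gray.shape[0]
    tex = tile_texture(texture, res)
    if tex.shape[:2] != shaded.gray.shape:
        raise ValueError("texture does not tile to the render's resolution")
    return shaded.gray[:, :, None] * tex


def retexture_2d(mask: np.ndarray, texture: TextureImage) -> np.ndarray:
    """Binary silhouette x texture RGB: flat texture fill inside the figure."""
    mask = np.asarray(mask)
    res = mask.shape[0]
    tex = tile_texture(texture, res)
    if tex.shape[:2] != mask.shape:
        raise ValueError("texture does not tile to the mask's resolution")
    return mask.astype(float)[:, :, None] * tex


def build_dataset(
    meshes: list[Mesh],
    textures: list[TextureImage],
    cameras: list[Camera],
    conditions: tuple[str, ...] = ("3D", "2D"),
    profile_tolerance: float = 31.0,
    light_kwargs: dict | None = None,
    materialize: str | Path | None = None,
    seed: int = 0,
) -> Manifest:
    """Enumerate the full stimulus grid and (optionally) write the images.

    One record per (mesh x camera x texture x condition).  With
    ``materialize=None`` only the manifest is built -- no pixels are touched
    -- which is how full-size combinatorics are verified.  With a directory,
    each base view is rendered once and every texture is multiplied in, so
    3D/2D records of the same (shape, texture, viewpoint) share one mask.

    Congruent records (shape and texture category equal) are generated and
    flagged; evaluation excludes them by default.
    """
    if not meshes or not textures or not cameras:
        raise ValueError("meshes, textures and cameras must be nonempty")
    bad = set(conditions) - {"3D", "2D"}
    if bad:
        raise ValueError(f"unknown conditions: {sorted(bad)}")
    mesh_keys = [(m.category_id, m.model_id) for m in meshes]
    if len(set(mesh_keys)) != len(mesh_keys):
        raise ValueError("duplicate (category, model_id) among meshes")
    tex_keys = [(t.category_id, t.texture_id) for t in textures]
    if len(set(tex_keys)) != len(tex_keys):
        raise ValueError("duplicate (category, texture_id) among textures")

    light_kwargs = light_kwargs or {}
    out_dir = Path(materialize) if materialize is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    from PIL import Image

    for mesh in meshes:
        canon = [
            label_canonicality(cam.azimuth, cam.elevation, mesh.front_axis,
                               profile_tolerance=profile_tolerance)
            for cam in cameras
        ]
        for vi, cam in enumerate(cameras):
            shaded = None
            if out_dir is not None:
                shaded = render_shaded(mesh, cam,
                                       LightSpec.from_camera(cam, **light_kwargs))
            for tex in textures:
                for cond in conditions:
                    name = (f"{mesh.category_id}_{mesh.model_id}_"
                            f"{tex.category_id}_{tex.texture_id}_v{vi}_{cond}.png")
                    if shaded is not None:
                        img = (retexture_3d(shaded, tex) if cond == "3D"
                               else retexture_2d(shaded.mask, tex))
                        Image.fromarray(
                            (img * 255).round().astype(np.uint8)
                        ).save(out_dir / name)
                    rows.append({
                        "stimulus_id": name[:-4],
                        "shape_category": mesh.category_id,
                        "shape_model_id": mesh.model_id,
                        "texture_category": tex.category_id,
                        "texture_id": tex.texture_id,
                        "viewpoint_index": vi,
                        "condition": cond,
                        "canonicality": canon[vi],
                        "congruent": mesh.category_id == tex.category_id,
                        "image_path": str(out_dir / name) if out_dir else "",
                    })

    records = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    config = {
        "n_meshes": len(meshes),
        "n_textures": len(textures),
        "n_cameras": len(cameras),
        "conditions": list(conditions),
        "profile_tolerance": profile_tolerance,
        "resolution": cameras[0].resolution,
        "seed": seed,
        "materialized": out_dir is not None,
        "n_base_renders": len(meshes) * len(cameras),
    }
    return Manifest(records=records, config=config)
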