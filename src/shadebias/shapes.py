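"""Procedural stand-ins for the shape-model and texture-photograph stimuli.

The study design calls for 10 object categories, 10 triangle-mesh models per
category, and 10 category-specific texture images per category.  Real assets
(ShapeNet meshes, texture photographs) are not redistributable, so this module
generates part-based procedural meshes and periodic procedural textures whose
category structure -- and each mesh's "front" direction, used to label
viewpoints as canonical or noncanonical -- are known by construction.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import trimesh

__all__ = [
    "CATEGORIES",
    "Mesh",
    "TextureImage",
    "family_registry",
    "generate_category_family",
    "generate_texture",
    "label_canonicality",
    "silhouette_features",
    "texture_features",
    "nearest_centroid",
]

#: The ten entry-level object categories, in lexicographic order.
CATEGORIES = (
    "bathtub",
    "bear",
    "bird",
    "butterfly",
    "elephant",
    "fish",
    "helmet",
    "mailbox",
    "mug",
    "phone",
)

_FRONT = np.array([1.0, 0.0, 0.0])  # +X is "front" in model coordinates


def family_registry() -> dict:
    """Load the JSON registry mapping category -> family parameter ranges."""
    with resources.files("shadebias.data").joinpath("shape_families.json").open() as fh:
        return json.load(fh)


@dataclass
class Mesh:
    """A closed triangle mesh with category identity and a front direction.

    ``front_axis`` is the unit vector (in model coordinates) the object
    "faces" along; a camera looking down this axis sees the object head-on.
    """

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray  # (F, 3) int
    front_axis: np.ndarray  # unit 3-vector
    category_id: str
    model_id: int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.front_axis = np.asarray(self.front_axis, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (F, 3) index array")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")
        if abs(np.linalg.norm(self.front_axis) - 1.0) > 1e-9:
            raise ValueError("front_axis must have unit norm")
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        if (areas > 1e-12).sum() < 4:
            raise ValueError("mesh needs at least 4 non-degenerate triangles")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def save_obj(self, path) -> None:
        self.as_trimesh().export(str(path), file_type="obj")

    @property
    def bounding_radius(self) -> float:
        return float(np.linalg.norm(self.vertices, axis=1).max())


@dataclass
class TextureImage:
    """An H x W RGB texture patch in [0, 1]; every pixel is texture content."""

    pixels: np.ndarray  # (H, W, 3) float in [0, 1]
    category_id: str
    texture_id: int
    tileable: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("texture values must lie in [0, 1]")
        if self.tileable:
            if np.abs(self.pixels[0] - self.pixels[-1]).max() > 1e-6:
                raise ValueError("tileable texture: top/bottom edges must match")
            if np.abs(self.pixels[:, 0] - self.pixels[:, -1]).max() > 1e-6:
                raise ValueError("tileable texture: left/right edges must match")

    def save_png(self, path) -> None:
        from PIL import Image

        Image.fromarray((self.pixels * 255).round().astype(np.uint8)).save(str(path))


# ---------------------------------------------------------------------------
# part helpers


def _t(dx=0.0, dy=0.0, dz=0.0):
    m = np.eye(4)
    m[:3, 3] = (dx, dy, dz)
    return m


def _rot(axis, deg, at=(0, 0, 0)):
    return trimesh.transformations.rotation_matrix(math.radians(deg), axis, at)


def _box(extents, transform=None):
    return trimesh.creation.box(extents=extents, transform=transform)


def _ball(radius, scale=(1, 1, 1), center=(0, 0, 0), subdivisions=2):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    m.apply_scale(scale)
    m.apply_translation(center)
    return m


def _cyl(radius, height, transform=None, sections=12):
    return trimesh.creation.cylinder(
        radius=radius, height=height, sections=sections, transform=transform
    )


def _cone(radius, height, transform=None, sections=12):
    return trimesh.creation.cone(
        radius=radius, height=height, sections=sections, transform=transform
    )


# ---------------------------------------------------------------------------
# the ten part-based shape families (front = +X, up = +Z)


def _build_fish(p):
    body = _ball(1.0, scale=(p["body_len"], p["body_fat"], p["body_height"]))
    tail = _cone(
        p["tail"] * 0.8,
        p["tail"],
        transform=_rot([0, 1, 0], -90) @ _t(dz=p["body_len"] * 0.85),
    )
    tail.apply_scale([1.0, 0.25, 1.0])
    tail.apply_transform(_rot([0, 1, 0], 180))  # point backwards (-X)
    fin = _box(
        (p["fin"] * 1.4, 0.04, p["fin"]),
        transform=_t(dx=-0.1, dz=p["body_height"] * 0.95),
    )
    return [body, tail, fin]


def _build_elephant(p):
    half_len = p["body_len"] / 2
    body = _box((p["body_len"], p["body_fat"], p["body_fat"]), transform=_t(dz=0.3))
    legs = [
        _cyl(0.09, p["leg_len"], transform=_t(dx=sx * half_len * 0.7,
                                              dy=sy * p["body_fat"] * 0.3,
                                              dz=0.3 - p["body_fat"] / 2 - p["leg_len"] / 2))
        for sx in (-1, 1)
        for sy in (-1, 1)
    ]
    head = _ball(p["head"], center=(half_len + p["head"] * 0.6, 0, 0.45))
    trunk = _cyl(
        0.07,
        p["trunk_len"],
        transform=_t(dx=half_len + p["head"] * 1.2, dz=0.45 - p["trunk_len"] / 2)
        @ _rot([0, 1, 0], 15),
    )
    ears = [
        _box((0.06, 0.06 + p["ear"] * 0.2, p["ear"]),
             transform=_t(dx=half_len + p["head"] * 0.5,
                          dy=sy * (p["head"] + 0.03), dz=0.5))
        for sy in (-1, 1)
    ]
    return [body, head, trunk, *legs, *ears]


def _build_butterfly(p):
    body = _cyl(p["body_r"], p["body_len"], transform=_rot([0, 1, 0], 90))
    wings = []
    for sy in (-1, 1):
        w = _box((p["wing_chord"], p["wing_span"], 0.035),
                 transform=_t(dy=sy * p["wing_span"] / 2))
        w.apply_transform(_rot([1, 0, 0], -sy * p["dihedral"]))
        wings.append(w)
    head = _ball(p["body_r"] * 1.6, center=(p["body_len"] / 2 + p["body_r"], 0, 0),
                 subdivisions=1)
    return [body, head, *wings]


def _build_bird(p):
    body = _ball(1.0, scale=(p["body_len"], p["body_fat"], p["body_fat"] * 1.1))
    head = _ball(p["head"], center=(p["body_len"] * 0.8, 0, p["body_fat"] * 1.2))
    beak = _cone(
        p["head"] * 0.45,
        p["beak"],
        transform=_t(dx=p["body_len"] * 0.8 + p["head"], dz=p["body_fat"] * 1.2)
        @ _rot([0, 1, 0], 90),
    )
    tail = _box((p["tail"], p["body_fat"] * 0.8, 0.035),
                transform=_t(dx=-p["body_len"] - p["tail"] * 0.3, dz=0.05)
                @ _rot([0, 1, 0], -20))
    legs = [
        _cyl(0.03, 0.3, sections=8,
             transform=_t(dx=0.1, dy=sy * 0.08, dz=-p["body_fat"] - 0.12))
        for sy in (-1, 1)
    ]
    return [body, head, beak, tail, *legs]


def _build_bear(p):
    body = _ball(p["body"], scale=(1.15, 0.85, 1.0), center=(0, 0, 0.1))
    head = _ball(p["head"], center=(p["body"] * 0.95, 0, p["body"] * 0.75))
    snout = _ball(p["head"] * 0.45,
                  center=(p["body"] * 0.95 + p["head"] * 0.9, 0, p["body"] * 0.7),
                  subdivisions=1)
    ears = [
        _ball(p["ear"], center=(p["body"] * 0.85, sy * p["head"] * 0.8,
                                p["body"] * 0.75 + p["head"] * 0.95), subdivisions=1)
        for sy in (-1, 1)
    ]
    legs = [
        _cyl(p["leg_r"], p["leg_len"],
             transform=_t(dx=sx * p["body"] * 0.6, dy=sy * p["body"] * 0.45,
                          dz=0.1 - p["body"] - p["leg_len"] / 2 + 0.15))
        for sx in (-1, 1)
        for sy in (-1, 1)
    ]
    return [body, head, snout, *ears, *legs]


def _build_helmet(p):
    dome = _ball(1.0, scale=(p["dome_w"], p["dome_w"] * 0.9, p["dome_h"]),
                 center=(0, 0, 0.12))
    brim = _cyl(p["brim_r"], p["brim_t"], sections=20, transform=_t(dz=-0.12))
    visor = _box((0.08, p["dome_w"], p["visor"]),
                 transform=_t(dx=p["dome_w"] * 0.95, dz=0.0))
    return [dome, brim, visor]


def _build_mailbox(p):
    body = _box((p["body_len"], p["body_w"], p["body_w"]), transform=_t(dz=0.45))
    roof = _cyl(p["roof_r"], p["body_len"],
                transform=_t(dz=0.45 + p["body_w"] / 2) @ _rot([0, 1, 0], 90),
                sections=14)
    post = _cyl(0.07, p["post_len"], transform=_t(dz=0.45 - p["body_w"] / 2
                                                  - p["post_len"] / 2))
    flag = _box((0.05, 0.05, p["flag"]),
                transform=_t(dx=p["body_len"] * 0.35, dy=p["body_w"] / 2 + 0.04,
                             dz=0.45 + p["body_w"] / 2 + p["flag"] / 2))
    return [body, roof, post, flag]


def _build_bathtub(p):
    base = _box((p["length"], p["width"], p["depth"]), transform=_t(dz=0.0))
    rims = []
    for sy in (-1, 1):
        rims.append(_box((p["length"] + 2 * p["rim"], p["rim"], p["rim"] * 2),
                         transform=_t(dy=sy * (p["width"] / 2 + p["rim"] / 2),
                                      dz=p["depth"] / 2)))
    for sx in (-1, 1):
        rims.append(_box((p["rim"], p["width"], p["rim"] * 2),
                         transform=_t(dx=sx * (p["length"] / 2 + p["rim"] / 2),
                                      dz=p["depth"] / 2)))
    feet = [
        _ball(p["foot"], center=(sx * p["length"] * 0.4, sy * p["width"] * 0.4,
                                 -p["depth"] / 2 - p["foot"] * 0.5), subdivisions=1)
        for sx in (-1, 1)
        for sy in (-1, 1)
    ]
    faucet = _cyl(0.05, 0.3, sections=8,
                  transform=_t(dx=p["length"] / 2, dz=p["depth"] / 2 + 0.15))
    return [base, *rims, *feet, faucet]


def _build_mug(p):
    body = _cyl(p["radius"], p["height"], sections=18)
    t = p["handle_t"]
    w = p["handle_w"]
    x0 = -p["radius"]
    handle = [
        _box((w, t, t), transform=_t(dx=x0 - w / 2, dz=p["height"] * 0.3)),
        _box((w, t, t), transform=_t(dx=x0 - w / 2, dz=-p["height"] * 0.3)),
        _box((t, t, p["height"] * 0.6 + t),
             transform=_t(dx=x0 - w + t / 2)),
    ]
    return [body, *handle]


def _build_phone(p):
    slab = _box((p["thickness"], p["width"], p["height"]))
    earpiece = _box((0.03, p["width"] * 0.5, 0.04),
                    transform=_t(dx=p["thickness"] / 2 + 0.015,
                                 dz=p["height"] * 0.38))
    button = _cyl(p["button"], 0.03, sections=10,
                  transform=_t(dx=p["thickness"] / 2) @ _rot([0, 1, 0], 90)
                  @ _t(dy=0, dz=-p["height"] * 0.4 * 0))
    button.apply_translation([0.0, 0.0, -p["height"] * 0.38])
    antenna = _cyl(0.02, 0.25, sections=8,
                   transform=_t(dy=p["width"] * 0.35,
                                dz=p["height"] / 2 + 0.12))
    return [slab, earpiece, button, antenna]


_BUILDERS = {
    "bathtub": _build_bathtub,
    "bear": _build_bear,
    "bird": _build_bird,
    "butterfly": _build_butterfly,
    "elephant": _build_elephant,
    "fish": _build_fish,
    "helmet": _build_helmet,
    "mailbox": _build_mailbox,
    "mug": _build_mug,
    "phone": _build_phone,
}


def _sample_params(ranges: dict, rng: np.random.Generator) -> dict:
    return {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in sorted(ranges.items())}


def generate_category_family(category_id: str, n_models: int, seed: int) -> list[Mesh]:
    """Generate ``n_models`` meshes of one category's part-based family.

    Meshes within a category share part topology and differ in sampled part
    dimensions.  Each mesh is centered and scaled to a unit bounding-sphere
    radius so camera framing is independent of the family.

    Raises
    ------
    KeyError if ``category_id`` is not one of the 10 configured categories;
    ValueError if ``n_models < 1``.
    """
    reg = family_registry()["shapes"]
    if category_id not in reg:
        raise KeyError(f"unknown category {category_id!r}")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    ranges = reg[category_id]["params"]
    builder = _BUILDERS[reg[category_id]["family"]]
    cat_index = CATEGORIES.index(category_id)
    meshes = []
    for model_id in range(n_models):
        rng = np.random.default_rng([int(seed), cat_index, model_id])
        parts = builder(_sample_params(ranges, rng))
        combined = trimesh.util.concatenate(parts)
        v = np.asarray(combined.vertices, dtype=np.float64)
        v = v - (v.min(axis=0) + v.max(axis=0)) / 2
        v = v / np.linalg.norm(v, axis=1).max()
        meshes.append(
            Mesh(
                vertices=v,
                faces=np.asarray(combined.faces, dtype=np.int64),
                front_axis=_FRONT.copy(),
                category_id=category_id,
                model_id=model_id,
            )
        )
    return meshes


# ---------------------------------------------------------------------------
# procedural textures
#
# Patterns are sampled on an inclusive-endpoint periodic grid (u = i/(H-1)
# spans exactly one full period set), so the first and last row/column are
# equal and the patch tiles seamlessly with one pixel of overlap.


def _torus_noise(shape, rng, smooth):
    """Smooth noise periodic on the torus, via FFT low-pass of white noise."""
    z = rng.standard_normal(shape)
    f = np.fft.fft2(z)
    ky = np.fft.fftfreq(shape[0])[:, None]
    kx = np.fft.fftfreq(shape[1])[None, :]
    f *= np.exp(-((ky**2 + kx**2) * (smooth * min(shape)) ** 2))
    out = np.fft.ifft2(f).real
    out = (out - out.min()) / (out.max() - out.min() + 1e-12)
    return out


def _hsv_to_rgb(h, s, v):
    h = np.asarray(h) % 1.0
    i = np.floor(h * 6).astype(int)
    f = h * 6 - i
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    i = i % 6
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.stack([r, g, b], axis=-1)


def generate_texture(category_id: str, texture_id: int, size: int = 256,
                     seed: int = 0) -> TextureImage:
    """Generate one tileable procedural texture of a category's pattern family.

    Each category owns a distinct periodic pattern (stripes, checks, dots,
    gratings, noise fields, ...) and a category-specific base hue, so the 10
    texture categories are separable by simple color/orientation features.
    """
    reg = family_registry()["textures"]
    if category_id not in reg:
        raise KeyError(f"unknown category {category_id!r}")
    if size < 16:
        raise ValueError("size must be >= 16")
    pattern = reg[category_id]["pattern"]
    hue = reg[category_id]["hue"]
    cat_index = CATEGORIES.index(category_id)
    rng = np.random.default_rng([int(seed), 1000 + cat_index, int(texture_id)])

    n = size
    # inclusive-endpoint coordinates in [0, 1]: u[0] == 0, u[-1] == 1
    u = np.linspace(0.0, 1.0, n)[:, None] * np.ones((1, n))
    v = np.linspace(0.0, 1.0, n)[None, :] * np.ones((n, 1))
    k = int(rng.integers(4, 8))  # periods across the patch

    if pattern == "hstripes":
        field_ = 0.5 + 0.5 * np.sin(2 * np.pi * k * u)
    elif pattern == "vstripes":
        field_ = 0.5 + 0.5 * np.sin(2 * np.pi * k * v)
    elif pattern == "diag_grating":
        field_ = 0.5 + 0.5 * np.sin(2 * np.pi * k * (u + v))
    elif pattern == "antidiag_grating":
        field_ = 0.5 + 0.5 * np.sin(2 * np.pi * k * (u - v))
    elif pattern == "checker":
        field_ = ((np.sin(2 * np.pi * k * u) > 0)
                  ^ (np.sin(2 * np.pi * k * v) > 0)).astype(float)
    elif pattern == "grid":
        field_ = np.maximum(0.5 + 0.5 * np.cos(2 * np.pi * k * u) ** 8,
                            0.5 + 0.5 * np.cos(2 * np.pi * k * v) ** 8) - 0.5
        field_ = np.clip(field_ * 2, 0, 1)
    elif pattern == "dots":
        field_ = (np.cos(2 * np.pi * k * u) * np.cos(2 * np.pi * k * v) > 0.45
                  ).astype(float)
    elif pattern in ("blobs", "clouds", "speckle"):
        smooth = {"blobs": 0.12, "clouds": 0.08, "speckle": 0.015}[pattern]
        core = _torus_noise((n - 1, n - 1), rng, smooth)
        field_ = np.empty((n, n))
        field_[:-1, :-1] = core
        field_[-1, :-1] = core[0]
        field_[:-1, -1] = core[:, 0]
        field_[-1, -1] = core[0, 0]
        if pattern == "blobs":
            field_ = (field_ > 0.55).astype(float)
    else:  # pragma: no cover
        raise KeyError(f"unknown pattern {pattern!r}")

    h = (hue + rng.uniform(-0.02, 0.02)) % 1.0
    sat = rng.uniform(0.55, 0.85)
    value = 0.35 + 0.6 * field_
    pixels = _hsv_to_rgb(np.full((n, n), h), sat, value)
    return TextureImage(pixels=np.clip(pixels, 0, 1), category_id=category_id,
                        texture_id=int(texture_id), tileable=True)


# ---------------------------------------------------------------------------
# canonicality


def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def label_canonicality(azimuth: float, elevation: float, front_axis,
                       profile_tolerance: float = 31.0) -> str:
    """Label a viewpoint ``canonical`` or ``noncanonical``.

    A view is canonical when the camera's azimuth is within
    ``profile_tolerance`` degrees of the object's front direction or of
    either profile (front +/- 90 deg); views toward the back are
    noncanonical.  With the default tolerance of 31 deg, a 12-view orbit in
    30 deg steps yields 9 canonical and 3 noncanonical views per model.
    """
    front_axis = np.asarray(front_axis, dtype=np.float64)
    if abs(np.linalg.norm(front_axis) - 1.0) > 1e-9:
        raise ValueError("front_axis must have unit norm")
    if not 0.0 <= azimuth < 360.0:
        raise ValueError("azimuth must lie in [0, 360)")
    if not 0.0 < profile_tolerance <= 45.0:
        raise ValueError("profile_tolerance must lie in (0, 45]")
    if np.hypot(front_axis[0], front_axis[1]) < 1e-9:
        raise ValueError("front_axis must have a horizontal component")
    front_az = math.degrees(math.atan2(front_axis[1], front_axis[0])) % 360.0
    offset = (azimuth - front_az) % 360.0
    for target in (0.0, 90.0, 270.0):
        if _circ_dist(offset, target) <= profile_tolerance:
            return "canonical"
    return "noncanonical"


# ---------------------------------------------------------------------------
# fixed simple feature extractors (used to verify category separability)


def silhouette_features(mask: np.ndarray) -> np.ndarray:
    """Moment/extent features of a binary silhouette.

    Fill fraction, bbox aspect, normalized second central moments and the
    four leading Hu-style invariant combinations -- enough signal for a
    nearest-centroid read-out of the shape category.
    """
    mask = np.asarray(mask, dtype=float)
    area = mask.sum()
    if area == 0:
        return np.zeros(8)
    ys, xs = np.nonzero(mask > 0)
    h = ys.max() - ys.min() + 1
    w = xs.max() - xs.min() + 1
    cy, cx = ys.mean(), xs.mean()
    dy, dx = (ys - cy) / math.sqrt(area), (xs - cx) / math.sqrt(area)
    mu20, mu02, mu11 = (dx**2).mean(), (dy**2).mean(), (dx * dy).mean()
    mu30, mu03 = (dx**3).mean(), (dy**3).mean()
    return np.array([
        area / (h * w),          # extent (fill of bbox)
        math.log(w / h),         # aspect
        mu20, mu02, mu11,
        mu30, mu03,
        area / mask.size,        # fill of frame
    ])


def texture_features(pixels: np.ndarray) -> np.ndarray:
    """Mean-RGB plus orientation-energy features of a texture patch."""
    px = np.asarray(pixels, dtype=float)
    gray = px.mean(axis=2)
    gx = np.abs(np.diff(gray, axis=1)).mean()
    gy = np.abs(np.diff(gray, axis=0)).mean()
    gd = np.abs(gray[1:, 1:] - gray[:-1, :-1]).mean()
    ga = np.abs(gray[1:, :-1] - gray[:-1, 1:]).mean()
    return np.concatenate([px.mean(axis=(0, 1)), px.std(axis=(0, 1)),
                           [gx, gy, gd, ga]])


def nearest_centroid(train_X, train_y, test_X):
    """Nearest-centroid classification after per-feature standardization."""
    train_X = np.asarray(train_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    mu, sd = train_X.mean(axis=0), train_X.std(axis=0) + 1e-9
    train_X = (train_X - mu) / sd
    test_X = (test_X - mu) / sd
    labels = sorted(set(train_y))
    cents = np.stack([train_X[[y == c for y in train_y]].mean(axis=0)
                      for c in labels])
    d = ((test_X[:, None, :] - cents[None]) ** 2).sum(axis=2)
    return [labels[i] for i in d.argmin(axis=1)]
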