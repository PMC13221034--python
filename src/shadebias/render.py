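"""Software renderer: white-surface-on-black shaded views and silhouettes.

The study's stimuli are grayscale photographs of white-surfaced objects on a
black background, taken from a 12-camera orbit in 30-degree azimuth steps.
The 3D condition keeps two monocular depth cues inside the silhouette --
Lambertian shading (intensity proportional to the cosine between the surface
normal and the light direction) and *attached shadows* (one part of the
object occluding another part from the light) -- while the 2D condition
reduces each view to its binary silhouette.  Both conditions share the same
rasterization, so a shaded render and its silhouette have pixel-identical
figure masks; that identity is what makes the two stimulus sets differ only
in their shading/attached-shadow content.

Rendering is a plain perspective rasterizer: depth-buffered triangle fill
with perspective-correct barycentric interpolation of smooth vertex normals,
then one shadow ray per lit figure pixel tested against every triangle with
a vectorized Moller-Trumbore intersection (meshes here stay under ~2,000
triangles, where the all-triangle test is fast and exactly verifiable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .shapes import Mesh

__all__ = [
    "Camera",
    "LightSpec",
    "ShadedRender",
    "orbit_cameras",
    "render_shaded",
    "render_silhouette",
    "occluded_rays",
]

logger = logging.getLogger(__name__)

#: Field of view is chosen so a unit-bounding-sphere object fills the frame
#: with a small margin at the camera's distance.
_FRAME_MARGIN = 1.25

#: Shadow-ray origins are offset along the interpolated surface normal by
#: this distance (in units of the unit bounding-sphere radius) before the
#: occlusion test.  Interpolated points lie on the polyhedral facets, up to
#: a chord's depth below the smooth surface they stand in for; without the
#: offset, grazing rays near the shading terminator re-enter the facet mesh
#: and stipple convex surfaces with spurious shadow ("shadow acne").
SHADOW_BIAS = 0.015


@dataclass(frozen=True)
class Camera:
    """A perspective camera on the viewing orbit, looking at ``target``."""

    azimuth: float  # degrees in [0, 360)
    elevation: float = 15.0  # degrees above the horizontal plane
    distance: float = 4.0  # length units from target (> bounding radius)
    target: tuple[float, float, float] = (0.0, 0.0, 0.0)
    resolution: int = 224  # square image side, pixels

    def __post_init__(self):
        if self.resolution < 32:
            raise ValueError("resolution must be >= 32")
        if self.distance <= 1.0:
            raise ValueError("distance must exceed the unit bounding radius")

    @property
    def position(self) -> np.ndarray:
        az, el = math.radians(self.azimuth), math.radians(self.elevation)
        offset = np.array([
            math.cos(el) * math.cos(az),
            math.cos(el) * math.sin(az),
            math.sin(el),
        ])
        return np.asarray(self.target) + self.distance * offset

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (right, up, forward) camera basis; forward points at the target."""
        forward = np.asarray(self.target) - self.position
        forward = forward / np.linalg.norm(forward)
        world_up = np.array([0.0, 0.0, 1.0])
        right = np.cross(forward, world_up)
        nr = np.linalg.norm(right)
        if nr < 1e-9:  # looking straight down/up
            right = np.array([1.0, 0.0, 0.0])
        else:
            right = right / nr
        up = np.cross(right, forward)
        return right, up, forward

    @property
    def tan_half_fov(self) -> float:
        return _FRAME_MARGIN / self.distance


@dataclass(frozen=True)
class LightSpec:
    """A single directional light; ``direction`` points from light toward scene."""

    direction: tuple[float, float, float]
    ambient: float = 0.1

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError("light direction must have unit norm")
        if not 0.0 <= self.ambient < 1.0:
            raise ValueError("ambient must lie in [0, 1)")

    @property
    def vec(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)

    @staticmethod
    def from_camera(camera: Camera, az_offset: float = 30.0,
                    el_offset: float = 30.0, ambient: float = 0.1) -> "LightSpec":
        """Directional light offset from the camera axis by the given angles."""
        az = math.radians(camera.azimuth + az_offset)
        el = math.radians(camera.elevation + el_offset)
        toward_light = np.array([
            math.cos(el) * math.cos(az),
            math.cos(el) * math.sin(az),
            math.sin(el),
        ])
        return LightSpec(direction=tuple(-toward_light), ambient=ambient)


@dataclass
class ShadedRender:
    """One rendered view: grayscale shading, figure mask, attached-shadow mask."""

    gray: np.ndarray  # (R, R) float in [0, 1]; 0 off-figure
    mask: np.ndarray  # (R, R) bool figure/background
    shadow: np.ndarray  # (R, R) bool; light-facing but occluded from the light
    camera: Camera
    light: LightSpec

    def __post_init__(self):
        if self.gray.min() < 0 or self.gray.max() > 1:
            raise ValueError("gray values must lie in [0, 1]")
        if np.any(self.gray[~self.mask] != 0):
            raise ValueError("background pixels must be exactly 0")
        if np.any(self.shadow & ~self.mask):
            raise ValueError("shadow mask must be a subset of the figure mask")

    def save_png(self, path) -> None:
        from PIL import Image

        Image.fromarray((self.gray * 255).round().astype(np.uint8), mode="L").save(str(path))


def orbit_cameras(n_views: int = 12, step: float = 30.0, elevation: float = 15.0,
                  distance: float = 4.0, resolution: int = 224,
                  target=(0.0, 0.0, 0.0)) -> list[Camera]:
    """Cameras at azimuths {0, step, 2*step, ...} sharing elevation/distance/target."""
    if step <= 0:
        raise ValueError("step must be positive")
    if n_views * step > 360.0 + 1e-9:
        raise ValueError("n_views * step must not exceed 360 degrees")
    return [
        Camera(azimuth=(i * step) % 360.0, elevation=elevation, distance=distance,
               target=tuple(target), resolution=resolution)
        for i in range(n_views)
    ]


# ---------------------------------------------------------------------------
# rasterization


def _vertex_normals(mesh: Mesh) -> np.ndarray:
    tm = mesh.as_trimesh()
    return np.asarray(tm.vertex_normals, dtype=np.float64)


def _rasterize(mesh: Mesh, camera: Camera):
    """Depth-buffered triangle fill.

    Returns (mask, points, normals): the boolean figure mask plus, for each
    figure pixel, the interpolated world-space surface point and unit normal
    (arrays of shape (R, R, 3); undefined off-figure).
    """
    res = camera.resolution
    right, up, forward = camera.frame()
    rot = np.stack([right, up, forward])  # world -> camera rows
    vcam = (mesh.vertices - camera.position) @ rot.T
    z = vcam[:, 2]  # depth along the viewing axis (positive in front)

    # perspective projection to pixel coordinates
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = vcam[:, 0] / (z * camera.tan_half_fov)
        yn = vcam[:, 1] / (z * camera.tan_half_fov)
    px = (xn * 0.5 + 0.5) * res - 0.5
    py = (0.5 - yn * 0.5) * res - 0.5  # pixel row 0 at the top

    vnorm = _vertex_normals(mesh)
    depth = np.full((res, res), np.inf)
    fidx = np.full((res, res), -1, dtype=np.int64)
    bary = np.zeros((res, res, 3))

    tris = mesh.faces
    for t, (i0, i1, i2) in enumerate(tris):
        zs = z[[i0, i1, i2]]
        if np.any(zs <= 1e-6):  # behind or at the camera plane
            continue
        xs = px[[i0, i1, i2]]
        ys = py[[i0, i1, i2]]
        x_min = max(int(math.floor(xs.min())), 0)
        x_max = min(int(math.ceil(xs.max())), res - 1)
        y_min = max(int(math.floor(ys.min())), 0)
        y_max = min(int(math.ceil(ys.max())), res - 1)
        if x_min > x_max or y_min > y_max:
            continue
        denom = (ys[1] - ys[2]) * (xs[0] - xs[2]) + (xs[2] - xs[1]) * (ys[0] - ys[2])
        if abs(denom) < 1e-12:  # degenerate in projection
            continue
        gx, gy = np.meshgrid(np.arange(x_min, x_max + 1), np.arange(y_min, y_max + 1))
        w0 = ((ys[1] - ys[2]) * (gx - xs[2]) + (xs[2] - xs[1]) * (gy - ys[2])) / denom
        w1 = ((ys[2] - ys[0]) * (gx - xs[2]) + (xs[0] - xs[2]) * (gy - ys[2])) / denom
        w2 = 1.0 - w0 - w1
        inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        if not inside.any():
            continue
        # perspective-correct depth: interpolate 1/z in screen space
        zinv = w0 / zs[0] + w1 / zs[1] + w2 / zs[2]
        zpix = 1.0 / zinv
        rows, cols = gy[inside], gx[inside]
        zvals = zpix[inside]
        closer = zvals < depth[rows, cols]
        rows, cols, zvals = rows[closer], cols[closer], zvals[closer]
        if rows.size == 0:
            continue
        depth[rows, cols] = zvals
        fidx[rows, cols] = t
        bary[rows, cols, 0] = w0[inside][closer]
        bary[rows, cols, 1] = w1[inside][closer]
        bary[rows, cols, 2] = w2[inside][closer]

    mask = fidx >= 0
    points = np.zeros((res, res, 3))
    normals = np.zeros((res, res, 3))
    if mask.any():
        rows, cols = np.nonzero(mask)
        f = fidx[rows, cols]
        w = bary[rows, cols]  # screen-space barycentric
        vid = tris[f]  # (N, 3) vertex ids
        zs = z[vid]  # (N, 3)
        # perspective-correct attribute weights
        wz = w / zs
        wz = wz / wz.sum(axis=1, keepdims=True)
        pts = (mesh.vertices[vid] * wz[:, :, None]).sum(axis=1)
        nrm = (vnorm[vid] * wz[:, :, None]).sum(axis=1)
        nrm = nrm / (np.linalg.norm(nrm, axis=1, keepdims=True) + 1e-12)
        points[rows, cols] = pts
        normals[rows, cols] = nrm
    return mask, points, normals


# ---------------------------------------------------------------------------
# shadow rays


def shadow_ray_origins(points: np.ndarray, normals: np.ndarray,
                       to_light: np.ndarray) -> np.ndarray:
    """Shadow-ray start points: surface points biased off the facet surface."""
    return points + SHADOW_BIAS * normals + 1e-4 * to_light


def occluded_rays(mesh: Mesh, origins: np.ndarray, direction: np.ndarray,
                  eps: float = 1e-6, chunk: int = 512) -> np.ndarray:
    """Whether each ray (shared direction) hits any mesh triangle.

    Vectorized Moller-Trumbore over all triangles, chunked over rays to bound
    memory.  Intersections closer than ``eps`` along the ray are ignored
    (the ray's own surface)."""
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    d = np.asarray(direction, dtype=np.float64)
    tri = mesh.vertices[mesh.faces]  # (T, 3, 3)
    e1 = tri[:, 1] - tri[:, 0]  # (T, 3)
    e2 = tri[:, 2] - tri[:, 0]
    pvec = np.cross(d, e2)  # (T, 3)
    det = np.einsum("tj,tj->t", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    hit = np.zeros(len(origins), dtype=bool)
    for lo in range(0, len(origins), chunk):
        o = origins[lo:lo + chunk]  # (N, 3)
        tvec = o[:, None, :] - tri[None, :, 0]  # (N, T, 3)
        u = np.einsum("ntj,tj->nt", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None])  # (N, T, 3)
        v = np.einsum("ntj,j->nt", qvec, d) * inv_det
        t = np.einsum("ntj,tj->nt", qvec, e2) * inv_det
        inter = (ok[None] & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > eps))
        hit[lo:lo + chunk] = inter.any(axis=1)
    return hit


def render_shaded(mesh: Mesh, camera: Camera, light: LightSpec | None = None) -> ShadedRender:
    """Render a shaded white-surface view with attached shadows.

    Per figure pixel the value is ``ambient + (1 - ambient) * max(0, n.(-l))
    * visibility`` where ``n`` is the interpolated surface normal, ``l`` the
    light direction, and visibility drops to 0 when a ray from the surface
    point toward the light re-enters the mesh (an attached shadow).  The
    ``shadow`` mask records exactly those light-facing occluded pixels;
    back-facing pixels get the ambient term only and are not counted.
    """
    if light is None:
        light = LightSpec.from_camera(camera)
    mask, points, normals = _rasterize(mesh, camera)
    res = camera.resolution
    gray = np.zeros((res, res))
    shadow = np.zeros((res, res), dtype=bool)
    if not mask.any():
        logger.warning("render_shaded: no front-facing triangles; empty mask")
        return ShadedRender(gray=gray, mask=mask, shadow=shadow,
                            camera=camera, light=light)
    rows, cols = np.nonzero(mask)
    n = normals[rows, cols]
    lam = n @ (-light.vec)  # cosine of normal-to-light angle
    lit = lam > 0
    vis = np.zeros(len(rows), dtype=bool)
    if lit.any():
        to_light = -light.vec
        origins = shadow_ray_origins(points[rows[lit], cols[lit]], n[lit], to_light)
        occ = occluded_rays(mesh, origins, to_light, eps=1e-6)
        vis[lit] = ~occ
    val = light.ambient + (1.0 - light.ambient) * np.maximum(lam, 0.0) * vis
    gray[rows, cols] = np.clip(val, 0.0, 1.0)
    shadow[rows[lit & ~vis], cols[lit & ~vis]] = True
    return ShadedRender(gray=gray, mask=mask, shadow=shadow,
                        camera=camera, light=light)


def render_silhouette(mesh: Mesh, camera: Camera) -> np.ndarray:
    """Binary silhouette from the identical rasterization as ``render_shaded``.

    Sharing the rasterizer guarantees the silhouette equals the shaded
    render's figure mask pixel for pixel."""
    mask, _, _ = _rasterize(mesh, camera)
    if not mask.any():
        logger.warning("render_silhouette: empty mask")
    return mask
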