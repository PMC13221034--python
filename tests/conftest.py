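"""Shared fixtures: small procedurally generated stimulus sets.

Everything is generated at test time; the materialized dataset is built once
per session at miniature scale (2 models and 2 textures per category, 12
viewpoints, 64 x 64 pixels) and shared read-only across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

import shadebias as sb
from shadebias.finetune import ArrayDataset
from shadebias.render import orbit_cameras
from shadebias.retexture import build_dataset

MINI_MODELS = 2
MINI_TEXTURES = 2
MINI_RES = 64
SEED = 0


@pytest.fixture(scope="session")
def label_map():
    return sb.default_label_map()


@pytest.fixture(scope="session")
def mini_meshes():
    return [m for cat in sb.CATEGORIES
            for m in sb.generate_category_family(cat, MINI_MODELS, seed=SEED)]


@pytest.fixture(scope="session")
def mini_textures():
    return [sb.generate_texture(cat, t, size=32, seed=SEED)
            for cat in sb.CATEGORIES for t in range(MINI_TEXTURES)]


@pytest.fixture(scope="session")
def orbit12():
    return orbit_cameras(n_views=12, step=30.0, resolution=MINI_RES)


@pytest.fixture(scope="session")
def lazy_manifest(mini_meshes, mini_textures, orbit12):
    """Manifest over the miniature grid, both conditions, no pixels."""
    return build_dataset(mini_meshes, mini_textures, orbit12,
                         conditions=("3D", "2D"), seed=SEED)


@pytest.fixture(scope="session")
def materialized(mini_meshes, mini_textures, orbit12, tmp_path_factory):
    """The miniature dataset rendered and written to disk, once per session."""
    out = tmp_path_factory.mktemp("stimuli")
    return build_dataset(mini_meshes, mini_textures, orbit12,
                         conditions=("3D", "2D"), seed=SEED, materialize=out)


@pytest.fixture(scope="session")
def stimulus_arrays(materialized):
    return ArrayDataset.from_manifest(materialized)


@pytest.fixture(scope="session")
def unit_sphere_mesh():
    import trimesh

    s = trimesh.creation.icosphere(subdivisions=3)
    return sb.Mesh(vertices=np.asarray(s.vertices), faces=np.asarray(s.faces),
                   front_axis=[1.0, 0.0, 0.0], category_id="fish", model_id=0)


@pytest.fixture(scope="session")
def flat_plate_mesh():
    """A flat triangulated plate in the YZ plane (normal +X), 4 x 4 quads.

    All faces are coplanar, so interpolated vertex normals equal the face
    normal exactly and the Lambertian value admits a closed form.
    """
    n = 5
    ys, zs = np.meshgrid(np.linspace(-0.6, 0.6, n), np.linspace(-0.6, 0.6, n))
    verts = np.stack([np.zeros(n * n), ys.ravel(), zs.ravel()], axis=1)
    faces = []
    for r in range(n - 1):
        for c in range(n - 1):
            a, b = r * n + c, r * n + c + 1
            d, e = (r + 1) * n + c, (r + 1) * n + c + 1
            faces += [[a, b, e], [a, e, d]]
    return sb.Mesh(vertices=verts, faces=np.asarray(faces),
                   front_axis=[1.0, 0.0, 0.0], category_id="phone", model_id=0)


@pytest.fixture(scope="session")
def l_shape_mesh():
    """Two blocks forming an L; under oblique light the wall shadows the slab."""
    import trimesh

    t = trimesh.transformations.translation_matrix
    slab = trimesh.creation.box(extents=(1.0, 1.0, 0.2), transform=t((0, 0, -0.4)))
    wall = trimesh.creation.box(extents=(0.2, 1.0, 1.0), transform=t((-0.4, 0, 0.2)))
    both = trimesh.util.concatenate([slab, wall])
    return sb.Mesh(vertices=np.asarray(both.vertices), faces=np.asarray(both.faces),
                   front_axis=[1.0, 0.0, 0.0], category_id="mailbox", model_id=0)
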