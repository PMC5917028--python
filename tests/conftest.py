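"""Shared fixtures: closed-form solids and small synthetic assemblages.

Everything is generated programmatically; expensive objects are
session-scoped so the geometry is built once.
"""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

import pipshape as ps

TETRA_OBJ = """\
v 0 0 0
v 1 0 0
v 0 1 0
v 0 0 1
f 1 3 2
f 1 2 4
f 1 4 3
f 2 3 4
"""


@pytest.fixture()
def tetra_path(tmp_path):
    p = tmp_path / "tetra.obj"
    p.write_text(TETRA_OBJ)
    return p


def make_icosphere(radius=1.0, center=(0, 0, 0), subdivisions=3) -> ps.TriangleMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return ps.TriangleMesh(
        vertices=tm.vertices + np.asarray(center, dtype=float),
        faces=tm.faces,
        watertight=True,
        source_id="sphere",
    )


def make_ellipsoid(
    semi_axes=(4.0, 2.0, 1.0), center=(0, 0, 0), subdivisions=3
) -> ps.TriangleMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions)
    v = tm.vertices * np.asarray(semi_axes, dtype=float) + np.asarray(
        center, dtype=float
    )
    return ps.TriangleMesh(
        vertices=v, faces=tm.faces, watertight=True, source_id="ellipsoid"
    )


@pytest.fixture(scope="session")
def ellipsoid():
    return make_ellipsoid(center=(1.0, 2.0, 3.0))


@pytest.fixture(scope="session")
def unit_sphere():
    return make_icosphere()


@pytest.fixture(scope="session")
def seed_mesh_and_truth():
    """One seed of the first preset variety at full mesh resolution."""
    arch = ps.default_archetypes()[0]
    rng = np.random.default_rng(42)
    return ps.generate_seed_mesh(arch, rng, seed_id="fixture_seed", grid=200)


@pytest.fixture(scope="session")
def small_assemblage():
    """Three well-separated varieties, 5 seeds each, coarse meshes."""
    archs = ps.default_archetypes()[:3]
    return ps.generate_assemblage(archs, [5, 5, 5], rng_seed=7, grid=100)


@pytest.fixture(scope="session")
def small_features(small_assemblage):
    feats = []
    for mesh in small_assemblage.meshes:
        fv, _ = ps.extract_features(mesh)
        feats.append(fv)
    return feats


def random_feature_vectors(n, rng, spread=1.0, label=None):
    """Random but contract-valid 42-vectors (positive r0 slots)."""
    vs = []
    for i in range(n):
        v = rng.normal(0.0, spread, 42) * 0.1
        v[0::7] = np.abs(v[0::7]) + 2.0
        vs.append(
            ps.FeatureVector(v=v, seed_id=f"r{label or ''}{i}", label=label)
        )
    return vs
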