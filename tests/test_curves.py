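"""Sections, silhouette and the radius-versus-arc-length representation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pipshape as ps
from pipshape.curves import PlanarCurve, resample_closed
from pipshape.errors import (
    GeometryError,
    StarShapeError,
    UnsupportedInputError,
)

from conftest import make_ellipsoid, make_icosphere


def ellipse_curve(a, b, center=(0.0, 0.0), n=256, start=0):
    t = 2 * np.pi * np.arange(n) / n
    pts = np.c_[center[0] + a * np.cos(t), center[1] + b * np.sin(t)]
    return PlanarCurve(points=np.roll(pts, -start, axis=0), plane_id="test")


class TestHorizontalSections:
    def test_canonical_ellipsoid_slices_match_closed_form(self):
        ell = make_ellipsoid(subdivisions=4)
        canonical, _ = ps.canonicalize_pose(ell)
        sections = ps.horizontal_sections(canonical, n=5)
        assert [c.plane_id for c in sections] == [
            f"section_{k}" for k in range(1, 6)
        ]
        heights = [c.plane_height for c in sections]
        assert heights == sorted(heights)  # bottom to top
        for curve in sections:
            z = curve.plane_height
            shrink = np.sqrt(1.0 - (z / 4.0) ** 2)
            # canonical frame: broad semi-axis 2 -> x, thin semi-axis 1 -> y
            assert np.abs(curve.points[:, 0]).max() == pytest.approx(
                2.0 * shrink, rel=0.01
            )
            assert np.abs(curve.points[:, 1]).max() == pytest.approx(
                1.0 * shrink, rel=0.01
            )

    def test_single_section_of_sphere(self):
        sphere = make_icosphere(radius=3.0, subdivisions=4)
        (curve,) = ps.horizontal_sections(sphere, n=1)
        z = curve.plane_height
        radii = np.linalg.norm(curve.points, axis=1)
        assert radii.mean() == pytest.approx(np.sqrt(9.0 - z * z), rel=0.01)

    def test_largest_loop_selected_when_plane_hits_two_bodies(self):
        big = make_icosphere(radius=2.0)
        small = make_icosphere(radius=0.4, center=(4.0, 0.0, 0.0))
        mesh = ps.TriangleMesh(
            vertices=np.vstack([big.vertices, small.vertices]),
            faces=np.vstack([big.faces, small.faces + len(big.vertices)]),
            watertight=True,
        )
        sections = ps.horizontal_sections(mesh, n=1)
        # the mid-plane crosses both spheres; the big sphere's loop wins
        assert np.abs(np.linalg.norm(sections[0].points, axis=1).mean()
                      ) == pytest.approx(2.0, rel=0.02)

    def test_non_watertight_rejected(self):
        sphere = make_icosphere()
        open_mesh = ps.TriangleMesh(sphere.vertices, sphere.faces[:-1])
        with pytest.raises(UnsupportedInputError):
            ps.horizontal_sections(open_mesh, n=5)


class TestSilhouette:
    def test_sphere_projection_is_circle(self):
        sphere = make_icosphere(radius=2.0, subdivisions=4)
        outline = ps.silhouette_outline(sphere, resolution=512)
        radii = np.linalg.norm(outline.points, axis=1)
        tol = 2.0 * 4.0 / 512
        assert abs(radii.mean() - 2.0) < tol
        assert radii.std() < tol

    def test_ellipsoid_projection_semi_axes(self):
        ell = make_ellipsoid(subdivisions=4)
        canonical, _ = ps.canonicalize_pose(ell)
        outline = ps.silhouette_outline(canonical, resolution=512)
        # broad view spans semi-axes (x, z) = (2, 4)
        assert np.abs(outline.points[:, 0]).max() == pytest.approx(2.0, rel=0.01)
        assert np.abs(outline.points[:, 1]).max() == pytest.approx(4.0, rel=0.01)

    def test_silhouette_contains_centroid_slice(self, seed_mesh_and_truth):
        mesh, _ = seed_mesh_and_truth
        canonical, _ = ps.canonicalize_pose(mesh)
        outline = ps.silhouette_outline(canonical)
        mid = ps.horizontal_sections(canonical, n=1)[0]
        assert outline.area >= mid.area * 0.999

    def test_midsagittal_cut_alternative(self, seed_mesh_and_truth):
        mesh, _ = seed_mesh_and_truth
        canonical, _ = ps.canonicalize_pose(mesh)
        cut = ps.silhouette_outline(canonical, method="section")
        proj = ps.silhouette_outline(canonical, method="projection")
        # a planar cut can never exceed the projection outline
        assert cut.area <= proj.area * 1.01


class TestRadialProfile:
    def test_circle_converges_to_center(self):
        # vertex count equal to the sample count puts resampled points
        # exactly on the circle, so the radii are exact
        curve = ellipse_curve(5.0, 5.0, center=(2.0, -1.0), n=1024)
        profile = ps.radial_profile(curve, n_samples=1024)
        assert np.abs(profile.origin - [2.0, -1.0]).max() < 1e-6
        assert np.abs(profile.radii - 5.0).max() < 1e-9

    def test_ellipse_origin_at_center(self):
        profile = ps.radial_profile(ellipse_curve(3.0, 2.0))
        assert np.abs(profile.origin).max() < 1e-6

    def test_translation_invariance(self):
        p0 = ps.radial_profile(ellipse_curve(3.0, 2.0))
        p1 = ps.radial_profile(ellipse_curve(3.0, 2.0, center=(1.0, 0.5)))
        assert np.abs(p1.origin - [1.0, 0.5]).max() < 1e-6
        s0 = ps.spectrum(p0).amplitudes()
        s1 = ps.spectrum(p1).amplitudes()
        assert np.abs(s0 - s1).max() < 1e-8

    def test_perimeter_preserved(self, seed_mesh_and_truth):
        mesh, _ = seed_mesh_and_truth
        canonical, _ = ps.canonicalize_pose(mesh)
        curve = ps.horizontal_sections(canonical, n=1)[0]
        resampled = resample_closed(curve.points, 1024)
        closed = np.vstack([resampled, resampled[:1]])
        length = np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))
        assert length == pytest.approx(curve.perimeter, rel=1e-3)

    def test_start_vertex_invariance_up_to_cyclic_shift(self):
        # base polygon with uniform arc-length vertices: rolling the start
        # by 2 vertices shifts the 1024 samples by exactly one grid step,
        # so the amplitudes are cyclic-shift invariant to round-off
        dense = ellipse_curve(3.0, 2.0, n=8192).points
        base_pts = resample_closed(dense, 2048)
        a0 = ps.spectrum(
            ps.radial_profile(PlanarCurve(base_pts, plane_id="a"), 1024)
        ).amplitudes()
        rolled = np.roll(base_pts, -2, axis=0)
        a1 = ps.spectrum(
            ps.radial_profile(PlanarCurve(rolled, plane_id="b"), 1024)
        ).amplitudes()
        assert np.abs(a0 - a1).max() < 1e-10
        # an arbitrary (grid-misaligned) start vertex only perturbs the
        # amplitudes at the interpolation-error level
        arb = np.roll(base_pts, -137, axis=0)
        a2 = ps.spectrum(
            ps.radial_profile(PlanarCurve(arb, plane_id="c"), 1024)
        ).amplitudes()
        assert np.abs(a0 - a2).max() < 1e-4

    def test_non_star_shaped_curve_rejected(self):
        # a deep U: the region around its centroid is outside the polygon
        outer = [(0, 0), (10, 0), (10, 10), (7, 10), (7, 2), (3, 2), (3, 10), (0, 10)]
        curve = PlanarCurve(points=np.array(outer, dtype=float), plane_id="U")
        with pytest.raises(StarShapeError):
            ps.radial_profile(curve, n_samples=256)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_convex_curves_always_profile(self, seed):
        """The star-shape error never fires for convex curves."""
        rng = np.random.default_rng(seed)
        angles = np.sort(rng.uniform(0, 2 * np.pi, 24))
        if np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]])).max() > np.pi:
            angles = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        radius = rng.uniform(1.0, 4.0)
        pts = np.c_[radius * np.cos(angles), radius * np.sin(angles)]
        pts += rng.normal(0, 0.5, 2)  # translated circle-ish convex polygon
        curve = PlanarCurve(points=pts, plane_id="hyp")
        profile = ps.radial_profile(curve, n_samples=256)
        assert np.all(profile.radii > 0)


def test_curve_validation_rules():
    with pytest.raises(GeometryError):
        PlanarCurve(points=np.zeros((20, 2)), plane_id="degenerate")
    bowtie = np.array([(0, 0), (2, 2), (2, 0), (0, 2)], dtype=float)
    with pytest.raises(GeometryError):
        PlanarCurve(points=bowtie, plane_id="bowtie")
    tri = np.array([(0, 0), (1, 0), (0, 1)], dtype=float)
    curve = PlanarCurve(points=tri, plane_id="tri")
    assert len(curve.points) >= 16  # densified
    assert curve.area == pytest.approx(0.5)
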