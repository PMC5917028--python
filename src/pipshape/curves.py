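"""Planar curves extracted from a canonically posed seed.

Five horizontal cross-sections at interior fractions k/(n+1) of the z
extent, plus the silhouette: the outer boundary of the orthogonal
projection of the seed onto the plane spanned by the elongation axis (+z)
and the broad axis (+x) — the broad side view. Each closed curve is then
re-expressed as radius versus normalized arc-length from an origin chosen
so that the first harmonic of the radius function vanishes; that choice
makes the representation unique and translation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw
from shapely.geometry import Point, Polygon
from skimage import measure

from .errors import (
    GeometryError,
    ParameterError,
    StarShapeError,
    UnsupportedInputError,
)
from .mesh_io import TriangleMesh

SECTION_IDS = ("section_1", "section_2", "section_3", "section_4", "section_5")
SILHOUETTE_ID = "silhouette"

#: convergence target for the origin adjustment: amplitude_1 / r0
ORIGIN_TOL = 1e-6
_MAX_ORIGIN_ITER = 50
_MIN_CURVE_POINTS = 16


@dataclass
class PlanarCurve:
    """A simple closed polyline (mm), counter-clockwise, positive area.

    ``points`` stores each vertex once; closure to the first point is
    implied. ``plane_height`` is the cutting-plane z for sections and
    ``None`` for the silhouette.
    """

    points: np.ndarray  # (m, 2)
    plane_id: str
    plane_height: float | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise GeometryError(f"{self.plane_id}: points must be (m, 2)")
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < _MIN_CURVE_POINTS:
            pts = _densify(pts, _MIN_CURVE_POINTS)
        area = _shoelace(pts)
        if area < 0:
            pts = pts[::-1]
            area = -area
        if area <= 0:
            raise GeometryError(f"{self.plane_id}: curve encloses no area")
        poly = Polygon(pts)
        if not poly.is_simple or not poly.is_valid:
            pts = _deduplicate(pts)
            poly = Polygon(pts)
            if not poly.is_simple or not poly.is_valid:
                raise GeometryError(f"{self.plane_id}: self-intersecting curve")
        self.points = pts

    @property
    def area(self) -> float:
        return _shoelace(self.points)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))

    def polygon(self) -> Polygon:
        return Polygon(self.points)


@dataclass
class RadialProfile:
    """Radius samples at uniform normalized arc-length s_j = 2*pi*j/N."""

    radii: np.ndarray  # (N,) mm, all > 0
    origin: np.ndarray  # (2,) mm
    total_length: float  # perimeter, mm
    angles: np.ndarray  # (N,) polar angle of each sample about origin
    plane_id: str = ""

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if np.any(self.radii <= 0):
            raise StarShapeError(f"{self.plane_id}: non-positive radius sample")

    @property
    def n_samples(self) -> int:
        return len(self.radii)


def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1)) - np.sum(y * np.roll(x, -1))
    )


def _deduplicate(pts: np.ndarray) -> np.ndarray:
    keep = np.ones(len(pts), dtype=bool)
    d = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    keep[d < 1e-12] = False
    return pts[keep]


def _densify(pts: np.ndarray, n_min: int) -> np.ndarray:
    """Midpoint subdivision of a closed polyline until >= n_min points."""
    while len(pts) < n_min:
        mids = 0.5 * (pts + np.roll(pts, -1, axis=0))
        out = np.empty((2 * len(pts), 2))
        out[0::2] = pts
        out[1::2] = mids
        pts = out
    return pts


def horizontal_sections(mesh: TriangleMesh, n: int = 5) -> list[PlanarCurve]:
    """Cut ``n`` horizontal sections at z = z_min + k (z_max - z_min)/(n+1).

    The mesh must be canonically posed and watertight. Per plane, the
    intersection loop enclosing the largest area is kept (scan debris or a
    detached beak loop may add small extra loops). Curves are returned
    bottom to top.
    """
    if not mesh.watertight:
        raise UnsupportedInputError(
            f"{mesh.source_id}: horizontal sections need a watertight mesh"
        )
    if n < 1:
        raise ParameterError("n must be >= 1")
    tm = mesh.to_trimesh()
    z_min, z_max = mesh.vertices[:, 2].min(), mesh.vertices[:, 2].max()
    curves: list[PlanarCurve] = []
    for k in range(1, n + 1):
        z = z_min + k * (z_max - z_min) / (n + 1)
        section = tm.section(plane_origin=[0.0, 0.0, z], plane_normal=[0, 0, 1])
        if section is None or len(section.discrete) == 0:
            raise GeometryError(
                f"{mesh.source_id}: empty intersection at plane z={z:.4f} "
                f"(section {k} of {n})"
            )
        loops = [np.asarray(loop)[:, :2] for loop in section.discrete]
        best = max(
            loops,
            key=lambda l: abs(
                _shoelace(l[:-1] if np.allclose(l[0], l[-1]) else l)
            ),
        )
        curves.append(
            PlanarCurve(points=best, plane_id=f"section_{k}", plane_height=float(z))
        )
    return curves


def silhouette_outline(
    mesh: TriangleMesh, resolution: int = 512, method: str = "projection"
) -> PlanarCurve:
    """Outer outline of the seed's broad side view.

    ``method='projection'`` (default): every face is projected onto the
    (x, z) plane, the union is rasterized at ``resolution`` pixels along
    the larger extent and the outer boundary traced with sub-pixel contour
    interpolation. ``method='section'``: mid-sagittal planar cut at y = 0
    (the alternative reading of the broad view), largest loop kept.
    """
    if method == "section":
        tm = mesh.to_trimesh()
        sec = tm.section(plane_origin=[0.0, 0.0, 0.0], plane_normal=[0, 1, 0])
        if sec is None or len(sec.discrete) == 0:
            raise GeometryError(f"{mesh.source_id}: empty mid-sagittal section")
        loops = [np.asarray(l)[:, [0, 2]] for l in sec.discrete]
        best = max(loops, key=lambda l: abs(_shoelace(l)))
        return PlanarCurve(points=best, plane_id=SILHOUETTE_ID, plane_height=None)
    if method != "projection":
        raise ParameterError(f"unknown silhouette method {method!r}")
    if resolution < 32:
        raise ParameterError("resolution must be >= 32 pixels")

    proj = mesh.vertices[:, [0, 2]]  # (x, z): broad axis and elongation axis
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    extent = float(max(hi - lo))
    if extent <= 0:
        raise GeometryError(f"{mesh.source_id}: degenerate projection")
    pad = 4  # pixels of margin so contours close inside the raster
    scale = (resolution - 1) / extent
    size = (np.ceil((hi - lo) * scale).astype(int) + 2 * pad + 1).tolist()

    img = Image.new("1", (size[0], size[1]), 0)
    draw = ImageDraw.Draw(img)
    tri = (proj[mesh.faces] - lo) * scale + pad  # (m, 3, 2) pixel coords
    for t in tri:
        draw.polygon([tuple(p) for p in t], fill=1, outline=1)
    mask = np.asarray(img, dtype=float)  # rows = y-pixel (z), cols = x-pixel

    contours = measure.find_contours(mask, 0.5)
    if not contours:
        raise GeometryError(f"{mesh.source_id}: empty silhouette raster")
    polys = [c[:, ::-1] for c in contours]  # (row, col) -> (col=x, row=z)
    best = max(polys, key=lambda c: abs(_shoelace(c)))
    world = (best - pad) / scale + lo
    return PlanarCurve(points=world, plane_id=SILHOUETTE_ID, plane_height=None)


def resample_closed(pts: np.ndarray, n_samples: int) -> np.ndarray:
    """Resample a closed polyline at uniform arc-length; returns (n, 2)."""
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("degenerate curve (zero perimeter)")
    t = np.arange(n_samples) * total / n_samples
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def radial_profile(curve: PlanarCurve, n_samples: int = 1024) -> RadialProfile:
    """Radius-versus-arc-length representation with the r1-vanishing origin.

    The curve is resampled at uniform arc-length; the origin starts at the
    polygon area centroid and is shifted by Newton steps on the first
    harmonic of the radius function until amplitude_1 / r0 < 1e-6. The
    sample points on the curve are fixed by arc-length alone, so only the
    radii change as the origin moves.
    """
    if n_samples < 64:
        raise ParameterError("n_samples must be >= 64")
    pts = resample_closed(curve.points, n_samples)
    poly = curve.polygon()
    origin = np.array(poly.centroid.coords[0], dtype=float)
    s = 2.0 * np.pi * np.arange(n_samples) / n_samples
    cos_s, sin_s = np.cos(s), np.sin(s)
    converged = False
    for _ in range(_MAX_ORIGIN_ITER):
        rel = pts - origin
        r = np.linalg.norm(rel, axis=1)
        if np.any(r <= 0):
            raise StarShapeError(f"{curve.plane_id}: origin touched the curve")
        a0 = r.mean()
        a1 = 2.0 / n_samples * np.sum(r * cos_s)
        b1 = 2.0 / n_samples * np.sum(r * sin_s)
        if np.hypot(a1, b1) < ORIGIN_TOL * a0:
            converged = True
            break
        u = rel / r[:, None]
        # Jacobian of (a1, b1) with respect to the origin: dr/d origin = -u
        jac = (
            -2.0
            / n_samples
            * np.array(
                [
                    [np.sum(u[:, 0] * cos_s), np.sum(u[:, 1] * cos_s)],
                    [np.sum(u[:, 0] * sin_s), np.sum(u[:, 1] * sin_s)],
                ]
            )
        )
        try:
            delta = np.linalg.solve(jac, -np.array([a1, b1]))
        except np.linalg.LinAlgError as exc:
            raise StarShapeError(
                f"{curve.plane_id}: origin adjustment is singular"
            ) from exc
        origin = origin + delta
    if not converged:
        raise StarShapeError(
            f"{curve.plane_id}: origin adjustment did not converge in "
            f"{_MAX_ORIGIN_ITER} iterations"
        )
    if not poly.contains(Point(origin)):
        raise StarShapeError(
            f"{curve.plane_id}: adjusted origin left the polygon interior"
        )
    rel = pts - origin
    r = np.linalg.norm(rel, axis=1)
    if np.any(r <= 0):
        raise StarShapeError(f"{curve.plane_id}: non-positive radius")
    angles = np.arctan2(rel[:, 1], rel[:, 0])
    # star-shapedness: the CCW traversal must wind monotonically once
    # around the origin, otherwise radius-vs-arc-length is ill-defined.
    # Backtracks up to half the mean angular step are tolerated: raster-
    # traced contours jitter at the sub-pixel level without ever folding.
    dtheta = np.diff(np.concatenate([angles, angles[:1]]))
    dtheta = np.mod(dtheta + np.pi, 2.0 * np.pi) - np.pi
    backtrack_tol = 0.5 * 2.0 * np.pi / n_samples
    if np.any(dtheta < -backtrack_tol) or abs(
        dtheta.sum() - 2.0 * np.pi
    ) > 1e-6:
        raise StarShapeError(
            f"{curve.plane_id}: curve is not star-shaped about the "
            "adjusted origin (polar angle not monotone)"
        )
    return RadialProfile(
        radii=r,
        origin=origin,
        total_length=curve.perimeter,
        angles=angles,
        plane_id=curve.plane_id,
    )


def curve_to_frame(curve: PlanarCurve, profile: RadialProfile) -> np.ndarray:
    """CSV-ready array of (s, x, y, r) rows for export."""
    n = profile.n_samples
    pts = profile.origin + profile.radii[:, None] * np.column_stack(
        [np.cos(profile.angles), np.sin(profile.angles)]
    )
    s = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([s, pts, profile.radii])
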