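"""Canonical pose from the inertia tensor of the seed body.

The seed is treated as a uniform-density solid. Its centre of gravity and
inertia tensor give three orthogonal principal axes, ordered by ascending
principal moment: the first axis (smallest moment) is the elongation axis
and runs through the beak; the second follows the broad face; the third
completes a right-handed frame. In canonical coordinates the first axis is
+z ("beak up"), the second +x and the third +y.

Eigenvectors carry no intrinsic sign, so signs are fixed by an intrinsic
convention: the third central moment (skewness) of the solid along axis 1
is made positive — a pip's thin tapering beak is a long upper tail of the
mass distribution along the length axis, so "skewness up" means "beak up".
The axis-2 sign is chosen the same way when the broad-face skewness is
non-zero, and axis 3 is then forced by right-handedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .mesh_io import TriangleMesh

#: relative eigenvalue gap below which two principal moments are degenerate
DEGENERACY_TOL = 1e-6

#: |skewness| below this fraction of scale^5 counts as "no sign signal"
_SKEW_TIE_TOL = 1e-9


@dataclass
class PrincipalFrame:
    """Centre of gravity plus ordered orthonormal inertia axes.

    ``axes[i]`` is the i-th principal axis (row vector), ordered by
    ascending principal moment; the frame is right-handed.
    """

    origin: np.ndarray  # (3,) centre of gravity, mm
    axes: np.ndarray  # (3, 3) rows = axis 1..3
    moments: np.ndarray  # (3,) ascending, mm^5 at unit density
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.moments = np.asarray(self.moments, dtype=float)
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(3), atol=1e-10):
            raise GeometryError("principal axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise GeometryError("principal frame is not right-handed")
        if not (self.moments[0] <= self.moments[1] <= self.moments[2]):
            raise GeometryError("principal moments are not ascending")

    @property
    def rotation(self) -> np.ndarray:
        """World -> canonical rotation (rows x, y, z = axes 2, 3, 1)."""
        return np.vstack([self.axes[1], self.axes[2], self.axes[0]])

    def to_canonical(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) @ self.rotation.T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation + self.origin

    def to_matrix(self) -> np.ndarray:
        """4x4 homogeneous world -> canonical transform."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = -self.rotation @ self.origin
        return m


def solid_properties(mesh: TriangleMesh) -> tuple[np.ndarray, np.ndarray]:
    """Centre of gravity and inertia tensor about it, uniform unit density.

    Watertight meshes use exact per-triangle divergence-theorem integrals of
    the enclosed solid; open meshes fall back to uniform point masses on the
    vertices (flagged upstream, never silently).
    """
    if mesh.watertight:
        tm = mesh.to_trimesh()
        with np.errstate(invalid="ignore"):  # zero volume checked below
            volume = float(tm.volume)
        if abs(volume) < 1e-12:
            raise GeometryError(
                f"{mesh.source_id}: watertight mesh encloses zero volume"
            )
        cog = np.asarray(tm.center_mass, dtype=float)
        inertia = np.asarray(tm.moment_inertia, dtype=float)
    else:
        cog = mesh.vertices.mean(axis=0)
        rel = mesh.vertices - cog
        r2 = np.einsum("ij,ij->i", rel, rel)
        inertia = r2.sum() * np.eye(3) - rel.T @ rel
    inertia = 0.5 * (inertia + inertia.T)  # enforce exact symmetry
    return cog, inertia


def third_axis_moment(
    mesh: TriangleMesh, direction: np.ndarray, origin: np.ndarray
) -> float:
    """Exact third central moment of the solid along ``direction``.

    Computes the volume integral of ((x - origin) . u)^3 by signed
    decomposition into tetrahedra against the centroid; for a linear
    function with tetra-vertex values c_i the integral over one tetrahedron
    of volume V is V (S1^3 + 3 S1 S2 + 2 S3) / 120 with S_k = sum c_i^k.
    Open meshes fall back to the vertex point-cloud moment.
    """
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    rel = mesh.vertices - np.asarray(origin, dtype=float)
    if not mesh.watertight:
        return float(np.mean((rel @ u) ** 3))
    tri = rel[mesh.faces]  # (m, 3, 3)
    vols = np.einsum(
        "ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])
    ) / 6.0
    c = tri @ u  # (m, 3); apex value (origin point) is 0
    s1 = c.sum(axis=1)
    s2 = (c**2).sum(axis=1)
    s3 = (c**3).sum(axis=1)
    total = np.sum(vols * (s1**3 + 3.0 * s1 * s2 + 2.0 * s3) / 120.0)
    volume = float(np.sum(vols))
    return float(total / volume)


def _disambiguate_pair(
    mesh: TriangleMesh, cog: np.ndarray, e_a: np.ndarray, e_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """For a degenerate eigenpair, rotate within the eigenplane to the
    direction of maximal |skewness| (deterministic 1-degree grid)."""
    angles = np.deg2rad(np.arange(0, 180))
    best, best_val = 0.0, -np.inf
    for phi in angles:
        u = np.cos(phi) * e_a + np.sin(phi) * e_b
        val = abs(third_axis_moment(mesh, u, cog))
        if val > best_val + 1e-15:
            best, best_val = phi, val
    ua = np.cos(best) * e_a + np.sin(best) * e_b
    ub = -np.sin(best) * e_a + np.cos(best) * e_b
    return ua, ub


def principal_frame(mesh: TriangleMesh) -> PrincipalFrame:
    """Principal axes of the inertia tensor, ordered, sign-disambiguated."""
    cog, inertia = solid_properties(mesh)
    moments, vecs = np.linalg.eigh(inertia)  # ascending
    axes = vecs.T.copy()  # rows
    warns: list[str] = []

    scale = max(abs(moments[2]), 1e-300)
    gaps = np.diff(moments) / scale
    if gaps[0] < DEGENERACY_TOL and gaps[1] < DEGENERACY_TOL:
        warns.append("fully degenerate inertia tensor (sphere-like body)")
        axes[0], axes[1] = _disambiguate_pair(mesh, cog, axes[0], axes[1])
    elif gaps[0] < DEGENERACY_TOL:
        warns.append("principal moments 1 and 2 nearly degenerate")
        axes[0], axes[1] = _disambiguate_pair(mesh, cog, axes[0], axes[1])
    elif gaps[1] < DEGENERACY_TOL:
        warns.append("principal moments 2 and 3 nearly degenerate")
        axes[1], axes[2] = _disambiguate_pair(mesh, cog, axes[1], axes[2])

    # sign convention: beak (long thin tail of the mass distribution) up
    extent = float(np.ptp(mesh.vertices @ axes[0]))
    skew_tol = _SKEW_TIE_TOL * max(extent, 1e-30) ** 3
    s1 = third_axis_moment(mesh, axes[0], cog)
    if abs(s1) <= skew_tol:
        warns.append("axis-1 skewness indistinguishable from zero")
    elif s1 < 0:
        axes[0] = -axes[0]
    s2 = third_axis_moment(mesh, axes[1], cog)
    if s2 < -skew_tol:
        axes[1] = -axes[1]
    axes[2] = np.cross(axes[0], axes[1])  # right-handed completion
    return PrincipalFrame(origin=cog, axes=axes, moments=moments, warnings=warns)


def canonicalize_pose(mesh: TriangleMesh) -> tuple[TriangleMesh, PrincipalFrame]:
    """Express the mesh in its canonical principal-axes coordinates.

    Axis 1 maps to +z (beak up), axis 2 to +x, axis 3 to +y; the origin is
    the centre of gravity. Applying ``frame.to_world`` to the output
    vertices reproduces the input.
    """
    frame = principal_frame(mesh)
    out = mesh.copy()
    out.vertices = frame.to_canonical(mesh.vertices)
    out.metadata["canonical"] = True
    out.metadata["frame_warnings"] = list(frame.warnings)
    return out, frame
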