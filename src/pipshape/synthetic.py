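"""Synthetic seed meshes with known ground-truth shape descriptors.

The generator emulates the shape space of real grape pips: prolate,
beaked, bilaterally quasi-symmetric bodies a few millimetres long, with
per-variety mean cross-section harmonics and within-variety Gaussian
variation. Each seed is a star-shaped (about its long axis) surface

    R(z, theta) = c0(z) * (1 + sum_k [ah_k(z) cos(k theta)
                                      + bh_k(z) sin(k theta)]) + beak(z)

where c0(z) is the mean-radius envelope interpolated through the five
section values and clamped to zero at both poles, ah/bh are *relative*
harmonic coefficients interpolated through the sections (flat beyond the
outermost sections so positivity is inherited from the amplitude bound
sum |amp| <= 0.5 r0), and beak(z) is a small Gaussian radial bump on the
top tenth of the height that reproduces the tapering micropile end the
canonical-pose sign rule keys on.

Ground truth is stored before meshing: the section slots evaluate the
analytic curve r(theta) = c0 (1 + sum ...) at the exact cutting heights
through the same arc-length/Fourier machinery the pipeline uses (at high
sampling), and the silhouette slot profiles the analytic projection
outline x(z) = extremal R(z, theta) cos(theta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from . import fourier
from .curves import PlanarCurve, radial_profile
from .errors import GeometryError, ParameterError
from .features import FeatureVector, assemble_features
from .fourier import FourierDescriptor
from .mesh_io import AssemblageManifest, TriangleMesh

#: harmonic orders carried by archetype section descriptors
_HARMONICS = (2, 3, 4, 5, 6, 7)

#: section heights as fractions of total length (k/6, k=1..5)
SECTION_FRACTIONS = tuple(k / 6.0 for k in range(1, 6))

#: relative amplitude budget keeping the surface star-shaped
MAX_RELATIVE_AMPLITUDE = 0.5


@dataclass
class VarietyArchetype:
    """Mean shape and within-variety spread of one seed variety.

    ``section_r0`` are the mean radii (mm) of the five horizontal sections
    bottom to top; ``section_amps[k_idx]`` the harmonic amplitudes (mm) of
    orders 2..7 per section; phases rotate each harmonic about the long
    axis (phase 0 aligns the r2 major axis with +x, the broad direction).
    """

    name: str
    length: float  # mean seed height, mm
    section_r0: np.ndarray  # (5,)
    section_amps: np.ndarray  # (5, 6) orders r2..r7
    section_phases: np.ndarray  # (5, 6) radians
    sd_length: float = 0.0
    sd_r0: np.ndarray | float = 0.0  # per-section or scalar, mm
    sd_amps: np.ndarray | float = 0.0  # per-entry or scalar, mm
    beak_height_fraction: float = 0.10
    beak_amplitude: float = 0.12  # mm

    def __post_init__(self) -> None:
        self.section_r0 = np.asarray(self.section_r0, dtype=float)
        self.section_amps = np.asarray(self.section_amps, dtype=float)
        self.section_phases = np.asarray(self.section_phases, dtype=float)
        if self.section_r0.shape != (5,) or np.any(self.section_r0 <= 0):
            raise ParameterError(f"{self.name}: section_r0 must be 5 positive values")
        if self.section_amps.shape != (5, 6) or np.any(self.section_amps < 0):
            raise ParameterError(f"{self.name}: section_amps must be (5, 6) >= 0")
        if self.section_phases.shape != (5, 6):
            raise ParameterError(f"{self.name}: section_phases must be (5, 6)")
        if self.length <= 0 or self.sd_length < 0:
            raise ParameterError(f"{self.name}: bad length parameters")
        budgets = self.section_amps.sum(axis=1) / self.section_r0
        if np.any(budgets > MAX_RELATIVE_AMPLITUDE):
            raise ParameterError(
                f"{self.name}: harmonic amplitudes exceed "
                f"{MAX_RELATIVE_AMPLITUDE} * r0 (star-shape bound)"
            )
        if not 0 < self.beak_height_fraction < 0.5:
            raise ParameterError(f"{self.name}: beak fraction out of range")
        self.sd_r0 = np.broadcast_to(
            np.asarray(self.sd_r0, dtype=float), (5,)
        ).copy()
        self.sd_amps = np.broadcast_to(
            np.asarray(self.sd_amps, dtype=float), (5, 6)
        ).copy()


@dataclass
class SyntheticAssemblage:
    """Generated meshes with labels and pre-meshing ground truth."""

    meshes: list[TriangleMesh]
    labels: list[str]
    truth: list[FeatureVector]
    rng_seed: int

    def manifest_entries(self) -> list[tuple[str, str]]:
        return [
            (m.source_id, l) for m, l in zip(self.meshes, self.labels)
        ]


@dataclass
class _SeedShape:
    """Drawn parameters of one seed plus its analytic radius field."""

    length: float
    r0: np.ndarray  # (5,)
    amps: np.ndarray  # (5, 6)
    phases: np.ndarray  # (5, 6)
    beak_fraction: float
    beak_amplitude: float
    _c0: PchipInterpolator = field(init=False, repr=False)
    _ah: list = field(init=False, repr=False)
    _bh: list = field(init=False, repr=False)

    def __post_init__(self) -> None:
        z_knots = np.concatenate(
            [[0.0], np.array(SECTION_FRACTIONS) * self.length, [self.length]]
        )
        c0_vals = np.concatenate([[0.0], self.r0, [0.0]])
        self._c0 = PchipInterpolator(z_knots, c0_vals)
        rel_a = self.amps * np.cos(self.phases) / self.r0[:, None]
        rel_b = self.amps * np.sin(self.phases) / self.r0[:, None]
        self._ah, self._bh = [], []
        for j in range(6):
            a_vals = np.concatenate([[rel_a[0, j]], rel_a[:, j], [rel_a[-1, j]]])
            b_vals = np.concatenate([[rel_b[0, j]], rel_b[:, j], [rel_b[-1, j]]])
            self._ah.append(PchipInterpolator(z_knots, a_vals))
            self._bh.append(PchipInterpolator(z_knots, b_vals))

    def beak(self, z: np.ndarray) -> np.ndarray:
        sigma = self.beak_fraction * self.length / 4.0
        center = self.length * (1.0 - self.beak_fraction / 2.0)
        return self.beak_amplitude * np.exp(
            -0.5 * ((np.asarray(z, dtype=float) - center) / sigma) ** 2
        )

    def radius(self, z: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """R(z, theta); broadcasts z against theta."""
        z = np.asarray(z, dtype=float)
        theta = np.asarray(theta, dtype=float)
        shape = np.ones(np.broadcast_shapes(z.shape, theta.shape))
        rel = np.zeros_like(shape)
        for j, k in enumerate(_HARMONICS):
            rel = rel + self._ah[j](z) * np.cos(k * theta) + self._bh[j](
                z
            ) * np.sin(k * theta)
        return self._c0(z) * (1.0 + rel) * shape + self.beak(z)

    def section_curve(self, z: float, n_theta: int = 2048) -> PlanarCurve:
        theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
        r = self.radius(np.full(n_theta, z), theta)
        if np.any(r <= 0):
            raise GeometryError("analytic section not star-shaped")
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        return PlanarCurve(points=pts, plane_id="analytic", plane_height=z)

    def silhouette_curve(self, n_z: int = 1024) -> PlanarCurve:
        """Analytic outline of the projection onto the (x, z) plane."""
        eps = 1e-6 * self.length
        z = np.linspace(eps, self.length - eps, n_z)
        theta = 2.0 * np.pi * np.arange(720) / 720
        r = self.radius(z[:, None], theta[None, :])
        x = r * np.cos(theta)[None, :]
        x_max, x_min = x.max(axis=1), x.min(axis=1)
        up = np.column_stack([x_max, z])
        down = np.column_stack([x_min, z])[::-1]
        pts = np.vstack([up, down])
        return PlanarCurve(points=pts, plane_id="silhouette", plane_height=None)


def _truncated_normal(rng, mean, sd, width: float = 3.0):
    """Gaussian draw clipped to mean +/- width * sd (elementwise)."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    draw = rng.normal(mean, sd)
    return np.clip(draw, mean - width * sd, mean + width * sd)


def _draw_shape(arch: VarietyArchetype, rng: np.random.Generator) -> _SeedShape:
    for _ in range(10):
        length = float(
            max(_truncated_normal(rng, arch.length, arch.sd_length), 0.5)
        )
        r0 = _truncated_normal(rng, arch.section_r0, arch.sd_r0)
        amps = np.clip(
            _truncated_normal(rng, arch.section_amps, arch.sd_amps), 0.0, None
        )
        if np.any(r0 <= 0):
            continue
        if np.any(amps.sum(axis=1) / r0 > MAX_RELATIVE_AMPLITUDE):
            continue
        return _SeedShape(
            length=length,
            r0=r0,
            amps=amps,
            phases=arch.section_phases.copy(),
            beak_fraction=arch.beak_height_fraction,
            beak_amplitude=arch.beak_amplitude,
        )
    raise GeometryError(
        f"{arch.name}: could not draw a star-shaped seed in 10 tries"
    )


def _mesh_from_shape(shape: _SeedShape, grid: int = 200) -> TriangleMesh:
    """Triangulate R(z, theta) on a grid x grid lattice; watertight by
    construction (rings plus two pole fans)."""
    n_z, n_t = grid, grid
    z_levels = shape.length * np.arange(1, n_z) / n_z  # interior rings
    theta = 2.0 * np.pi * np.arange(n_t) / n_t
    r = shape.radius(z_levels[:, None], theta[None, :])
    if np.any(r <= 0):
        raise GeometryError("sampled surface not star-shaped")
    x = r * np.cos(theta)[None, :]
    y = r * np.sin(theta)[None, :]
    z = np.broadcast_to(z_levels[:, None], r.shape)
    ring_verts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    bottom = np.array([[0.0, 0.0, 0.0]])
    top = np.array([[0.0, 0.0, shape.length]])
    vertices = np.vstack([ring_verts, bottom, top])
    i_bottom = len(ring_verts)
    i_top = i_bottom + 1

    faces = []
    n_rings = len(z_levels)
    idx = lambda i, j: i * n_t + (j % n_t)  # noqa: E731
    for i in range(n_rings - 1):
        for j in range(n_t):
            a, b = idx(i, j), idx(i, j + 1)
            c, d = idx(i + 1, j), idx(i + 1, j + 1)
            faces.append((a, b, d))
            faces.append((a, d, c))
    for j in range(n_t):  # bottom fan, outward = -z
        faces.append((i_bottom, idx(0, j + 1), idx(0, j)))
    for j in range(n_t):  # top fan, outward = +z
        faces.append((i_top, idx(n_rings - 1, j), idx(n_rings - 1, j + 1)))

    mesh = TriangleMesh(
        vertices=vertices, faces=np.asarray(faces, dtype=np.int64)
    )
    tm = mesh.to_trimesh()
    if not tm.is_watertight:
        raise GeometryError("generated mesh is not watertight")
    if tm.volume < 0:
        mesh.faces = mesh.faces[:, ::-1]
    mesh.watertight = True
    return mesh


def _truth_features(
    shape: _SeedShape, seed_id: str, label: str, n_samples: int = 4096
) -> FeatureVector:
    """Ground-truth descriptors from the analytic curves, in the same
    arc-length parameterization the pipeline measures in."""
    descriptors: dict[str, FourierDescriptor] = {}
    for k, frac in enumerate(SECTION_FRACTIONS, start=1):
        curve = shape.section_curve(frac * shape.length)
        prof = radial_profile(curve, n_samples=n_samples)
        spec = fourier.spectrum(prof, K=fourier.DEFAULT_K)
        desc = fourier.descriptor(spec)
        descriptors[f"section_{k}"] = FourierDescriptor(
            r0=desc.r0, amplitudes=desc.amplitudes, plane_id=f"section_{k}"
        )
    sil = shape.silhouette_curve()
    prof = radial_profile(sil, n_samples=n_samples)
    spec = fourier.spectrum(prof, K=fourier.DEFAULT_K)
    desc = fourier.descriptor(spec)
    descriptors["silhouette"] = FourierDescriptor(
        r0=desc.r0, amplitudes=desc.amplitudes, plane_id="silhouette"
    )
    return assemble_features(descriptors, seed_id=seed_id, label=label)


def generate_seed_mesh(
    arch: VarietyArchetype,
    rng: np.random.Generator,
    seed_id: str = "seed",
    grid: int = 200,
) -> tuple[TriangleMesh, FeatureVector]:
    """Draw one seed from the archetype; returns (mesh, ground truth)."""
    shape = _draw_shape(arch, rng)
    truth = _truth_features(shape, seed_id=seed_id, label=arch.name)
    mesh = _mesh_from_shape(shape, grid=grid)
    mesh.label = arch.name
    mesh.source_id = seed_id
    mesh.metadata["beak_z"] = shape.length  # beak end is the top pole
    return mesh, truth


def generate_assemblage(
    archetypes: list[VarietyArchetype],
    n_per_variety: list[int] | dict[str, int],
    rng_seed: int = 0,
    grid: int = 200,
) -> SyntheticAssemblage:
    """Reproducible assemblage of seeds drawn from the archetypes."""
    if len(archetypes) < 2:
        raise ParameterError("need at least 2 archetypes")
    if isinstance(n_per_variety, dict):
        counts = [n_per_variety[a.name] for a in archetypes]
    else:
        counts = list(n_per_variety)
    if len(counts) != len(archetypes) or any(c < 4 for c in counts):
        raise ParameterError("need one count >= 4 per archetype")
    rng = np.random.default_rng(rng_seed)
    meshes, labels, truth = [], [], []
    for arch, n in zip(archetypes, counts):
        for i in range(n):
            sid = f"{arch.name}_{i + 1:02d}"
            mesh, ft = generate_seed_mesh(arch, rng, seed_id=sid, grid=grid)
            meshes.append(mesh)
            labels.append(arch.name)
            truth.append(ft)
    return SyntheticAssemblage(
        meshes=meshes, labels=labels, truth=truth, rng_seed=rng_seed
    )


def _preset_table() -> list[dict]:
    """Seven variety archetypes spanning realistic pip morphology:
    lengths 5.5-7.5 mm, mid-section mean radii 1.3-1.9 mm, section
    eccentricities r2/r0 up to ~0.18 and small higher harmonics."""
    return [
        dict(name="A", length=6.8, r0_mid=1.85, taper=0.32, r2=0.10, r3=0.030),
        dict(name="B", length=7.4, r0_mid=1.60, taper=0.38, r2=0.18, r3=0.020),
        dict(name="C", length=6.2, r0_mid=1.75, taper=0.25, r2=0.05, r3=0.045),
        dict(name="D", length=5.6, r0_mid=1.45, taper=0.30, r2=0.13, r3=0.012),
        dict(name="E", length=6.5, r0_mid=1.35, taper=0.42, r2=0.08, r3=0.035),
        dict(name="F", length=7.1, r0_mid=1.90, taper=0.20, r2=0.15, r3=0.040),
        dict(name="G", length=5.9, r0_mid=1.55, taper=0.35, r2=0.11, r3=0.055),
    ]


#: group sizes of the default assemblage (seven varieties, 10-16 seeds each)
DEFAULT_GROUP_SIZES = (13, 12, 13, 10, 10, 11, 14)


def default_archetypes(separation: float = 1.0) -> list[VarietyArchetype]:
    """The seven-variety preset.

    ``separation`` scales every archetype's distance from the across-
    variety mean shape: 1 is the preset itself, 0 collapses all varieties
    onto one mean (a null assemblage where classification can only perform
    at chance).
    """
    rows = _preset_table()
    archs = []
    for row in rows:
        # axial profile: plumper below the middle, tapering to the beak end
        profile = np.array([0.80, 0.97, 1.00, 0.93, 0.72])
        profile = profile - row["taper"] * np.array(
            [-0.10, -0.05, 0.0, 0.12, 0.30]
        )
        r0 = row["r0_mid"] * profile
        amps = np.zeros((5, 6))
        amps[:, 0] = row["r2"] * r0  # r2 scales with local size
        amps[:, 1] = row["r3"] * r0
        amps[:, 2] = 0.012 * r0  # faint r4..r7 texture shared by all
        amps[:, 3] = 0.006 * r0
        amps[:, 4] = 0.003 * r0
        amps[:, 5] = 0.002 * r0
        phases = np.zeros((5, 6))
        phases[:, 1] = np.pi / 2  # r3 asymmetry across the broad face
        archs.append(
            dict(
                name=row["name"],
                length=row["length"],
                section_r0=r0,
                section_amps=amps,
                section_phases=phases,
                sd_length=0.18,
                sd_r0=0.05,
                sd_amps=0.012,
            )
        )
    if separation != 1.0:
        mean_len = np.mean([a["length"] for a in archs])
        mean_r0 = np.mean([a["section_r0"] for a in archs], axis=0)
        mean_amps = np.mean([a["section_amps"] for a in archs], axis=0)
        for a in archs:
            a["length"] = mean_len + separation * (a["length"] - mean_len)
            a["section_r0"] = mean_r0 + separation * (a["section_r0"] - mean_r0)
            a["section_amps"] = np.clip(
                mean_amps + separation * (a["section_amps"] - mean_amps),
                0.0,
                None,
            )
    return [VarietyArchetype(**a) for a in archs]


def default_assemblage(
    rng_seed: int = 0, grid: int = 200, separation: float = 1.0
) -> SyntheticAssemblage:
    """The default seven-variety study-sized assemblage."""
    return generate_assemblage(
        default_archetypes(separation=separation),
        list(DEFAULT_GROUP_SIZES),
        rng_seed=rng_seed,
        grid=grid,
    )


def write_assemblage(
    assemblage: SyntheticAssemblage, directory
) -> AssemblageManifest:
    """Write meshes as PLY plus a manifest CSV; returns the manifest."""
    from pathlib import Path

    from .mesh_io import write_manifest, write_mesh

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for mesh, label in zip(assemblage.meshes, assemblage.labels):
        path = directory / f"{mesh.source_id}.ply"
        write_mesh(mesh, path)
        entries.append((path, label))
    manifest = AssemblageManifest(entries=entries)
    write_manifest(manifest, directory / "manifest.csv")
    return manifest
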