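"""Reading, validation and writing of single-seed triangle meshes.

Seeds arrive one per file (PLY, OBJ or STL, millimetre units). Coordinates
are never rescaled on input: the mean-radius descriptor r0 is an absolute
size cue, so units must survive untouched. Multi-component files (scan
debris) are reduced to the largest connected component with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import MeshFormatError, MeshValidationError

_FORMATS = ("ply", "obj", "stl")

#: vertices closer than this (mm) are merged during cleaning
MERGE_TOLERANCE = 1e-9


@dataclass
class TriangleMesh:
    """A cleaned triangle mesh of one seed, coordinates in millimetres."""

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int
    label: str | None = None
    source_id: str | None = None
    watertight: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be an (m, 3) array")
        if not np.isfinite(self.vertices).all():
            raise MeshValidationError("non-finite vertex coordinates")
        if len(self.vertices) < 4 or len(self.faces) < 4:
            raise MeshValidationError(
                f"mesh too small: {len(self.vertices)} vertices, "
                f"{len(self.faces)} faces (need >= 4 of each)"
            )
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshValidationError("face index out of range")

    def to_trimesh(self) -> trimesh.Trimesh:
        """A trimesh view of this mesh; no processing applied."""
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            label=self.label,
            source_id=self.source_id,
            watertight=self.watertight,
            metadata=dict(self.metadata),
        )


@dataclass
class AssemblageManifest:
    """Paths and variety labels of the meshes forming one assemblage."""

    entries: list[tuple[Path, str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise MeshValidationError("manifest has no entries")
        paths = [Path(p) for p, _ in self.entries]
        if len(set(paths)) != len(paths):
            raise MeshValidationError("manifest paths are not distinct")
        for _, label in self.entries:
            if not isinstance(label, str) or not label.strip():
                raise MeshValidationError("manifest labels must be non-empty")
        self.entries = [(Path(p), str(l)) for p, l in self.entries]


@dataclass
class MeshReport:
    """Pure diagnostics of one mesh; never raises."""

    watertight: bool
    n_components: int
    largest_component_faces: int
    bounds: np.ndarray  # (2, 3) min/max
    extents: np.ndarray  # (3,)
    surface_area: float
    signed_volume: float | None  # only for watertight meshes
    oriented_consistently: bool


def _clean(tm: trimesh.Trimesh, source_id: str | None) -> TriangleMesh:
    """Merge near-duplicate vertices, drop degenerate faces, fix orientation,
    keep the largest connected component."""
    tm = tm.copy()
    tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=9)
    tm.update_faces(tm.nondegenerate_faces(height=1e-12))
    tm.remove_unreferenced_vertices()
    if tm.is_empty or len(tm.faces) == 0:
        raise MeshValidationError(f"{source_id}: empty mesh after cleaning")
    components = tm.split(only_watertight=False)
    if len(components) > 1:
        warnings.warn(
            f"{source_id}: {len(components)} connected components; "
            "keeping the largest (scan debris assumed)",
            stacklevel=3,
        )
        tm = max(components, key=lambda c: len(c.faces))
    try:
        trimesh.repair.fix_normals(tm)
    except Exception:  # orientation not always repairable on open meshes
        pass
    if tm.is_watertight and tm.volume < 0:
        tm.invert()
    if len(tm.vertices) < 4 or len(tm.faces) < 4:
        raise MeshValidationError(f"{source_id}: mesh too small after cleaning")
    return TriangleMesh(
        vertices=np.asarray(tm.vertices, dtype=float),
        faces=np.asarray(tm.faces, dtype=np.int64),
        source_id=source_id,
        watertight=bool(tm.is_watertight),
    )


def read_mesh(
    path: str | Path, format: str = "auto", label: str | None = None
) -> TriangleMesh:
    """Read one seed mesh from ``path`` and return it cleaned.

    Parameters
    ----------
    path:
        Mesh file (PLY ascii/binary, OBJ, STL ascii/binary).
    format:
        One of ``ply``, ``obj``, ``stl`` or ``auto`` (from the suffix).
    label:
        Optional variety label attached to the mesh.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"{path}: file does not exist")
    fmt = path.suffix.lstrip(".").lower() if format == "auto" else format
    if fmt not in _FORMATS:
        raise MeshFormatError(f"{path}: unsupported format {fmt!r}")
    try:
        loaded = trimesh.load(str(path), file_type=fmt, force="mesh", process=False)
    except Exception as exc:
        raise MeshFormatError(f"{path}: unreadable as {fmt}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise MeshFormatError(f"{path}: no triangle geometry found")
    mesh = _clean(loaded, source_id=path.stem)
    mesh.label = label
    return mesh


def write_mesh(mesh: TriangleMesh, path: str | Path, format: str = "auto") -> Path:
    """Write a mesh to PLY/OBJ/STL; the format follows the suffix by default.

    PLY and OBJ are written as ascii with full float64 precision, so
    read -> write -> read round-trips coordinates to 1e-12 and preserves
    the index structure exactly. STL stores float32 facets by design and
    cannot honour that contract.
    """
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower() if format == "auto" else format
    if fmt not in _FORMATS:
        raise MeshFormatError(f"{path}: unsupported format {fmt!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        _write_ply_ascii(mesh, path)
    elif fmt == "obj":
        _write_obj(mesh, path)
    else:
        mesh.to_trimesh().export(str(path), file_type="stl")
    return path


def _write_ply_ascii(mesh: TriangleMesh, path: Path) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(mesh.vertices)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in mesh.vertices]
    lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
    path.write_text("\n".join(lines) + "\n")


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    lines = [f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in mesh.vertices]
    lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in mesh.faces]
    path.write_text("\n".join(lines) + "\n")


def validate_mesh(mesh: TriangleMesh) -> MeshReport:
    """Diagnostic report: watertightness, components, extents, area, volume."""
    tm = mesh.to_trimesh()
    components = tm.split(only_watertight=False)
    n_components = max(len(components), 1)
    largest = max(components, key=lambda c: len(c.faces)) if len(components) else tm
    watertight = bool(tm.is_watertight)
    signed_volume = float(tm.volume) if watertight else None
    return MeshReport(
        watertight=watertight,
        n_components=n_components,
        largest_component_faces=len(largest.faces),
        bounds=np.asarray(tm.bounds, dtype=float),
        extents=np.asarray(tm.extents, dtype=float),
        surface_area=float(tm.area),
        signed_volume=signed_volume,
        oriented_consistently=bool(tm.is_winding_consistent),
    )


def load_manifest(path: str | Path) -> AssemblageManifest:
    """Load a UTF-8 CSV manifest with header ``path,label``.

    Relative mesh paths are resolved against the manifest's directory.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise MeshFormatError(f"{path}: unreadable manifest: {exc}") from exc
    if not {"path", "label"}.issubset(table.columns):
        raise MeshFormatError(f"{path}: manifest needs columns 'path' and 'label'")
    base = path.parent
    entries = []
    for _, row in table.iterrows():
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = base / p
        entries.append((p, str(row["label"])))
    return AssemblageManifest(entries=entries)


def write_manifest(manifest: AssemblageManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(str(p), l) for p, l in manifest.entries], columns=["path", "label"]
    ).to_csv(path, index=False)
    return path
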