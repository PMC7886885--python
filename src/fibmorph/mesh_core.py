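"""Triangle-mesh data model, STL I/O and validity checks.

All mesh coordinates are stored in nanometres (physical units), never in
voxel indices: every biological distance threshold used downstream (e.g.
the 30 nm / 90 nm organelle-proximity criteria) is physical, so unit
ambiguity is excluded at the data-model level.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "COMPARTMENTS",
    "CompartmentLabel",
    "TriangleMesh",
    "ValidityReport",
    "MeshError",
    "STLParseError",
    "read_stl",
    "write_stl",
    "validate",
    "weld_vertices",
]

#: Closed vocabulary of compartment names. ``qualifier`` refines but never
#: replaces one of these.
COMPARTMENTS = (
    "cell",
    "nucleus",
    "plastid",
    "mitochondrion",
    "pyrenoid",
    "thylakoid",
    "crista",
    "matrix",
    "storage",
    "other",
)


class MeshError(ValueError):
    """Invalid mesh construction or operation on an unsuitable mesh."""


class STLParseError(MeshError):
    """Corrupt or truncated STL file; message names the byte offset."""


@dataclass(frozen=True)
class CompartmentLabel:
    """A subcellular compartment identity.

    ``name`` must belong to the closed vocabulary in :data:`COMPARTMENTS`;
    ``qualifier`` carries free-text refinement (e.g. ``"mitochondrion"``
    qualified ``"network-2"``).
    """

    name: str
    qualifier: str = ""

    def __post_init__(self) -> None:
        if self.name not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.name!r}; must be one of {COMPARTMENTS}"
            )

    def __str__(self) -> str:
        return f"{self.name}:{self.qualifier}" if self.qualifier else self.name


@dataclass
class TriangleMesh:
    """An oriented triangle surface in nanometre coordinates.

    Face winding is counter-clockwise when viewed from outside for an
    outward-oriented mesh. Vertices are an ``(n, 3)`` float64 array, faces
    an ``(m, 3)`` int64 array of vertex indices.
    """

    vertices: np.ndarray
    faces: np.ndarray
    compartment: CompartmentLabel | None = None
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (m, 3) array")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshError("face index out of vertex range")
        degen = (
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 0] == self.faces[:, 2])
        )
        if degen.any():
            raise MeshError(f"{int(degen.sum())} degenerate face(s) with repeated indices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape ``(m, 3, 3)``."""
        return self.vertices[self.faces]

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), self.compartment, self.cell_id
        )

    def with_geometry(self, vertices: np.ndarray, faces: np.ndarray) -> "TriangleMesh":
        """New mesh with the same identity but different geometry."""
        return TriangleMesh(vertices, faces, self.compartment, self.cell_id)


@dataclass(frozen=True)
class ValidityReport:
    is_watertight: bool
    n_boundary_edges: int
    n_nonmanifold_edges: int
    is_consistently_oriented: bool
    n_components: int

    def __post_init__(self) -> None:
        expect = self.n_boundary_edges == 0 and self.n_nonmanifold_edges == 0
        if self.is_watertight != expect:
            raise ValueError("is_watertight inconsistent with edge counts")


# ---------------------------------------------------------------------------
# STL I/O
#
# Binary layout: 80-byte header, uint32 triangle count, then per triangle
# 12 float32 (normal + 3 vertices) + uint16 attribute = 50 bytes.
# ---------------------------------------------------------------------------

_RECORD = 50
_HEADER = 84


def _dedup_vertices(tri_pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse bit-identical coordinates of a triangle soup into a shared
    vertex table so edges become detectable. Winding order is preserved."""
    flat = tri_pts.reshape(-1, 3)
    verts, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    keep = ~(
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    return verts, faces[keep]


def read_stl(
    path: str | Path,
    compartment: CompartmentLabel | None = None,
    cell_id: str = "",
) -> TriangleMesh:
    """Read a binary or ASCII STL file into a :class:`TriangleMesh`.

    The dialect is sniffed by checking the binary size invariant
    ``len(file) == 84 + 50 * n`` first, because files whose 80-byte header
    begins with ``"solid"`` but whose body is binary are common in the wild.
    Vertices repeated across triangles are deduplicated by exact coordinate
    equality; face winding is preserved from the file.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) >= _HEADER:
        (count,) = struct.unpack_from("<I", raw, 80)
        if len(raw) == _HEADER + _RECORD * count:
            return _parse_binary(raw, count, path, compartment, cell_id)
    if raw.lstrip()[:5].lower() == b"solid":
        return _parse_ascii(raw, path, compartment, cell_id)
    if len(raw) < _HEADER:
        raise STLParseError(f"{path}: truncated file, {len(raw)} bytes < 84-byte binary header")
    (count,) = struct.unpack_from("<I", raw, 80)
    raise STLParseError(
        f"{path}: expected {_HEADER + _RECORD * count} bytes for {count} binary "
        f"triangles but file has {len(raw)} (corrupt at/after byte offset {min(len(raw), _HEADER)})"
    )


def _parse_binary(raw, count, path, compartment, cell_id) -> TriangleMesh:
    if count == 0:
        raise MeshError(f"{path}: STL contains zero triangles")
    body = np.frombuffer(raw, dtype=np.uint8, count=_RECORD * count, offset=_HEADER)
    records = body.reshape(count, _RECORD)
    floats = records[:, :48].copy().view("<f4").reshape(count, 4, 3)
    tri = floats[:, 1:, :].astype(np.float64)  # drop the stored normal
    verts, faces = _dedup_vertices(tri)
    if len(faces) == 0:
        raise MeshError(f"{path}: all triangles degenerate")
    return TriangleMesh(verts, faces, compartment, cell_id)


def _parse_ascii(raw, path, compartment, cell_id) -> TriangleMesh:
    pts: list[tuple[float, float, float]] = []
    for lineno, line in enumerate(raw.decode("ascii", errors="replace").splitlines(), 1):
        parts = line.split()
        if parts[:1] == ["vertex"]:
            if len(parts) != 4:
                raise STLParseError(f"{path}: malformed vertex line {lineno}")
            try:
                pts.append((float(parts[1]), float(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise STLParseError(f"{path}: bad coordinate on line {lineno}") from exc
    if len(pts) == 0:
        raise MeshError(f"{path}: STL contains zero triangles")
    if len(pts) % 3:
        raise STLParseError(
            f"{path}: vertex count {len(pts)} not a multiple of 3 (truncated facet)"
        )
    tri = np.asarray(pts, dtype=np.float64).reshape(-1, 3, 3)
    verts, faces = _dedup_vertices(tri)
    if len(faces) == 0:
        raise MeshError(f"{path}: all triangles degenerate")
    return TriangleMesh(verts, faces, compartment, cell_id)


def write_stl(mesh: TriangleMesh, path: str | Path, dialect: str = "binary") -> None:
    """Write ``mesh`` as STL; re-reading yields identical geometry.

    Normals are recomputed from winding. ``dialect`` is ``"binary"`` or
    ``"ascii"``.
    """
    if mesh.n_faces == 0:
        raise MeshError("refusing to write an empty mesh")
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    tri = mesh.triangles()
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.where(norm > 0, n / norm, 0.0)
    path = Path(path)
    if dialect == "binary":
        records = np.zeros((mesh.n_faces, _RECORD), dtype=np.uint8)
        floats = np.ascontiguousarray(
            np.concatenate([n[:, None, :], tri], axis=1), dtype="<f4"
        )
        records[:, :48] = floats.view(np.uint8).reshape(mesh.n_faces, 48)
        header = b"fibmorph binary STL".ljust(80, b" ")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", mesh.n_faces))
            fh.write(records.tobytes())
    else:
        name = str(mesh.compartment) if mesh.compartment else "mesh"
        lines = [f"solid {name}"]
        for fi in range(mesh.n_faces):
            nx, ny, nz = n[fi]
            lines.append(f"  facet normal {nx:.9g} {ny:.9g} {nz:.9g}")
            lines.append("    outer loop")
            for v in tri[fi]:
                lines.append(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {name}\n")
        path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Validity
# ---------------------------------------------------------------------------


def _edge_table(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directed edges (3 per face), their undirected keys, and face ids."""
    e = np.stack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=1
    ).reshape(-1, 2)
    face_of = np.repeat(np.arange(len(faces)), 3)
    und = np.sort(e, axis=1)
    return e, und, face_of


def validate(mesh: TriangleMesh) -> ValidityReport:
    """Check closedness, manifoldness, orientation consistency and count
    connected components (faces connected through shared edges).

    A mesh is watertight iff every undirected edge is shared by exactly two
    faces; it is consistently oriented iff, additionally, each such edge is
    traversed once in each direction.
    """
    if mesh.n_faces == 0:
        return ValidityReport(False, 0, 0, True, 0)
    directed, und, face_of = _edge_table(mesh.faces)
    keys, inverse, counts = np.unique(
        und, axis=0, return_inverse=True, return_counts=True
    )
    n_boundary = int((counts == 1).sum())
    n_nonmanifold = int((counts > 2).sum())

    # Orientation: among edges shared by exactly 2 faces, the two directed
    # copies must point in opposite directions.
    consistent = True
    pair_mask = counts[inverse] == 2
    if pair_mask.any():
        order = np.argsort(inverse[pair_mask], kind="stable")
        d = directed[pair_mask][order].reshape(-1, 2, 2)
        same_dir = (d[:, 0] == d[:, 1]).all(axis=1)
        consistent = not bool(same_dir.any())

    # Components over the face adjacency graph.
    n_comp = _face_components(mesh.faces, directed, inverse, counts, face_of)[0]
    return ValidityReport(
        is_watertight=(n_boundary == 0 and n_nonmanifold == 0),
        n_boundary_edges=n_boundary,
        n_nonmanifold_edges=n_nonmanifold,
        is_consistently_oriented=consistent,
        n_components=n_comp,
    )


def _face_components(faces, directed, inverse, counts, face_of):
    """Connected components of the shared-edge face graph.

    Returns (n_components, per-face component label).
    """
    # Faces sharing an undirected edge are adjacent. Build sparse adjacency
    # by grouping directed-edge rows by their undirected key.
    order = np.argsort(inverse, kind="stable")
    grp = inverse[order]
    f = face_of[order]
    boundaries = np.flatnonzero(np.diff(grp)) + 1
    groups = np.split(f, boundaries)
    rows, cols = [], []
    for g in groups:
        if len(g) > 1:
            rows.append(np.repeat(g[0], len(g) - 1))
            cols.append(g[1:])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        adj = coo_matrix(
            (np.ones(len(r)), (r, c)), shape=(len(faces), len(faces))
        )
        n, labels = connected_components(adj, directed=False)
    else:
        n, labels = len(faces), np.arange(len(faces))
    return n, labels


def face_components(mesh: TriangleMesh) -> np.ndarray:
    """Per-face connected-component labels (shared-edge connectivity)."""
    directed, und, face_of = _edge_table(mesh.faces)
    _, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    return _face_components(mesh.faces, directed, inverse, counts, face_of)[1]


def weld_vertices(mesh: TriangleMesh, epsilon: float) -> TriangleMesh:
    """Optional tolerance welding: merge vertices closer than ``epsilon`` nm
    by snapping to an ``epsilon``-pitch grid. Exact-duplicate removal happens
    already at STL read; this pass is for meshes produced by writers that
    perturb coordinates."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    snapped = np.round(mesh.vertices / epsilon) * epsilon
    verts, faces = _dedup_vertices(snapped[mesh.faces])
    return mesh.with_geometry(verts, faces)


def mesh_filename(cell_id: str, compartment: CompartmentLabel | str) -> str:
    """Filename convention ``<cell_id>__<compartment>.stl``."""
    name = compartment.name if isinstance(compartment, CompartmentLabel) else str(compartment)
    return f"{cell_id}__{name}.stl"


def parse_mesh_filename(filename: str) -> tuple[str, str]:
    """Inverse of :func:`mesh_filename`; returns (cell_id, compartment name)."""
    stem = Path(filename).stem
    if "__" not in stem:
        raise ValueError(f"filename {filename!r} does not follow <cell_id>__<compartment>.stl")
    cell_id, comp = stem.rsplit("__", 1)
    return cell_id, comp
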