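"""Surface, volume and occupancy measurements on organelle meshes.

Surface area is the sum over faces of half the cross-product magnitude of
two triangle edges. Enclosed volume is the sum of signed volumes of the
tetrahedra spanned by the origin and each triangle,

    V = | sum_f det(v0, v1, v2) / 6 |,

which is exact for a closed (watertight), consistently oriented surface and
independent of the choice of origin. Computation is carried out in nm;
reporting converts to um^2 / um^3 at the boundary only.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mesh_core import MeshError, TriangleMesh, face_components, validate

__all__ = [
    "MorphometricsRecord",
    "surface_area",
    "enclosed_volume",
    "orient_consistently",
    "measure",
    "occupancy",
    "compartment_ratio",
    "records_to_frame",
    "write_records_csv",
    "read_records_csv",
]

NM3_PER_UM3 = 1e9
NM2_PER_UM2 = 1e6

#: Exact CSV header for morphometrics tables.
RECORD_COLUMNS = [
    "cell_id",
    "tag",
    "compartment",
    "volume_um3",
    "surface_um2",
    "sv_ratio_per_um",
    "occupancy_pct",
]


@dataclass
class MorphometricsRecord:
    """Per-cell, per-compartment volume/surface bookkeeping (um units)."""

    cell_id: str
    tag: str
    compartment: str
    volume_um3: float
    surface_um2: float
    occupancy_pct: float | None = None
    signed_volume_um3: float | None = None  # diagnostic: sign before abs

    @property
    def sv_ratio_per_um(self) -> float:
        return self.surface_um2 / self.volume_um3


def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area in nm^2; orientation-independent."""
    if mesh.n_faces == 0:
        raise MeshError("cannot measure an empty mesh")
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(np.linalg.norm(cross, axis=1).sum() / 2.0)


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    tri = vertices[faces]
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def orient_consistently(mesh: TriangleMesh) -> TriangleMesh:
    """Repair mixed face windings by breadth-first propagation from a seed
    face within each connected component. The resulting orientation is
    consistent but may still be globally inward; callers relying on sign
    fix that with a signed-volume check."""
    faces = mesh.faces.copy()
    n_f = len(faces)
    # half-edge -> face lookup
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            edge_faces.setdefault((min(u, v), max(u, v)), []).append(fi)
    visited = np.zeros(n_f, dtype=bool)
    for seed in range(n_f):
        if visited[seed]:
            continue
        visited[seed] = True
        queue = deque([seed])
        while queue:
            fi = queue.popleft()
            a, b, c = faces[fi]
            for u, v in ((a, b), (b, c), (c, a)):
                key = (min(u, v), max(u, v))
                for fj in edge_faces[key]:
                    if fj == fi or visited[fj]:
                        continue
                    # neighbour consistent iff it traverses (v, u)
                    fa, fb, fc = faces[fj]
                    directed = ((fa, fb), (fb, fc), (fc, fa))
                    if (u, v) in directed:  # same direction -> flip neighbour
                        faces[fj] = faces[fj, ::-1]
                    visited[fj] = True
                    queue.append(fj)
    return mesh.with_geometry(mesh.vertices.copy(), faces)


def enclosed_volume(mesh: TriangleMesh, return_signed: bool = False):
    """Enclosed volume in nm^3 of a watertight mesh.

    Orientation is repaired automatically: windings are made consistent per
    component, and components whose signed contribution is negative (inward
    orientation) are counted by absolute value, so meshes holding several
    disjoint organelles (e.g. a cell's mitochondria stored in one file)
    measure as the sum of their volumes.
    """
    report = validate(mesh)
    if not report.is_watertight:
        raise MeshError(
            "enclosed volume requires a watertight mesh; validity: "
            f"{report.n_boundary_edges} boundary edge(s), "
            f"{report.n_nonmanifold_edges} non-manifold edge(s)"
        )
    m = mesh if report.is_consistently_oriented else orient_consistently(mesh)
    labels = face_components(m)
    total = 0.0
    signed_total = 0.0
    for comp in np.unique(labels):
        sv = _signed_volume(m.vertices, m.faces[labels == comp])
        signed_total += sv
        total += abs(sv)
    if return_signed:
        return total, signed_total
    return total


def component_volumes(mesh: TriangleMesh) -> np.ndarray:
    """Per-connected-component absolute enclosed volumes (nm^3)."""
    report = validate(mesh)
    if not report.is_watertight:
        raise MeshError("component volumes require a watertight mesh")
    m = mesh if report.is_consistently_oriented else orient_consistently(mesh)
    labels = face_components(m)
    return np.array(
        [abs(_signed_volume(m.vertices, m.faces[labels == c])) for c in np.unique(labels)]
    )


def measure(mesh: TriangleMesh, tag: str = "") -> MorphometricsRecord:
    """Measure one mesh into a :class:`MorphometricsRecord` (um units)."""
    vol_nm3, signed = enclosed_volume(mesh, return_signed=True)
    area_nm2 = surface_area(mesh)
    comp = mesh.compartment.name if mesh.compartment else "other"
    return MorphometricsRecord(
        cell_id=mesh.cell_id,
        tag=tag,
        compartment=comp,
        volume_um3=vol_nm3 / NM3_PER_UM3,
        surface_um2=area_nm2 / NM2_PER_UM2,
        signed_volume_um3=signed / NM3_PER_UM3,
    )


#: Organelles whose occupancies add into the "organelles_total" record.
MAIN_ORGANELLES = ("nucleus", "plastid", "mitochondrion")


def occupancy(
    records: Sequence[MorphometricsRecord], cell_record: MorphometricsRecord
) -> list[MorphometricsRecord]:
    """Fill ``occupancy_pct`` = 100 * compartment volume / cell volume.

    Appends a synthetic ``organelles_total`` record summing the occupancy of
    nucleus + plastid + mitochondrion (sub-compartments such as the pyrenoid
    are nested inside the plastid and not double-counted).
    """
    if cell_record.compartment != "cell":
        raise ValueError("cell_record must be the 'cell' compartment")
    cell_vol = cell_record.volume_um3
    out = []
    for rec in records:
        if rec.cell_id != cell_record.cell_id:
            raise ValueError(
                f"record {rec.compartment} belongs to cell {rec.cell_id!r}, "
                f"not {cell_record.cell_id!r}"
            )
        if rec.volume_um3 > cell_vol * (1 + 1e-9):
            raise ValueError(
                f"{rec.compartment} volume {rec.volume_um3:g} um^3 exceeds cell "
                f"volume {cell_vol:g} um^3: segmentation inconsistency"
            )
        filled = MorphometricsRecord(
            rec.cell_id,
            rec.tag,
            rec.compartment,
            rec.volume_um3,
            rec.surface_um2,
            occupancy_pct=100.0 * rec.volume_um3 / cell_vol,
            signed_volume_um3=rec.signed_volume_um3,
        )
        out.append(filled)
    total = sum(
        r.occupancy_pct for r in out if r.compartment in MAIN_ORGANELLES
    )
    out.append(
        MorphometricsRecord(
            cell_record.cell_id,
            cell_record.tag,
            "organelles_total",
            sum(r.volume_um3 for r in out if r.compartment in MAIN_ORGANELLES),
            float("nan"),
            occupancy_pct=total,
        )
    )
    return out


def compartment_ratio(
    numerator: MorphometricsRecord,
    denominator: MorphometricsRecord,
    quantity: str = "volume",
) -> float:
    """100 * numerator / denominator for volume or surface, same cell."""
    if numerator.cell_id != denominator.cell_id:
        raise ValueError("ratio requires records from the same cell")
    attr = {"volume": "volume_um3", "surface": "surface_um2"}.get(quantity)
    if attr is None:
        raise ValueError("quantity must be 'volume' or 'surface'")
    denom = getattr(denominator, attr)
    if denom == 0:
        raise ZeroDivisionError(f"zero denominator {quantity}")
    return 100.0 * getattr(numerator, attr) / denom


def records_to_frame(records: Iterable[MorphometricsRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "cell_id": r.cell_id,
                "tag": r.tag,
                "compartment": r.compartment,
                "volume_um3": r.volume_um3,
                "surface_um2": r.surface_um2,
                "sv_ratio_per_um": (
                    r.surface_um2 / r.volume_um3 if r.volume_um3 else float("nan")
                ),
                "occupancy_pct": (
                    float("nan") if r.occupancy_pct is None else r.occupancy_pct
                ),
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records_csv(records: Iterable[MorphometricsRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.6g")


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"morphometrics CSV missing columns {sorted(missing)}")
    return df
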