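"""End-to-end synthetic studies: generate cells, reconstruct, measure,
and score against the generator's analytic ground truth.

Two entry points matter:

* :func:`run_default_study` — the comparative design (by default three
  replicate cells for each of six size presets spanning ~2-200 um^3),
  measured from label volumes through meshing, decimation, occupancy and
  the plastid-mitochondrion volume coupling.
* :func:`run_stack_roundtrip` — one cell pushed through the full image
  path: render a drifted noisy stack, re-align, denoise, threshold-segment,
  reconstruct and measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh_core import CompartmentLabel, TriangleMesh
from .morphometrics import (
    MorphometricsRecord,
    measure,
    occupancy,
    records_to_frame,
)
from .proximity import vertex_to_mesh_distances
from .reconstruct import ReconstructionConfig, labels_to_mesh
from .stack_preprocess import (
    LabelVolume,
    align_stack,
    crop_roi,
    denoise,
    segment_threshold,
)
from .stats_report import CorrelationResult, fit_linear
from .synthetic_data import (
    SyntheticCellSpec,
    default_class_ranges,
    default_study_specs,
    make_cell_labels,
    render_intensity_stack,
)

__all__ = [
    "CellResult",
    "StudyResult",
    "measure_cell_from_labels",
    "run_default_study",
    "run_stack_roundtrip",
]

#: pyrenoid voxels belong to the plastid: meshing the plastid merges them.
NESTING = {"pyrenoid": "plastid"}


@dataclass
class CellResult:
    cell_id: str
    tag: str
    records: list[MorphometricsRecord]
    meshes: dict[str, TriangleMesh]
    manifest: dict
    measured_gaps: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class StudyResult:
    cells: list[CellResult]
    records: pd.DataFrame
    coupling_measured: CorrelationResult | None
    coupling_truth: CorrelationResult | None

    def volume_errors(self) -> pd.DataFrame:
        """Relative volume error of every measured compartment against the
        manifest's analytic value."""
        rows = []
        for cell in self.cells:
            truth = {
                c["compartment"]: c["analytic_volume_nm3"] / 1e9
                for c in cell.manifest["compartments"]
            }
            for rec in cell.records:
                if rec.compartment not in truth:
                    continue
                t = truth[rec.compartment]
                rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "compartment": rec.compartment,
                        "measured_um3": rec.volume_um3,
                        "analytic_um3": t,
                        "rel_error": (rec.volume_um3 - t) / t,
                    }
                )
        return pd.DataFrame(rows)

    def gap_errors(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            voxel = cell.manifest["voxel_size_nm"]
            for g in cell.manifest["gaps"]:
                key = (g["a"], g["b"])
                if key not in cell.measured_gaps:
                    continue
                rows.append(
                    {
                        "cell_id": cell.cell_id,
                        "pair": f"{g['a']}-{g['b']}",
                        "prescribed_nm": g["gap_nm"],
                        "measured_nm": cell.measured_gaps[key],
                        "error_nm": cell.measured_gaps[key] - g["gap_nm"],
                        "voxel_nm": voxel,
                        "error_voxels": (cell.measured_gaps[key] - g["gap_nm"]) / voxel,
                    }
                )
        return pd.DataFrame(rows)


def measure_cell_from_labels(
    labels: LabelVolume,
    manifest: dict,
    config: ReconstructionConfig | None = None,
    measure_gaps: bool = True,
) -> CellResult:
    """Mesh and measure every compartment of one label volume.

    Nested compartments (pyrenoid in plastid) are merged into the parent's
    mask when the parent is meshed, and measured separately as well. The
    cell mesh provides the denominator for occupancy percentages.
    """
    config = config or ReconstructionConfig()
    cell_id = manifest["cell_id"]
    tag = manifest["tag"]
    value_of = {c["compartment"]: c["label"] for c in manifest["compartments"]}
    children: dict[str, list[int]] = {}
    for comp, parent in NESTING.items():
        if comp in value_of and parent in value_of:
            children.setdefault(parent, []).append(value_of[comp])

    meshes: dict[str, TriangleMesh] = {}
    for comp, label_value in value_of.items():
        include = tuple(children.get(comp, ()))
        if comp == "cell":
            # the cell mask is everything that is not background
            include = tuple(v for v in value_of.values() if v != label_value)
        meshes[comp] = labels_to_mesh(
            labels,
            label_value,
            config,
            include_labels=include,
            compartment=CompartmentLabel(comp),
            cell_id=cell_id,
        )

    recs = [measure(m, tag=tag) for comp, m in meshes.items() if comp != "cell"]
    cell_rec = measure(meshes["cell"], tag=tag)
    # nested compartments are part of their parent, not parallel occupants
    top_level = [r for r in recs if r.compartment not in NESTING]
    nested = [r for r in recs if r.compartment in NESTING]
    filled = occupancy(top_level, cell_rec)
    filled.extend(nested)
    filled.append(cell_rec)

    measured_gaps = {}
    if measure_gaps:
        for g in manifest.get("gaps", []):
            a, b = g["a"], g["b"]
            if a in meshes and b in meshes:
                dist = vertex_to_mesh_distances(meshes[b], meshes[a]).distances.min()
                measured_gaps[(a, b)] = float(dist)
    return CellResult(cell_id, tag, filled, meshes, manifest, measured_gaps)


def run_default_study(
    seed: int = 0,
    n_cells: int = 3,
    presets: dict[str, float] | None = None,
    voxels_across: int = 64,
    config: ReconstructionConfig | None = None,
    specs: list[SyntheticCellSpec] | None = None,
) -> StudyResult:
    """Simulate the comparative study and recover the organelle coupling.

    Returns measured records for every cell plus two OLS fits of
    mitochondrion volume against plastid volume across cells: one on the
    pipeline's measurements and one on the generator's analytic volumes
    (the noise-implied truth that measurement error should not degrade).
    """
    if specs is None:
        specs = default_study_specs(
            seed=seed, n_cells=n_cells, presets=presets, voxels_across=voxels_across
        )
    cells = []
    for spec in specs:
        labels, manifest = make_cell_labels(spec)
        cells.append(measure_cell_from_labels(labels, manifest, config))

    frames = [records_to_frame(c.records).assign(cell_id=c.cell_id) for c in cells]
    records = pd.concat(frames, ignore_index=True)

    def fit(source: str) -> CorrelationResult:
        xs, ys, tags = [], [], []
        for c in cells:
            if source == "measured":
                vols = {r.compartment: r.volume_um3 for r in c.records}
            else:
                vols = {
                    m["compartment"]: m["analytic_volume_nm3"] / 1e9
                    for m in c.manifest["compartments"]
                }
            xs.append(vols["plastid"])
            ys.append(vols["mitochondrion"])
            tags.append(c.tag)
        return fit_linear(xs, ys, tags=tags)

    if len(cells) < 3:  # OLS needs three cells; tiny studies skip the fit
        return StudyResult(cells, records, None, None)
    return StudyResult(cells, records, fit("measured"), fit("truth"))


def run_stack_roundtrip(
    spec: SyntheticCellSpec,
    denoise_method: str = "median",
    denoise_params: dict | None = None,
    min_component_voxels: int = 30,
    config: ReconstructionConfig | None = None,
    margin_voxels: int = 12,
):
    """Full image path on one synthetic cell.

    Render the labelled cell into a drifted, noisy stack; re-align with
    previous-slice template matching; denoise; threshold-segment back into
    labels; reconstruct and measure. Returns ``(CellResult, true_trace,
    recovered_trace)`` for scoring both registration and morphometrics.
    """
    # a generous resin margin keeps enough landmark texture in frame for
    # registration even on slices without cell content
    labels, manifest = make_cell_labels(spec, margin_voxels=margin_voxels)
    stack, true_trace = render_intensity_stack(labels, spec)
    # corrections are absolute (template = previous *aligned* slice), so the
    # search must cover the total accumulated drift, not one step
    radius = max(2, spec.max_drift_total_px + spec.max_drift_step_px)
    aligned, recovered = align_stack(stack, search_radius=radius, presmooth_sigma=1.0)
    # crop to the common field: translation fill bands at the frame edges
    # would otherwise be segmented as spurious content
    my, mx = np.abs(recovered.shifts).max(axis=0).astype(int)
    nz, ny, nx = aligned.shape
    aligned = crop_roi(aligned, ((0, nz), (my, ny - my), (mx, nx - mx)))
    clean = denoise(aligned, denoise_method, **(denoise_params or {}))
    seg = segment_threshold(
        clean, default_class_ranges(spec), min_component_voxels=min_component_voxels
    )
    # map segmentation class names onto the manifest's label values
    remap = {c["compartment"]: c["label"] for c in manifest["compartments"]}
    out = np.zeros(seg.shape, dtype=np.int32)
    for value, name in seg.label_map.items():
        out[seg.labels == value] = remap[name]
    relabelled = LabelVolume(
        out, seg.voxel_size, {v: k for k, v in remap.items() if (out == v).any()}
    )
    result = measure_cell_from_labels(relabelled, manifest, config)
    return result, true_trace, recovered
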