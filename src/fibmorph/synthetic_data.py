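"""Ground-truth synthetic cells for every pipeline entry point.

Builds multi-compartment "cells" from parametric solids (spheres,
ellipsoids, capsules) whose surface areas and volumes are known in closed
form, then emits the same artefacts the real workflow consumes: triangle
meshes, voxelized label volumes at a stated voxel pitch, and noisy,
slice-drifted intensity stacks. Every stage of the measurement pipeline can
therefore be scored against analytic truth recorded in a manifest.

Geometry is deterministic given the seed; there is no hidden global
random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh
from scipy.special import ellipeinc, ellipkinc

from .mesh_core import CompartmentLabel, TriangleMesh
from .stack_preprocess import ImageStack, LabelVolume, ShiftTrace

__all__ = [
    "Sphere",
    "Ellipsoid",
    "Capsule",
    "OrganelleSpec",
    "SyntheticCellSpec",
    "make_parametric_mesh",
    "make_cell_labels",
    "render_intensity_stack",
    "standard_cell",
    "high_occupancy_cell",
    "default_study_specs",
    "STUDY_PRESETS",
]


# ---------------------------------------------------------------------------
# Parametric solids (all lengths in nm)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    def surface(self) -> float:
        return 4.0 * np.pi * self.radius**2

    def inside(self, pts: np.ndarray) -> np.ndarray:
        d = pts - np.asarray(self.center)
        return np.einsum("...i,...i->...", d, d) <= self.radius**2

    def bounds(self) -> np.ndarray:
        c = np.asarray(self.center)
        return np.stack([c - self.radius, c + self.radius])


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]  # semi-axes along x, y, z

    def __post_init__(self):
        if any(r <= 0 for r in self.radii):
            raise ValueError("semi-axes must be positive")

    def volume(self) -> float:
        a, b, c = self.radii
        return 4.0 / 3.0 * np.pi * a * b * c

    def surface(self) -> float:
        """Exact surface via incomplete elliptic integrals (Legendre form);
        spheroid and sphere limits are handled by the same formula."""
        a, b, c = sorted(self.radii, reverse=True)
        if (a - c) < 1e-9 * a:
            return 4.0 * np.pi * a * c  # sphere (use product for continuity)
        phi = np.arccos(c / a)
        m = (a**2 * (b**2 - c**2)) / (b**2 * (a**2 - c**2))
        s = np.sin(phi)
        return float(
            2 * np.pi * c**2
            + (2 * np.pi * a * b / s)
            * (ellipeinc(phi, m) * s**2 + ellipkinc(phi, m) * np.cos(phi) ** 2)
        )

    def inside(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - np.asarray(self.center)) / np.asarray(self.radii)
        return np.einsum("...i,...i->...", d, d) <= 1.0

    def bounds(self) -> np.ndarray:
        c = np.asarray(self.center)
        r = np.asarray(self.radii)
        return np.stack([c - r, c + r])


@dataclass(frozen=True)
class Capsule:
    """Cylinder of half-length ``half_length`` capped by hemispheres."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float
    half_length: float

    def __post_init__(self):
        if self.radius <= 0 or self.half_length < 0:
            raise ValueError("radius must be positive, half_length non-negative")
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(np.asarray(self.axis) / n))

    def volume(self) -> float:
        return np.pi * self.radius**2 * 2 * self.half_length + 4.0 / 3.0 * np.pi * self.radius**3

    def surface(self) -> float:
        return 2 * np.pi * self.radius * 2 * self.half_length + 4 * np.pi * self.radius**2

    def _segment(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        u = np.asarray(self.axis)
        return c - self.half_length * u, c + self.half_length * u

    def inside(self, pts: np.ndarray) -> np.ndarray:
        return _dist_point_segment(pts, *self._segment()) <= self.radius

    def bounds(self) -> np.ndarray:
        p0, p1 = self._segment()
        lo = np.minimum(p0, p1) - self.radius
        hi = np.maximum(p0, p1) + self.radius
        return np.stack([lo, hi])


def _dist_point_segment(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        return np.linalg.norm(pts - p0, axis=-1)
    t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
    proj = p0 + t[..., None] * d
    return np.linalg.norm(pts - proj, axis=-1)


def surface_gap(a, b) -> float:
    """Analytic minimal surface-to-surface distance between two solids.

    Closed forms exist for sphere/capsule combinations; ellipsoids have no
    elementary pair distance and are not accepted as gap-pair members.
    """
    if isinstance(a, Sphere) and isinstance(b, Sphere):
        return float(
            np.linalg.norm(np.asarray(a.center) - np.asarray(b.center)) - a.radius - b.radius
        )
    if isinstance(a, Sphere) and isinstance(b, Capsule):
        return float(
            _dist_point_segment(np.asarray(a.center)[None], *b._segment())[0]
            - a.radius
            - b.radius
        )
    if isinstance(a, Capsule) and isinstance(b, Sphere):
        return surface_gap(b, a)
    if isinstance(a, Capsule) and isinstance(b, Capsule):
        return float(_segment_segment_distance(*a._segment(), *b._segment()) - a.radius - b.radius)
    raise NotImplementedError(
        f"no closed-form gap between {type(a).__name__} and {type(b).__name__}"
    )


def _segment_segment_distance(p0, p1, q0, q1) -> float:
    """Minimal distance between two 3D segments (clamped closest points)."""
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d, e = u @ w, v @ w
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm(w + s * u - t * v))


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class OrganelleSpec:
    compartment: str
    shape: Sphere | Ellipsoid | Capsule
    intensity: float = 128.0
    nested_in: str | None = None  # parent compartment (pyrenoid -> plastid)

    def __post_init__(self):
        CompartmentLabel(self.compartment)  # vocabulary check


@dataclass
class SyntheticCellSpec:
    """A whole synthetic cell: outer shape, organelles, prescribed surface
    gaps for designated pairs, voxel pitch, and the drift/noise model of
    the rendered stack."""

    cell: OrganelleSpec
    organelles: list[OrganelleSpec]
    voxel_size_nm: float = 8.0
    gap_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    noise_sigma: float = 10.0
    max_drift_step_px: int = 3
    max_drift_total_px: int = 6
    background_intensity: float = 30.0
    #: amplitude of the bounded, spatially smooth resin texture added to
    #: background voxels; it drifts with the specimen and is what
    #: template matching locks onto in slices without cell content
    texture_amplitude: float = 12.0
    seed: int = 0
    cell_id: str = "synthetic"
    tag: str = "synthetic"

    def __post_init__(self):
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel size must be positive")
        if self.cell.compartment != "cell":
            raise ValueError("cell spec must have compartment 'cell'")
        names = [o.compartment for o in self.organelles]
        for a, b, gap in self.gap_pairs:
            sa = self._shape_of(a)
            sb = self._shape_of(b)
            actual = surface_gap(sa, sb)
            if abs(actual - gap) > max(1e-6, 1e-9 * gap):
                raise ValueError(
                    f"prescribed gap {gap} nm between {a} and {b} is not realised "
                    f"by the geometry (actual {actual:.3f} nm)"
                )

    def _shape_of(self, compartment: str):
        for o in [self.cell, *self.organelles]:
            if o.compartment == compartment:
                return o.shape
        raise KeyError(compartment)


# ---------------------------------------------------------------------------
# Parametric meshes
# ---------------------------------------------------------------------------


def make_parametric_mesh(
    spec: OrganelleSpec, subdivision: int = 4, cell_id: str = ""
) -> tuple[TriangleMesh, float, float]:
    """Closed, outward-oriented mesh of one solid plus its analytic surface
    and volume. Spheres/ellipsoids are icospheres (scaled for ellipsoids);
    capsules are capped cylinders with hemispherical ends."""
    if subdivision < 0:
        raise ValueError("subdivision must be >= 0")
    shape = spec.shape
    if isinstance(shape, Sphere):
        tm = _trimesh.creation.icosphere(subdivisions=subdivision, radius=shape.radius)
        tm.apply_translation(shape.center)
    elif isinstance(shape, Ellipsoid):
        tm = _trimesh.creation.icosphere(subdivisions=subdivision, radius=1.0)
        tm.apply_scale(shape.radii)
        tm.apply_translation(shape.center)
    elif isinstance(shape, Capsule):
        count = max(8, 4 * 2**subdivision)
        tm = _trimesh.creation.capsule(
            height=2 * shape.half_length, radius=shape.radius, count=(count, count)
        )
        tm.apply_translation(-tm.center_mass)  # centre on origin
        rot = _rotation_to(np.array([0.0, 0.0, 1.0]), np.asarray(shape.axis))
        tf = np.eye(4)
        tf[:3, :3] = rot
        tm.apply_transform(tf)
        tm.apply_translation(shape.center)
    else:
        raise TypeError(f"unsupported shape {type(shape).__name__}")
    mesh = TriangleMesh(
        np.asarray(tm.vertices, dtype=np.float64),
        np.asarray(tm.faces, dtype=np.int64),
        CompartmentLabel(spec.compartment),
        cell_id,
    )
    return mesh, shape.surface(), shape.volume()


def _rotation_to(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a to unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def make_cell_labels(spec: SyntheticCellSpec, margin_voxels: int = 3):
    """Voxelize a cell spec by the centre-of-voxel inclusion test.

    Returns ``(LabelVolume, manifest)``. The manifest records, per
    compartment, the analytic volume/surface, voxel count and label value,
    plus the prescribed pairwise surface gaps — everything needed to score
    downstream stages. Raises if an organelle escapes the cell or two
    non-nested organelles overlap.
    """
    vs = spec.voxel_size_nm
    lo, hi = spec.cell.shape.bounds()
    origin = lo - margin_voxels * vs
    shape = np.ceil((hi - origin) / vs).astype(int) + margin_voxels
    # grid is (z, y, x); world coordinates are (x, y, z)
    nz, ny, nx = int(shape[2]), int(shape[1]), int(shape[0])
    zs = origin[2] + (np.arange(nz) + 0.5) * vs
    ys = origin[1] + (np.arange(ny) + 0.5) * vs
    xs = origin[0] + (np.arange(nx) + 0.5) * vs
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)

    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    cell_mask = spec.cell.shape.inside(pts)
    labels[cell_mask] = 1
    label_map = {1: "cell"}
    masks = {"cell": cell_mask}
    value_of = {"cell": 1}
    for i, org in enumerate(spec.organelles, start=2):
        m = org.shape.inside(pts)
        if (m & ~cell_mask).any():
            raise ValueError(f"organelle {org.compartment} escapes the cell")
        for prev_name, prev_mask in masks.items():
            if prev_name == "cell":
                continue
            nested = org.nested_in == prev_name or _nested_name(spec, prev_name) == org.compartment
            if not nested and (m & prev_mask).any():
                raise ValueError(
                    f"organelles {org.compartment} and {prev_name} overlap but are not nested"
                )
        labels[m] = i
        label_map[i] = org.compartment
        masks[org.compartment] = m
        value_of[org.compartment] = i

    voxel_vol = vs**3
    compartments = []
    for o in [spec.cell, *spec.organelles]:
        name = o.compartment
        own = int((labels == value_of[name]).sum())
        # voxel count of the full solid includes nested children's voxels
        full = int(masks[name].sum())
        compartments.append(
            {
                "compartment": name,
                "label": value_of[name],
                "shape": type(o.shape).__name__.lower(),
                "nested_in": o.nested_in,
                "analytic_volume_nm3": o.shape.volume(),
                "analytic_surface_nm2": o.shape.surface(),
                "voxel_count": full,
                "voxel_count_exclusive": own,
                "voxel_volume_nm3": full * voxel_vol,
                "intensity": o.intensity,
            }
        )
    manifest = {
        "cell_id": spec.cell_id,
        "tag": spec.tag,
        "seed": spec.seed,
        "voxel_size_nm": vs,
        "grid_shape_zyx": [nz, ny, nx],
        "origin_nm_xyz": [float(v) for v in origin],
        "compartments": compartments,
        "gaps": [
            {"a": a, "b": b, "gap_nm": float(g)} for a, b, g in spec.gap_pairs
        ],
        "noise_sigma": spec.noise_sigma,
        "max_drift_step_px": spec.max_drift_step_px,
    }
    vol = LabelVolume(labels, (vs, vs, vs), label_map)
    return vol, manifest


def _nested_name(spec: SyntheticCellSpec, name: str) -> str | None:
    for o in spec.organelles:
        if o.compartment == name:
            return o.nested_in
    return None


def label_volume_origin(manifest: dict) -> np.ndarray:
    """World (x, y, z) nm coordinate of the grid corner, for mapping meshes
    reconstructed from the label grid back into spec coordinates."""
    return np.asarray(manifest["origin_nm_xyz"], dtype=np.float64)


# ---------------------------------------------------------------------------
# Intensity rendering
# ---------------------------------------------------------------------------


def render_intensity_stack(
    labels: LabelVolume, spec: SyntheticCellSpec
) -> tuple[ImageStack, ShiftTrace]:
    """Render a label volume into a noisy, drifted intensity stack.

    Per-label mean intensities come from the spec; Gaussian noise with
    ``noise_sigma`` is added; each slice is translated by a seeded
    bounded-step random walk (step ``<= max_drift_step_px`` per axis per
    slice), emulating slice-to-slice registration drift. The true applied
    ShiftTrace is returned for scoring the aligner.
    """
    rng = np.random.default_rng(spec.seed)
    intensity_of = {0: spec.background_intensity, 1: spec.cell.intensity}
    for i, org in enumerate(spec.organelles, start=2):
        intensity_of[i] = org.intensity
    nz, ny, nx = labels.shape
    pad = spec.max_drift_total_px + spec.max_drift_step_px

    # specimen canvas, one padded frame per slice: background plus a
    # bounded resin texture that is constant along the milling axis — the
    # persistent landmark pattern slice-to-slice template matching locks
    # onto. Bounded amplitude guarantees the texture can never cross the
    # background/cell segmentation threshold.
    texture = np.zeros((ny + 2 * pad, nx + 2 * pad))
    if spec.texture_amplitude > 0:
        from scipy import ndimage as _ndi

        texture = _ndi.gaussian_filter(rng.normal(size=texture.shape), sigma=1.0)
        peak = np.abs(texture).max()
        if peak > 0:
            texture *= spec.texture_amplitude / peak

    steps = rng.integers(
        -spec.max_drift_step_px, spec.max_drift_step_px + 1, size=(nz, 2)
    )
    steps[0] = 0
    # bounded random walk: cumulative drift stays within the padded margin
    shifts = np.clip(
        np.cumsum(steps, axis=0), -spec.max_drift_total_px, spec.max_drift_total_px
    )

    out = np.empty((nz, ny, nx), dtype=np.float64)
    canvas = np.empty_like(texture)
    for k in range(nz):
        canvas[:] = spec.background_intensity + texture
        sl = labels.labels[k]
        content = canvas[pad : pad + ny, pad : pad + nx]
        for value, level in intensity_of.items():
            if value != 0:
                content[sl == value] = level
        dy, dx = int(shifts[k, 0]), int(shifts[k, 1])
        # the frame crops the drifted specimen: content appears moved by
        # (+dy, +dx), and texture from outside the nominal frame slides in
        out[k] = canvas[pad - dy : pad - dy + ny, pad - dx : pad - dx + nx]
    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
    stack = ImageStack(out, labels.voxel_size, provenance=f"synthetic seed={spec.seed}")
    return stack, ShiftTrace(shifts)


def default_class_ranges(spec: SyntheticCellSpec):
    """Threshold intervals recovering the spec's intensity levels, listed
    innermost-first so nested compartments win the priority tie-break."""
    entries = [(o.compartment, o.intensity, o.nested_in is not None) for o in spec.organelles]
    entries.append(("cell", spec.cell.intensity, False))
    levels = sorted({spec.background_intensity} | {e[1] for e in entries})
    ranges = []
    # midpoints between adjacent levels define the interval edges
    for name, level, _nested in sorted(entries, key=lambda e: (not e[2], -e[1])):
        idx = levels.index(level)
        lo = (levels[idx - 1] + level) / 2 if idx > 0 else -np.inf
        hi = (levels[idx + 1] + level) / 2 if idx + 1 < len(levels) else np.inf
        ranges.append((name, (lo, hi)))
    return ranges


# ---------------------------------------------------------------------------
# Canonical layouts and the default comparative study
# ---------------------------------------------------------------------------

#: Intensity levels (arbitrary 8-bit-like units, higher = more stained).
INTENSITIES = {
    "background": 30.0,
    "cell": 80.0,
    "nucleus": 120.0,
    "mitochondrion": 160.0,
    "plastid": 200.0,
    "pyrenoid": 230.0,
}


def standard_cell(
    cell_radius_nm: float,
    voxel_size_nm: float,
    gap_nm: float,
    mito_volume_factor: float = 0.12,
    plastid_fraction: float = 0.16,
    nucleus_fraction: float = 0.05,
    pyrenoid_plastid_pct: float = 8.0,
    seed: int = 0,
    cell_id: str = "cell",
    tag: str = "standard",
) -> SyntheticCellSpec:
    """Spherical cell with plastid (+nested pyrenoid), nucleus and one
    mitochondrion placed at a prescribed surface gap from the plastid.

    The mitochondrion volume is ``mito_volume_factor`` times the plastid
    volume — the volumetric coupling between the two energy organelles that
    the correlation analysis downstream is designed to recover.
    """
    R = cell_radius_nm
    r_p = plastid_fraction ** (1 / 3) * R
    r_n = nucleus_fraction ** (1 / 3) * R
    r_m = (mito_volume_factor * plastid_fraction) ** (1 / 3) * R
    r_py = (pyrenoid_plastid_pct / 100.0) ** (1 / 3) * r_p

    c_p = np.array([0.44 * R, 0.0, 0.0])
    c_n = np.array([-0.62 * R, 0.0, 0.0])
    c_py = c_p + np.array([0.25 * r_p, 0.0, 0.0])

    # place the mitochondrion at the prescribed surface gap from the
    # plastid, swung as far from the nucleus as the cell membrane allows
    # (mitochondria hugging the periphery are the common arrangement)
    margin = max(0.01 * R, 0.5 * voxel_size_nm)
    D = r_p + r_m + gap_nm
    cp = float(np.linalg.norm(c_p))
    T = R - r_m - margin
    cos_phi = (cp * cp + D * D - T * T) / (2.0 * cp * D)
    if cos_phi > 1.0:
        raise ValueError(
            "mitochondrion cannot be placed inside the cell at the prescribed gap"
        )
    cos_phi = max(cos_phi, 0.0)
    sin_phi = float(np.sqrt(1.0 - cos_phi**2))
    c_m = c_p + D * np.array([-cos_phi, sin_phi, 0.0])
    if np.linalg.norm(c_m - c_n) < r_m + r_n + margin:
        raise ValueError(
            "mitochondrion placement collides with the nucleus; reduce the gap "
            "or the organelle fractions"
        )

    plastid = OrganelleSpec("plastid", Sphere(tuple(c_p), r_p), INTENSITIES["plastid"])
    pyrenoid = OrganelleSpec(
        "pyrenoid", Sphere(tuple(c_py), r_py), INTENSITIES["pyrenoid"], nested_in="plastid"
    )
    nucleus = OrganelleSpec("nucleus", Sphere(tuple(c_n), r_n), INTENSITIES["nucleus"])
    mito = OrganelleSpec(
        "mitochondrion", Sphere(tuple(c_m), r_m), INTENSITIES["mitochondrion"]
    )
    cell = OrganelleSpec("cell", Sphere((0.0, 0.0, 0.0), R), INTENSITIES["cell"])
    return SyntheticCellSpec(
        cell=cell,
        organelles=[plastid, pyrenoid, nucleus, mito],
        voxel_size_nm=voxel_size_nm,
        gap_pairs=[("plastid", "mitochondrion", float(gap_nm))],
        noise_sigma=10.0,
        max_drift_step_px=3,
        background_intensity=INTENSITIES["background"],
        seed=seed,
        cell_id=cell_id,
        tag=tag,
    )


def high_occupancy_cell(
    scale_nm: float = 1000.0,
    voxel_size_nm: float = 40.0,
    seed: int = 0,
    cell_id: str = "hi-occ",
    tag: str = "high_occupancy",
) -> SyntheticCellSpec:
    """Elongated cell with prescribed occupancy fractions (plastid 0.30,
    nucleus 0.10, mitochondrion 0.04) — the upper end of realistic organelle
    packing. Spherical organelles at these fractions cannot be disjoint
    inside any cell, so the cell is a prolate ellipsoid (as in pennate
    diatoms) with the three organelles strung along its long axis."""
    s = scale_nm
    plastid = OrganelleSpec(
        "plastid",
        Ellipsoid((-1.20 * s, 0.0, 0.0), (1.25 * s, 0.80 * s, 0.585 * s)),
        INTENSITIES["plastid"],
    )
    nucleus = OrganelleSpec(
        "nucleus",
        Ellipsoid((0.92 * s, 0.0, 0.0), (0.55 * s, 0.69 * s, 0.5131 * s)),
        INTENSITIES["nucleus"],
    )
    mito = OrganelleSpec(
        "mitochondrion",
        Ellipsoid((2.02 * s, 0.0, 0.0), (0.50 * s, 0.48 * s, 0.325 * s)),
        INTENSITIES["mitochondrion"],
    )
    cell = OrganelleSpec(
        "cell", Ellipsoid((0.0, 0.0, 0.0), (2.6 * s, 1.0 * s, 0.75 * s)), INTENSITIES["cell"]
    )
    return SyntheticCellSpec(
        cell=cell,
        organelles=[plastid, nucleus, mito],
        voxel_size_nm=voxel_size_nm,
        background_intensity=INTENSITIES["background"],
        seed=seed,
        cell_id=cell_id,
        tag=tag,
    )


#: Shape/scale presets for the comparative study: six "taxa" spanning the
#: ~2-200 um^3 cell-volume range typical of small eukaryotic phytoplankton.
STUDY_PRESETS = {
    "taxonA": 2.0,
    "taxonB": 5.0,
    "taxonC": 12.0,
    "taxonD": 30.0,
    "taxonE": 80.0,
    "taxonF": 200.0,
}

#: Grid resolution of study cells: voxels across the cell diameter. The
#: voxel pitch scales with the preset so the label grids stay tractable
#: while organelle diameters remain tens of voxels.
STUDY_VOXELS_ACROSS = 64


def default_study_specs(
    seed: int = 0,
    n_cells: int = 3,
    presets: dict[str, float] | None = None,
    mito_volume_factor: float = 0.12,
    mito_noise_cv: float = 0.05,
    voxels_across: int = STUDY_VOXELS_ACROSS,
) -> list[SyntheticCellSpec]:
    """The default comparative study: ``n_cells`` cells for each preset,
    with a fixed mitochondrion:plastid volume coupling (factor 0.12,
    log-normal noise of cv ~5%) and ±5% jitter on cell radius between
    replicate cells. Deterministic given ``seed``."""
    presets = presets or STUDY_PRESETS
    rng = np.random.default_rng(seed)
    specs = []
    for tag, vol_um3 in presets.items():
        base_R = (3.0 * vol_um3 * 1e9 / (4.0 * np.pi)) ** (1 / 3)
        for k in range(n_cells):
            R = base_R * float(rng.uniform(0.95, 1.05))
            voxel = 2.0 * R / voxels_across
            gap = 3.0 * voxel
            factor = mito_volume_factor * float(
                np.exp(rng.normal(0.0, mito_noise_cv))
            )
            specs.append(
                standard_cell(
                    cell_radius_nm=R,
                    voxel_size_nm=voxel,
                    gap_nm=gap,
                    mito_volume_factor=factor,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    cell_id=f"{tag}-{k + 1}",
                    tag=tag,
                )
            )
    return specs


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
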