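# fibmorph

Quantitative 3D subcellular morphometry for volume electron microscopy.

Focused ion beam scanning electron microscopy (FIB-SEM) turns a resin-embedded
cell into an isotropic 3D image stack (typically 8 × 8 × 8 nm³ voxels, 4 nm for
the smallest cells). From such stacks, quantitative cell biology needs a chain
of careful steps: registering the serial slices, denoising, segmenting
compartments, turning label volumes into triangle meshes, and measuring those
meshes — organelle volumes, surface areas, cell-volume occupancy, and the
proximity surfaces between organelles that serve as an operational proxy for
membrane contact sites. `fibmorph` implements that chain as a tested Python
library plus CLI, aimed at people quantifying organelle architecture in
phytoplankton and other single cells.

Because real FIB-SEM stacks are tens of gigabytes and segmentation is partly
manual, the package ships a first-class synthetic-cell generator: parametric
cells (spheres, ellipsoids, capsules) with closed-form surface areas and
volumes, voxelized at a stated pitch, rendered into noisy drifted stacks. Every
pipeline stage can therefore be scored against analytic ground truth.

## The measurements at the core

For a watertight triangle mesh with vertices in nm:

* **Surface area** — for each triangle with corners v₀, v₁, v₂,
  A = ‖(v₁ − v₀) × (v₂ − v₀)‖ / 2, summed over triangles.
* **Enclosed volume** — the signed volumes of the tetrahedra joining the
  origin to each triangle, V = |Σ det(v₀, v₁, v₂) / 6|, exact for a closed,
  consistently oriented surface and independent of the origin. Mixed or
  inverted windings are repaired automatically before measuring.
* **Proximity surfaces** — for every vertex of a source mesh (canonically the
  plastid) the exact minimal point-to-triangle distance to a target mesh
  (mitochondria) is computed; vertices within a physical threshold (30 nm for
  candidate contacts, 90 nm as the upper limit of proximity) contribute their
  barycentric vertex area (one third of incident face area), and the proximity
  area is reported as a fraction of the total source surface.
* **Decimation** — quadric edge-collapse simplification to 25% of the faces,
  with a built-in guarantee that enclosed volume drifts ≤ 1% and surface
  ≤ 2%, so measurements on simplified meshes remain trustworthy.

## Worked example

Build a synthetic cell (1 µm radius; plastid with nested pyrenoid, nucleus,
and a mitochondrion placed 60 nm from the plastid surface), voxelize it,
reconstruct every compartment, and measure:

```python
from fibmorph.synthetic_data import standard_cell, make_cell_labels
from fibmorph.study import measure_cell_from_labels
from fibmorph.proximity import contact_report

spec = standard_cell(cell_radius_nm=1000.0, voxel_size_nm=31.25,
                     gap_nm=60.0, seed=42, cell_id="demo", tag="demo")
labels, manifest = make_cell_labels(spec)
result = measure_cell_from_labels(labels, manifest)

for rec in result.records:
    occ = "" if rec.occupancy_pct is None else f"  occupancy {rec.occupancy_pct:5.2f} %"
    print(f"{rec.compartment:16s} V = {rec.volume_um3:8.4f} um^3   "
          f"S = {rec.surface_um2:8.4f} um^2{occ}")

r30, r90 = contact_report(result.meshes["plastid"],
                          [result.meshes["mitochondrion"]])
for r in (r30, r90):
    print(f"proximity <= {r.threshold_nm:.0f} nm: {r.proximity_area_um2:.4f} um^2 "
          f"({r.fraction_pct:.2f} % of plastid surface)")
```

which prints:

```
plastid          V =   0.6703 um^3   S =   3.7438 um^2  occupancy 15.99 %
nucleus          V =   0.2091 um^3   S =   1.7260 um^2  occupancy  4.99 %
mitochondrion    V =   0.0798 um^3   S =   0.9108 um^2  occupancy  1.90 %
organelles_total V =   0.9591 um^3   S =      nan um^2  occupancy 22.88 %
pyrenoid         V =   0.0527 um^3   S =   0.6898 um^2
cell             V =   4.1912 um^3   S =  12.7243 um^2
proximity <= 30 nm: 0.0000 um^2 (0.00 % of plastid surface)
proximity <= 90 nm: 0.0331 um^2 (0.88 % of plastid surface)
```

The plastid volume agrees with the generator's closed form (0.6702 µm³) to
0.01%; the mitochondrion sits 60 nm away, so nothing lies within 30 nm while
a small cap of the plastid surface lies within 90 nm. The pyrenoid is nested
inside the plastid (its volume is included in the plastid's) and is therefore
not a separate line in the occupancy accounting.

## Command line

The same chain is scriptable as stages over a shared JSON config:

```bash
fibmorph simulate    --config pipeline.json   # synthetic study -> label TIFFs
fibmorph reconstruct --config pipeline.json   # labels -> STL meshes
fibmorph measure     --config pipeline.json   # meshes -> morphometrics.csv
fibmorph proximity   --config pipeline.json   # meshes -> contacts.csv
fibmorph report      --config pipeline.json   # summaries + report.json
```

`fibmorph preprocess` covers the image side (crop, per-slice template-matching
registration, Gaussian-sharpen or median denoising, priority threshold
segmentation). Each stage writes a run manifest naming the config hash and
input checksums; reruns with the same config and seed are byte-identical.

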