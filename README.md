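# radcs

Automatic placement of an anatomical coordinate system (origin + right-handed
x/y/z triad) on full or partial radius bone surface meshes, together with the
machinery to study how robust that placement is when the bone is only
partially imaged:

- **`radcs.mesh_core`** — triangle-mesh data model, STL/PLY I/O (ASCII and
  binary), rigid transforms, left/right mirroring, and exact plane clipping
  for shortening experiments. All units are millimetres.
- **`radcs.rcs_auto`** — the placement algorithm: inertia tensor of the mesh
  vertices → smallest-eigenvalue axis oriented by a scan-direction hint →
  distal window (15% of the available length, at least 20 mm) → origin on the
  distal articular surface → x-axis toward the styloid process.
- **`radcs.error_metrics`** — pose error between a reference and a test
  frame: Δx/Δy/Δz in the reference frame, intrinsic y-x-z Euler angles in
  degrees, and the quadratic totals `d_err` and `phi_err`.
- **`radcs.synthetic_radius`** — parametric radius-like meshes (curved
  tapered shaft, distal flare, styloid bump) with known ground-truth frames,
  segmentation-noise emulation, and a stochastic manual-placement simulator.
- **`radcs.stats_eval`** — random-intercept linear mixed models with
  likelihood-ratio tests, Mann-Whitney U and Ansari-Bradley comparisons,
  two-way absolute-agreement ICC, and the end-to-end shortening experiment.
- **`radcs.cli`** — `radcs` command-line entry point.

## CLI

```sh
# generate a synthetic cohort (STL/PLY meshes + ground-truth JSON sidecars)
radcs simulate --n 5 --seed 1 --out cohort/

# place a coordinate system on a mesh (prints origin + axes, 12 numbers)
radcs place cohort/bone000.stl --json cs.json

# run the full shortening experiment (records.csv, summary.csv, stats.json)
radcs experiment --n 85 --seed 1 --out results/ --lengths 10,20,30,40,50,60,70,80,90,100

# per-length summary tables from a records CSV
radcs report --records results/records.csv
```

Meshes are assumed to be in millimetres in a right-handed frame with +z
roughly pointing distal (configurable via `--global-up`).

## Notes

- The experiment driver is deterministic given its seed; per-bone randomness
  is derived from (seed, bone index) so any bone is reproducible on its own.
- Clipping cuts triangles exactly at the plane and leaves the cut open (no
  cap), so vertex-based inertia computations are not biased by cap vertices.
- Binary STL stores float32 coordinates; use PLY (double precision) when
  exact round-trips matter.
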