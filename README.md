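# colkit

Cortical column detection and voxel-wise tuning metrics for mesoscopic
(sub-millimeter) fMRI.

Ultra-high-field fMRI can resolve cortical columns — e.g. axis-of-motion
columns in the human motion complex hMT+/V5 — but quantifying "how
columnar" a response pattern is, and how much of an apparent response is
draining-vein contamination rather than neural tuning, requires dedicated
voxel-wise statistics. `colkit` implements them for laminar-fMRI users who
already have per-condition t-value maps and a local cortical coordinate
frame (geodesic surface coordinates U, V in mm and normalized equi-volume
depth D, as produced by standard layering/flattening tools):

- **Sensitivity** of a voxel with condition t-vector **v** (K conditions):
  `S = ‖v‖₂`.
- **Specificity**: normalize **v** to unit length, sort entries ascending,
  take the angle θ to the reference winner `ŵ = [0, …, 0, 1]`, and score
  `1 − θ/θ_max` with `θ_max = arccos(1/√K)` (60° for K = 4, 45° for K = 2).
  1 = responds to exactly one condition, 0 = responds equally to all.
  Negative t-values are treated as absence of response and zeroed.
- **Voxel selection**: Benjamini–Hochberg FDR thresholding, leave-one-run-out
  cross-validated preference consistency (CV), CV plus all-conditions-positive
  response (CV+), and cluster-size filtering (threshold 4).
- **Columnarity index**: a searchlight that, at each voxel of the tuned
  domain (first extended to cover the full cortical thickness), collects all
  domain voxels inside a cylinder of radius 0.6 mm in the UV plane spanning
  the full depth, and reports the modal preference-label share
  `(# modal-label voxels)/(window size)` — 1 for a pure column, ≈ 1/K for
  label noise.
- **Benchmarks**: a "random" preference map (i.i.d. labels at native
  resolution, block-upsampled) and an "ideal" map of 1 mm hexagonal
  full-depth columns bracket empirical columnarity distributions from below
  and above.
- A **synthetic-data module** (flat and sinusoidally folded ribbon phantoms
  with analytic UVD coordinates; seeded multi-run t-value simulation with
  planted columns, untuned voxels and vessel-like voxels) makes the whole
  pipeline testable without acquired data.

## Worked example

```python
import numpy as np
import colkit as ck
from colkit.columnarity import CylinderSpec

geom  = ck.make_flat_slab(40, 40, 12, 0.2)            # 0.2 mm patch, 2.4 mm deep
truth = ck.hexbin_ideal_map(geom, 1.0, 4, seed=2)     # planted 1 mm columns, K=4
runs, classes = ck.simulate_runs(geom, truth, ck.SimulationConfig(seed=2))
avg   = ck.average_runs(runs)
pref  = ck.preference_map(avg, geom.gm_mask)
colmap = ck.columnarity_map(geom, pref, geom.gm_mask, CylinderSpec(radius=0.6))
print(np.median(colmap.values()))
```

Running `python examples/03_searchlight_columns.py` (this exact workflow)
prints:

```
preference recovery on tuned voxels: 100.0%
columnarity index over 19200 voxels: median 0.60, range [0.33, 0.95]
  columnar volume at index >= 0.25: 100.0% of the domain
  columnar volume at index >= 0.50:  72.9% of the domain
  columnar volume at index >= 0.65:  36.8% of the domain
```

The run-averaged preference map recovers every planted tuned voxel, and the
searchlight finds a median columnarity of 0.60: well above the matched
random benchmark (median 0.43) and below the noise-free ideal map (0.69) —
see `examples/04_benchmarks.py`, which prints exactly that bracketing.
The other examples cover the sensitivity/specificity scatter
(`01_sensitivity_specificity.py`), the three selection strategies
(`02_voxel_selection.py`) and the manifest-driven NIfTI pipeline
(`05_full_pipeline.py`).

A thin CLI mirrors the library for shell use:

```bash
colkit simulate-geometry --n-u 40 --n-v 40 --n-d 12 --voxel-size 0.2 --out-dir geom/
colkit benchmark-maps --geometry-dir geom/ --diameter 1.0 --k 4 --seed 1 --out-dir bench/
colkit columns --geometry-dir geom/ --pref bench/ideal_pref.nii.gz \
       --domain geom/mask.nii.gz --radius 0.6 --out-prefix out/ideal
colkit run --manifest manifest.txt
```

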