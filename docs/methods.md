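# Methods

## The measurement model

`colkit` operates downstream of a GLM: each gray-matter voxel carries a
K-vector **v** of t-values, one per stimulus condition (K = 4 axes of
motion in the motivating application), plus local cortical coordinates.
U and V (mm) parametrize the cortical surface geodesically; D ∈ [0, 1] is
the normalized equi-volume depth, 0 at the white-matter border and 1 at
the CSF border (the searchlight in full-depth mode is invariant to this
orientation convention). Everything the package computes — tuning
metrics, voxel selection, the columnarity index — is a function of these
two inputs.

## Sensitivity and specificity

Sensitivity is `‖v‖₂` of the raw vector; negative entries contribute
through squaring, and there is no zeroing clause. Specificity first zeroes
negative entries (a negative t is read as absence of neural response, not
suppression), normalizes to unit length, sorts ascending and measures the
angle to the reference winner `ŵ = [0…0, 1]`. Sorting confines the angle
to `[0, θ_max]` with `θ_max = arccos(1/√K)`; the score is `1 − θ/θ_max`.
Equivalently, after zeroing, `cos θ = max_i v_i / ‖v‖` — the sorted
construction realizes the minimal angle between any permutation of **v**
and any one-hot vector, which the test suite confirms by brute-force
enumeration for K ≤ 4. Angles are computed in degrees and dot products
clipped to [−1, 1] before the arccos; results are clipped to [0, 1]
against round-off.

Degenerate vectors (no positive entry after zeroing) have no tuning
direction: they score 0 and are counted and flagged, never silently
dropped. This is a package convention for an undefined corner case.
Response sets guaranteed all-positive (the CV+ set) skip zeroing via
`zero_negatives=False` / `negative_handling="reject"`.

Tuning curves group domain voxels by preferred condition and average their
K-vectors; the selectivity index of a group is the preferred-condition
mean divided by the mean over the other K−1 conditions. The per-voxel
preference label is the 1-based argmax, ties broken toward the lowest
condition index so maps are machine-independent.

## Voxel selection

FDR selection is Benjamini–Hochberg step-up (statsmodels) over the
caller's p-values at q = 0.05; p-values may be derived from t-statistics
with caller-supplied degrees of freedom (two-sided). The package never
fits GLMs.

CV selection iterates leave-one-run-out folds: training label = argmax of
the mean of the remaining runs, test label = argmax of the left-out run. A
voxel survives a fold when both agree and the all-runs-average label
equals that fold label; by default survival requires every fold (the
strictest reading of per-fold agreement), and `min_folds` exposes the
majority-agreement alternative since the two readings are both defensible.
CV+ keeps CV voxels with strictly positive run-averaged t for every
condition; exactly 0 counts as no positive response. Cluster-size
filtering (default threshold 4 voxels, 26-neighborhood; 6 and 18
available) is applied last, after set definition. Nestedness
CV+ ⊆ CV ⊆ seed domain holds by construction and is asserted on every
simulation.

## The cylindrical UVD searchlight

The tuned domain is first extended across the cortical thickness: a GM
voxel joins when at least one domain voxel lies within its full-depth
cylinder of the searchlight radius, so a lone mid-depth activation grows
into a complete depth column. The searchlight then visits every extended
domain voxel and collects domain voxels with in-plane distance
`√(ΔU² + ΔV²) ≤ r` (r = 0.6 mm default); with full-depth height (the
default and the only mode the reference analyses use) depth is
unconstrained, with a finite height h the window requires `|ΔD| ≤ h/2`.
The cylinder is a true cylinder — radius tested in UV only, height in D
only — not a 3D ball in UVD, since full-depth mode makes D irrelevant and
a ball would conflate surface distance with depth. The columnarity index
is the modal preference-label count divided by the window size; modal ties
use the tied maximal count (the index is unaffected) and report the lowest
tied label. Window size varies with local thickness and curvature, and
windows near patch edges simply contain fewer voxels; benchmark maps are
evaluated with identical edge behavior.

The 0.6 mm default radius makes the cylinder diameter (1.2 mm) slightly
larger than the longest in-plane diagonal a 0.8 mm acquisition voxel can
present to the cortical frame (√2 × 0.8 = 1.13 mm), while staying below
the 3D diagonal (√3 × 0.8 ≈ 1.38 mm). Note that on a grid coarser than
the radius every window degenerates to a single depth column and the
index saturates at 1; discriminative behavior requires the upsampled-grid
regime (0.2 mm here), matching how empirical maps are upsampled before
column analysis.

Derived summaries: thresholded column maps (labels kept where index ≥ t;
the threshold grid default is 0 to 1 in steps of 0.05), columnar volume
fraction (percent of domain at or above each threshold, non-increasing by
construction), mean sensitivity/specificity of survivors per threshold,
and a spatial consistency score between two contrasts: surviving-in-both
voxels with matching labels divided by the union of survivors, ×100. The
union denominator is a package choice — it is symmetric in the two
contrasts, where a per-contrast denominator would yield two different
curves.

## Benchmarks

The "random" map draws i.i.d. uniform labels on a grid coarsened by the
upsample factor (default 4, i.e. native 0.8 mm for a 0.2 mm patch) and
block-replicates them, mirroring label-preserving nearest-neighbor
upsampling of empirical maps. The "ideal" map tiles the UV plane with a
triangular lattice whose Voronoi cells are regular hexagons of flat-to-flat
width equal to `bin_diameter` (default 1 mm, exposed as a diameter; the
originating description mixes "radius" and "diameter" language), assigns
each bin one uniform label, and extends it through the full depth — an
upper-bound geometric ideal of 1 mm columns. Bin labels are i.i.d., so
adjacent bins may repeat labels. Benchmark comparison reports quartiles,
medians and 1.5 × IQR whiskers per distribution plus a verdict on whether
the empirical median falls between the random and ideal medians.

## The synthetic generator

Flat slabs have exact coordinates (U = i·Δ, V = j·Δ, D = (k+0.5)/n_d).
Curved patches follow a sinusoidal mid-surface; U is arc length along the
fold (the honest geodesic coordinate, checked against numeric arc-length
integration), D the normalized signed-normal offset, and folds whose
curvature radius falls below half the thickness are rejected as
self-intersecting. Simulated runs plant three voxel classes: tuned
(mean `amp_pref` on the true label, `amp_nonpref` elsewhere; defaults 5
and 1 t-units), untuned (mean 0), and vessel (mean `vessel_amp` = 8 on
every condition, seeded as 1 mm UV discs confined to D ≥ 0.6 to mimic
pial-vein contamination; default fraction 5%, untuned 10%). Per run,
voxel and condition, i.i.d. Gaussian noise of SD 1 t-unit is added —
sub-millimeter data are thermal-noise dominated — and four runs are the
default session. The default effect size of four noise SDs
(`amp_pref − amp_nonpref = 4·noise_sd`) is a strong but attainable
mesoscopic contrast.

The generator does **not** model spatial noise covariance (the scanner
point-spread function), hemodynamic time courses, GLM estimation error
structure, BOLD-vs-VASO biophysics, or realistic vascular trees. Passing
tests therefore demonstrate the algorithms' correctness and their behavior
under idealized thermal noise, not performance on acquired data; spatially
correlated noise would raise the random benchmark's columnarity floor.

## Problem sizes and numerics

Test and acceptance workloads use patches of 10⁴–2×10⁴ voxels (e.g.
40×40×12 at 0.2 mm, or 25×25×16 at 0.8 mm for selection statistics) —
comfortably larger than the regime where the statistics stabilize, and
the package's chosen standard fixture sizes. Window search uses a k-d
tree on UV coordinates; a brute-force enumeration oracle validates the
searchlight on small patches. All randomness flows through explicit
integer seeds (`numpy.random.default_rng`), making every simulation,
benchmark map and pipeline report bit-reproducible. NIfTI affines are the
sole authority on physical units (stored in float32 by the format; voxel
data round-trip bit-identically), and grids are never resampled
implicitly.

## Known limitations

- UVD coordinates are consumed, not computed: real-data use requires an
  external layering/flattening pipeline to produce them.
- The consistency score and benchmark verdict are descriptive; no
  inferential test on columnarity distributions is provided.
- The hexbin lattice assigns labels independently per bin; it does not
  emulate pinwheel-like continuity of preference across neighboring
  columns.
- Specificity of the degenerate all-non-positive vector is a convention
  (0, flagged), not an estimate.
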