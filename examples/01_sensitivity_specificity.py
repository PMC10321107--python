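"""Voxel-wise sensitivity and specificity of condition t-value vectors.

Builds a handful of archetypal 4-condition response vectors, scores them,
then shows how the two metrics separate tuned, untuned and vessel-like
voxels on a simulated patch.
"""

import numpy as np

import colkit as ck

archetypes = {
    "perfectly tuned  [0,0,0,6]": [0, 0, 0, 6],
    "well tuned       [1,1,1,3]": [1, 1, 1, 3],
    "untuned          [2,2,2,2]": [2, 2, 2, 2],
    "vessel-like      [7,8,7,8]": [7, 8, 7, 8],
    "negative entries [-2,0,0,1]": [-2, 0, 0, 1],
}
print(f"theta_max for K=4: {ck.theta_max(4):.1f} deg (45.0 deg for K=2)\n")
print(f"{'voxel':<30} {'sensitivity':>11} {'specificity':>11}")
for name, v in archetypes.items():
    v = np.array(v, float)
    print(f"{name:<30} {ck.sensitivity(v):>11.2f} {ck.specificity(v):>11.2f}")

# On a simulated patch the classes occupy distinct scatter regions:
geom = ck.make_flat_slab(40, 40, 12, 0.2)
truth = ck.hexbin_ideal_map(geom, 1.0, 4, seed=0)
cfg = ck.SimulationConfig(vessel_fraction=0.05, untuned_fraction=0.10, seed=0)
runs, classes = ck.simulate_runs(geom, truth, cfg)
avg = ck.average_runs(runs)
sens, spec, _, _ = ck.sensitivity_specificity_maps(avg, geom.gm_mask)
print("\nclass means on a simulated patch (sensitivity / specificity):")
for name, code in [("tuned", 1), ("untuned", 2), ("vessel", 3)]:
    m = classes == code
    print(f"  {name:<8} {sens[m].mean():6.2f} / {spec[m].mean():.2f}")
print("\nVessel voxels sit in the high-sensitivity/low-specificity corner —")
print("the voxel-wise signature of draining-vein contamination.")
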