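"""Show why projection-artifact removal matters for deep-slab metrics.

Simulates an eye with strong decorrelation tails (strength 0.5), measures
the DVC 2D perfusion density before and after removal, and compares both
against the exact planar ground truth.
"""

import octa3d as o
from octa3d import quantify2d as q2

config = o.SimEyeConfig(geometry=o.reduced_geometry(), tail_strength=0.5, seed=3)
_, octa, truth = o.simulate_eye(config)

bounds = q2.slab_bounds(truth.surfaces, "dvc")
truth_pct = 100 * o.planar_vessel_fraction(truth, bounds)


def dvc_density(volume):
    enface = q2.enface_project(volume, bounds)
    return q2.perfusion_density_2d(q2.binarize_enface(enface))


before = dvc_density(octa)
after = dvc_density(o.remove_projection_artifacts(octa))

print(f"ground-truth DVC planar coverage: {truth_pct:.2f} %")
print(f"DVC 2D density, tails untreated:  {before:.2f} %  "
      f"(error {before - truth_pct:+.2f} pp)")
print(f"DVC 2D density, after removal:    {after:.2f} %  "
      f"(error {after - truth_pct:+.2f} pp)")
# Superficial vessels cast exponential tails into the deep slab; removal
# attenuates them, pulling the measured density back toward the truth.
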