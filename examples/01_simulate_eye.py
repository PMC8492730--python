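"""Simulate one synthetic macular OCTA eye and inspect its ground truth.

Builds a desk-scale 3x3-mm-style scan pair (structural OCT + OCTA) with two
vascular plexuses and prints the realized vessel volume fractions, which
downstream quantification should recover.
"""

import octa3d as o

config = o.SimEyeConfig(geometry=o.reduced_geometry(), seed=42)
structural, octa, truth = o.simulate_eye(config)

print(f"volume shape (z, y, x): {octa.shape}")
print(f"axial pitch: {octa.geometry.axial_pitch_um:.2f} um, "
      f"lateral pitch: {octa.geometry.lateral_pitch_x_mm * 1000:.1f} um")
print(f"realized SCP vessel fraction: {truth.true_fraction_scp:.4f} "
      f"(target {config.target_fraction_scp})")
print(f"realized DVC vessel fraction: {truth.true_fraction_dvc:.4f} "
      f"(target {config.target_fraction_dvc})")
print(f"ground-truth vessel voxels: {truth.vessel_mask.n_true}")
# The realized fractions land within ~1% of the targets: the phantom's
# vasculature is exactly known, so pipeline errors are measurable.
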