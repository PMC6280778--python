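"""Simulate a dynamic cardiac PET phantom and inspect its ground truth.

The phantom renders a 29-frame, 27-minute acquisition with distinct
right-ventricular, left-ventricular and myocardial-wall kinetics, PSF
blur and frame-duration-scaled noise.  Every quantity the analysis
pipeline is supposed to recover is known exactly.
"""

import acemee as am

spec = am.PhantomSpec(seed=1)
image, truth = am.simulate_phantom(spec)

print(f"image shape {image.values.shape}, voxels {spec.voxel_size} mm")
print(f"frames: {image.schedule.n_frames}, total {image.schedule.total_duration:.0f} min")
print()
print("ground truth:")
for key, value in truth.summary().items():
    print(f"  {key:>18s} = {value:.4g}")
print()
print("Interpretation: a healthy-control heart. k2 is the acetate washout")
print("rate, which maps to MVO2 ~0.10 mL/g/min; MAP 97 mmHg and FCO ~4.6 L/min")
print("give the external work, and the 158 g wall at MVO2 sets the total")
print("energy use, so the true efficiency (mee_pct) is ~18.6%.")
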