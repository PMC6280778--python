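"""Fit the one-tissue spillover model, map it voxelwise, and segment the LV.

The single-compartment model with arterial and right-ventricular
spillover terms is fitted by the basis-function method: a grid of
washout rates k2 with a small non-negative linear problem at each grid
point.  The voxelwise K1/V_A maps then drive the automatic radial-profile
segmentation of the LV wall, whose volume gives LV mass at 1.05 g/cm3.
"""

import acemee as am
from acemee.input_functions import metabolite_correct, parent_fraction_sigmoid

image, truth = am.simulate_phantom(am.PhantomSpec(seed=1))
ifs = am.cluster_blood_pools(image)
ifs.c_p = metabolite_correct(ifs.c_a, parent_fraction_sigmoid)
basis = am.BasisSet.build(ifs.c_p, image.schedule)

frame_mean = image.values.mean(axis=3)
maps = am.make_parametric_maps(image, ifs, basis,
                               frame_mean > 0.05 * frame_mean.max())

midpoints = am.find_slice_midpoints(maps)
seg = am.segment_lv(maps, midpoints)
print(f"segmented {len(seg.qc['segmented_slices'])} short-axis slices")
print(f"LV mass {seg.lvm_g:.1f} g (true {truth.lvm_g:.1f} g)")

tac = am.extract_tac(image, seg.mask)
fit = am.fit_single_compartment(tac, ifs, basis)
mvo2 = am.mvo2_from_k2(fit.k2)
print(f"global LV fit: K1 {fit.k1:.3f} mL/g/min, k2 {fit.k2:.4f}/min "
      f"(true {truth.k2:.4f}), V_A {fit.v_a:.2f}, V_V {fit.v_v:.2f}")
print(f"MVO2 = 1.35*k2 - 0.0096 = {mvo2:.4f} mL/g/min (true {truth.mvo2:.4f})")
print()
print("Interpretation: k2, the acetate washout rate of the whole LV, is the")
print("oxidative-metabolism readout; V_A/V_V absorb blood spillover so the")
print("wall kinetics are not biased by the adjacent cavities.")
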