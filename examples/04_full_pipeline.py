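"""Run the complete single-scan MEE analysis and compare with ground truth.

One call orchestrates input functions, kinetics, segmentation, cardiac
output and the energy balance, with QC and a reproducibility fingerprint.
"""

import acemee as am

image, truth = am.simulate_phantom(am.PhantomSpec(seed=1))

vitals = am.VitalsRecord(timepoints_min=[-1.0, 1.0, 5.0],
                         sbp_mmhg=[124.0] * 3, dbp_mmhg=[79.0] * 3,
                         hr_min=[62.0] * 3, map_mmhg=[97.0] * 3)

report = am.run_mee_pipeline(am.PipelineConfig(), image=image, vitals=vitals,
                             dose_bq=truth.injected_dose_bq)

r = report.result
print(f"MEE  {r.mee_pct:6.2f} %   (true {truth.mee_pct:.2f} %)")
print(f"EW   {r.ew_j:6.1f} J   = MAP {r.map_mmhg:.0f} mmHg x FCO "
      f"{r.fco_ml_min:.0f} mL/min x 1.33e-4")
print(f"TE   {r.te_j:6.1f} J   = MVO2 {r.mvo2:.4f} x LVM {r.lvm_g:.1f} g x 20")
print(f"motion QC: max centroid shift "
      f"{report.qc['motion']['max_shift_mm']:.1f} mm "
      f"(suspected: {report.qc['motion']['motion_suspected']})")
print()
print("Interpretation: a healthy LV converts ~20% of the energy it consumes")
print("into forward stroke work; valvular disease lowers this ratio.")
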