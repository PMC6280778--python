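# acemee

Myocardial external efficiency (MEE) from a **single dynamic ¹¹C-acetate
cardiac PET scan**, fully automated.

MEE asks how much of the energy the left ventricle consumes is converted
into useful pumping work.  The classic measurement needs PET for
metabolism plus CMR or echo for cardiac output and mass; `acemee`
extracts everything from the one dynamic PET series:

```
MEE = EW / TE · 100%
EW  = MAP · FCO · 1.33·10⁻⁴        external work (J)
TE  = MVO₂ · LVM · 20              total energy use (J)
```

* **MVO₂** — the myocardial time–activity curve is fitted with a
  one-tissue compartment model with blood spillover,
  `C_PET(t) = (1−V_A)·K1·C_P(t) ⊗ e^(−k2·t) + V_A·C_A(t) + V_V·C_RV(t)`,
  and the washout rate maps to oxygen consumption via
  `MVO₂ = 1.35·k2 − 9.6·10⁻³` (mL O₂·g⁻¹·min⁻¹).
* **Input functions** — arterial and right-ventricular blood curves are
  found automatically by k-means clustering of voxel TAC shapes
  (physiological transit order tells the pools apart); the arterial curve
  becomes a metabolite-corrected plasma input.
* **LVM** — voxelwise parametric K1/V_A images (basis-function method)
  drive an automatic radial-profile segmentation: per short-axis slice,
  36 rays from the V_A centre of gravity, borders at the first/last point
  above 2/3 of each profile's maximum; mass = volume × 1.05 g·cm⁻³.
* **FCO** — indicator dilution: injected dose divided by the area under
  the gamma-variate-isolated arterial first-pass peak; forward stroke
  volume is FCO/HR.
* **MAP/HR** — vitals at −1, +1 and +5 min around injection, averaged.

A digital cardiac phantom (`acemee.phantom`) with exact ground truth for
every one of these quantities — kinetics, blood curves, mass, flow, MEE
itself — backs the test suite and the acceptance script.

## Worked example

```bash
python examples/04_full_pipeline.py
```

```
MEE   18.72 %   (true 18.57 %)
EW     58.8 J   = MAP 97 mmHg x FCO 4557 mL/min x 1.33e-4
TE    314.0 J   = MVO2 0.1008 x LVM 155.7 g x 20
motion QC: max centroid shift 1.7 mm (suspected: False)
```

A noisy phantom of a healthy control is simulated and analysed end to
end; the automated estimate lands within 1% of the phantom's true
efficiency.  A healthy LV converts roughly 20% of consumed energy into
forward stroke work; valvular disease lowers the ratio.  The other
scripts in `examples/` walk through the individual stages (phantom,
input functions, kinetics + segmentation, method agreement).

The same analysis is available from the shell:

```bash
acemee simulate --seed 2 --out-prefix ph          # writes NIfTI + sidecars
acemee mee ph.nii.gz ph.json --vitals vitals.csv --dose-mbq 410.4
acemee report mee_report.json
```

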