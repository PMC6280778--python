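# Methods

## Scope and model

`acemee` implements the fully automated single-scan estimation of
myocardial external efficiency (MEE) from a dynamic ¹¹C-acetate cardiac
PET series.  The energy balance is

    MEE = EW / TE · 100%,   EW = MAP·FCO·1.33e−4 [J],   TE = MVO₂·LVM·20 [J]

with MAP in mmHg, forward cardiac output FCO in mL·min⁻¹, MVO₂ in
mL O₂·g⁻¹·min⁻¹ and LV mass in grams.  1.33e−4 converts mmHg·mL to
joules and 20 converts mL O₂ to joules.  The conventional unit label is
joules although MAP·FCO and MVO₂·LVM are per-minute rates; we report the
numbers in these conventional units for comparability across the
literature.  EW uses the *forward* stroke volume and MAP alone (no
transvalvular gradient): the quantity estimated is the net, global LV
efficiency of pumping blood into the systemic circulation.

### Tissue kinetics

Myocardial activity follows a one-tissue compartment model with explicit
blood spillover:

    C_PET(t) = (1 − V_A)·K1·[C_P ⊗ e^(−k2·t)](t) + V_A·C_A(t) + V_V·C_RV(t)

K1 (mL·g⁻¹·min⁻¹) is the acetate uptake rate, k2 (min⁻¹) the washout
rate, V_A the arterial and V_V the right-ventricular blood fraction of a
voxel or region.  At fixed k2 the model is linear in
{(1−V_A)K1, V_A, V_V}; fitting scans 100 log-spaced k2 values in
[0.005, 1] min⁻¹ (basis-function method), solves a 3-parameter
non-negative least-squares problem per grid point, and refines the
winning k2 by bounded scalar minimisation (region fits) or by a
parabolic fit of the residual profile in log k2 (voxel maps).  The grid
spans well beyond the physiologic washout range so the operating range
0.03–0.3 min⁻¹ is resolved at ≲5% grid spacing before refinement.

Global MVO₂ uses the fit of the LV-mask mean TAC (not the mean of voxel
fits; the two differ under noise) and the washout calibration
MVO₂ = 1.35·k2 − 9.6e−3.

**Frame weighting.**  Rebinned dynamic frames have noise variance
proportional to activity/duration.  Fits therefore weight frames by
√duration by default, which whitens the duration-dependent part of the
variance without making weights data-dependent; at the phantom's default
noise this cuts the voxelwise k2 bias from ≈7% to ≈2%.  Unweighted and
custom weightings remain available (`weights="none"` / an array).

**Convolution.**  Inputs are linearly interpolated to a uniform 1 s grid
(frame durations span 5–300 s; convolving on the frame grid is badly
inaccurate during the bolus) and convolved with the washout exponential
by a trapezoidal recursive filter, then sampled at frame mid-times.

### Image-derived input functions

Voxels whose early-window (≤2 min) AUC exceeds the 75th percentile of
body voxels are clustered by k-means (k = 6, fixed seed) on TACs
normalised to unit area.  Clusters with an early, sharp peak (peak ≥5×
the late-frame level) are blood-like; grouping them by time-to-peak and
using the physiological transit order assigns the earlier group to the
right ventricle and the next to the arterial (LV-cavity) pool, taking
the tallest-peak cluster of each group as the pool core.  Curves are
means over a one-voxel erosion of the pool masks, which suppresses
partial-volume contamination at the pool borders.  The arterial curve
becomes the plasma input through a pluggable parent-fraction function;
the default is a sigmoid 1/(1+(t/12 min)^1.8), an average-shaped acetate
metabolite correction whose parameters live in the configuration and
should be replaced by site-calibrated values where available.

### Parametric images and LV segmentation

Voxelwise fits use an exact vectorised 3-variable NNLS (active-set
enumeration) over the k2 grid.  K1 is reported in its tissue-fraction
normalised form c₀/(1−V_A), which partial-volume-corrects the uptake on
the blood side; voxels with fitted total blood fraction V_A+V_V > 0.8
are classified as blood and carry K1 = 0 (the normalisation is
meaningless in near-pure blood).  The 0.8 cutoff is a conventional
majority-blood classification; together with the 2/3-threshold border
rule below it approximately balances the endo- and epicardial border
shifts that PSF blur induces.

Per short-axis slice, the LV-cavity mid-point is the intensity-weighted
centre of gravity of the V_A map restricted to the largest
high-V_A (>0.5) connected component whose arterial fraction dominates
its venous fraction — the V_A/V_V contrast is what separates the LV from
the RV cavity.  From each mid-point, 36 radial profiles (every 10°)
sample the K1 map at 0.5-voxel steps with linear interpolation; the K1
map is median-filtered 3×3 in-plane first, because the V_A-normalised
ratio amplifies noise where the blood fraction is large and a single
spiked voxel would otherwise set a profile's maximum.  On each profile
the endo- and epicardial borders are the first and last crossing of 2/3
of the profile maximum, localised sub-sample by linear interpolation
(the discrete first/last-sample rule rounds both borders inward by up to
one step).  Rays without a valid wall crossing (< 30% of the slice
maximum) are skipped and filled by circular interpolation; slices with
more than half their rays skipped are excluded.  The endo/epi contours
are densified to 1° and rasterised by 4× supersampled majority coverage,
and LVM = segmented volume × 1.05e−3 g·mm⁻³.

### Indicator-dilution cardiac output

A gamma-variate A·(t−t₀)^α·e^(−(t−t₀)/β) is fitted to the arterial curve
from bolus arrival to the first downslope frame below 30% of the peak
(which excludes recirculation), with the model evaluated as frame
averages, not point samples.  The first-pass area is the analytic
integral A·β^(α+1)·Γ(α+1), and FCO = injected dose / area.  A
config-supplied linear calibration (default identity) absorbs
scanner-dependent differences.  FSV = FCO / mean HR.

### Vitals

HR and blood pressure at −1, +1 and +5 min around injection are
averaged; missing timepoints are skipped.  Directly measured MAP is
preferred; otherwise MAP = (SBP + 2·DBP)/3 per timepoint, flagged
`derived` in the report.

### QC and reproducibility

Patient motion is flagged (never auto-excluded) when the activity
centroid of any post-2-min frame drifts more than 5 mm from the median.
Negative reconstruction voxels are retained for fitting and counted.
All seeds live in the configuration; a report carries a SHA-256
fingerprint of the configuration, and identical configurations produce
bit-identical reports.

## The digital phantom

The phantom is the package's verification instrument: a 64×64×12 grid of
2×2×10 mm voxels holding an LV-cavity disc (25 mm radius), a myocardial
annulus (25–35 mm) over eight 10-mm slices, and an adjacent RV cavity
(12 mm radius), all rendered with 4×4 sub-voxel occupancy fractions so
that boundary voxels carry the correct geometric mixture rather than a
staircase.  Default conditions emulate a healthy control:

| parameter | default | why |
|---|---|---|
| schedule | 12×5 s, 6×10 s, 4×30 s, 4×120 s, 3×300 s | 29 frames / 27 min acquisition |
| wall K1, k2 | 0.20 mL·g⁻¹·min⁻¹, 0.0812 min⁻¹ | k2 chosen so MVO₂ = 0.100, a control value |
| wall V_A | 0.15 | intrinsic myocardial blood volume |
| bolus | gamma-variate α=2, β=0.10 min, delay 0.10 min | arterial peak at 0.30 min |
| RV bolus | β=0.075 min, no delay | RV peak at 0.15 min, equal first-pass area |
| recirculation | 15% of first-pass area, 0.5 min delay, τ=2 min | dispersed tail |
| FCO, HR, MAP | 4560 mL·min⁻¹, 62 min⁻¹, 97 mmHg | control hemodynamics (cardiac index 2.4 L·min⁻¹·m⁻² at 1.9 m²) |
| dose | FCO × first-pass AUC ≈ 410 MBq | consistent with indicator dilution by construction |
| PSF FWHM | 6 mm | clinical whole-body PET resolution |
| noise scale | 10 | ≈5–8% per voxel per frame at wall activities |

Wall voxels follow the forward compartment model driven by the same
parent-fraction default as the analysis; cavity voxels follow their
blood curves; curves are integrated over each frame interval (mirroring
rebinned list-mode data) rather than sampled at mid-times.  Spillover is
produced physically by the PSF blur, not injected through the model's
spillover terms, so V_A/V_V recovery is a genuine test.  Noise is
zero-mean Gaussian with variance ∝ activity/duration.

**What the phantom does not emulate** — and hence what passing tests do
not demonstrate about patient data: Poisson sinogram statistics and
reconstruction correlations, attenuation/scatter artefacts, cardiac and
respiratory motion, apex/base anatomy (the wall is a straight annulus),
papillary muscles, and metabolite kinetics beyond the average parent
fraction.  Scanner-specific FCO calibration factors must come from an
external reference; the default calibration is identity.

## Numerical choices and degenerate inputs

- k2 grid [0.005, 1] min⁻¹, 100 points; solutions on the grid boundary
  are flagged.
- NNLS enforces non-negative coefficients; V_A+V_V > 1 is projected back
  to the simplex (flagged).  V_A ≥ 1 − 1e−9 forces K1 = 0.
- Empty masks, overlapping frames, frame-count mismatches, constant
  curves without a bolus peak, parent fractions outside (0, 1] and
  non-positive hemodynamics all raise immediately with specific errors.
- Pipeline stages wrap failures in a `StageError` carrying the stage
  name and the QC context collected so far.

## Known limitations

- The 2/3-of-maximum border rule systematically thins the measured wall
  when the profile shoulder is widened by partial volume and PSF blur;
  at 2 mm voxels the residual LVM bias is a few percent and grows for
  thin walls (≈ −6% at 8 mm).  This mirrors the behaviour of the
  radial-profile method on real scanners and is the dominant error term
  of the pipeline.
- The blood-classification cutoff (V_A+V_V > 0.8) trades endo- against
  epicardial border shifts; it is a fixed convention, not a fitted
  parameter.
- The metabolite correction is an average curve; per-subject metabolite
  analysis is out of scope.
- FCO is only as good as the first-pass isolation; severe recirculation
  overlap (very low output states) would bias the gamma-variate fit.
- The phantom's Gaussian noise is a desk-scale stand-in for full
  list-mode/reconstruction simulation.
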