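# Methods

## Model and assumptions

The package treats a vascular region's tracer/contrast curve as the
convolution of an upstream input with a transport function, under the
standard indicator-dilution assumptions: conservation of indicator (no
extraction between the sampled regions on the first pass), stationary flow
over the measurement, and well-mixed sampling regions.  Under these
assumptions the first-pass area is the same in every region
(`∫C_fp dt = D/CO`, the Stewart–Hamilton relation), centroids add along the
cascade, and the blood volume between two landmarks is `CO × MTT` (central
volume principle).

First-pass isolation follows the down-slope-fitting tradition: the
recirculation-free early curve determines a gamma-variate
`g(t) = A·u^α·e^{α−u}`, `u = (t−t0)/β`, whose analytic tail replaces the
measured, recirculation-contaminated tail.  This parameterization has
closed-form peak (`t0+αβ`), area (`A·β·e^α·Γ(α+1)`) and centroid
(`t0+β(α+1)`), which the estimators and the test oracles both use.

## First-pass isolation: numerical choices

* **Arrival detection.** Baseline is the mean of samples strictly before
  the threshold crossing, excluding the sample adjacent to it (a frame can
  straddle arrival); the threshold is baseline + 5 baseline-noise SDs, with
  a floor of 1 % of the peak excursion so noise-free input is handled;
  arrival is backtracked to the preceding local minimum.
* **Fit window.** Arrival to the first post-peak sample below 30 % of the
  baseline-corrected peak (configurable).  A curve whose down-slope never
  reaches the cut-off is fitted whole, with a warning.
* **Forward model.** The fit predicts *frame averages* using the exact
  per-frame integral of the gamma-variate (incomplete-gamma differences),
  not point values at frame mid-times.  With 5–30 s frames against ~10 s
  transit structures, mid-time evaluation biases area and centroid by
  several percent; frame integration removes that bias entirely, which is
  what lets region-to-region area agreement reach the sub-percent level.
* **Optimization.** Bounded least squares (`scipy.optimize.curve_fit`)
  from a deterministic ladder of six onset candidates, each initialized by
  a log-linear regression (`ln y` on `[1, ln(t−t0), −(t−t0)]`); solutions
  whose fitted peak falls outside the fit window are rejected as
  implausible.  No randomness anywhere in the fit, so the pipeline is
  reproducible run to run.
* **Area/centroid conventions.** Default (`auc_mode="model"`): closed forms
  on the fitted model, extrapolated to 0.1 % of peak.  Alternative
  (`auc_mode="hybrid"`): measured frame masses up to the down-slope cut-off
  (placed at the fitted model's within-frame mass centres) plus the
  analytic model tail — useful when the measured shape departs further from
  a gamma-variate.  On the synthetic cascade both agree to well under 1 %.
* **Mono-exponential tail** (`fit_method="exp_tail"`): log-linear fit of
  the strictly post-peak down-slope, measured frames plus `v_cut·τ` tail;
  provided as the classical alternative, a few percent less accurate here.
* **Degenerate inputs.** Flat curves or peaks at the first sample raise
  `NoBolusError`; fewer than five window samples or no converged start
  raises `FitError` with diagnostics.  Negative transit times are returned
  with a warning, never clipped.

## Transit readings for CMR and echo

CMR first-pass perfusion is sampled once per heartbeat, so peak-to-peak and
midpoint readings carry a ± one-beat-interval uncertainty; both the
half-maximum up-slope crossing (default "midpoint") and the temporal
midpoint between half-maximum crossings are implemented, since "midpoint"
is ambiguous.  Echo arrival is the first up-slope crossing of
baseline + k·(peak−baseline), default k = 0.1; on the synthetic cascade the
reading varies by <10 % for k in [0.05, 0.2].  These threshold readings
systematically underestimate the centroid MTT for dispersed downstream
curves (verified directionally in the tests) — they measure leading-edge
transit, not mean transit.  CMR blood volume uses right-ventricular CO and
echo uses left-ventricular CO, as the respective protocols specify; the CO
source chamber is recorded on every estimate.

## Synthetic generator

`simulate_transit` transports a gamma-variate venous bolus through three
segments (SVC→RV, RV→LV, LV→AAo), each a pure delay plus a gamma-density
dispersion kernel (mean = kernel mean, shape k; scale = mean/k).  Kernels
are discretized by CDF differences per bin, so unit mass and the first
moment survive discretization even for sub-grid kernels, and discrete
convolution then makes centroid differences equal segment MTTs essentially
exactly.  Recirculation feeds a delayed, dispersed, ρ-scaled copy of the
aortic output back into the SVC and iterates until the residual loop
contribution is negligible (convergent for ρ < 1).  Input amplitude is
scaled so dose / first-pass area equals the prescribed CO in every region.

Defaults are the study's printed resting hemodynamics: dose 400 MBq, CO
108.3 ml/s, HR 56 /min, RV→LV MTT 11.0 s and SVC→AAo 12.0 s (so the SVC→RV
and LV→AAo segments carry 0.5 s each), acquisition 240 s sampled at 0.5 s.
Values the study does not state are fixed at physiologically sensible
choices and documented here: bolus shape α = 3, β = 3 s, onset 6 s (a ~10 s
wide bolus arriving in the SVC shortly after an antecubital injection);
dispersion-kernel shape 5 (relative dispersion ≈ 0.45, typical of pulmonary
transport functions); recirculation fraction 0.3 with 35 s loop delay and a
broad (shape 2, mean 15 s) loop kernel; 5 % multiplicative Gaussian noise
floored at zero (Poisson option for count statistics).  Segment delays
default to 20 % of each segment MTT in the pipeline configuration.

The generator emulates curve *structure* — cascade dispersion,
recirculation, noise — not scanner physics: no attenuation, scatter,
partial volume, spill-over, motion, or ECG gating.  Passing tests therefore
demonstrate that the estimators are unbiased and noise-stable on curves
with the assumed structure, not that they are robust to reconstruction
artefacts in real data.

The 4-D phantom (`render_phantom4d`) paints region curves into a small
labelled voxel grid (default 12×12×6, ≥50 voxels per chamber) with
per-voxel noise, purely as a test surface for ROI extraction.

## Study pipeline and statistics

`run_pipeline` simulates n subjects (default 6) per condition — defaults
mirror the printed study: rest (CO 108.3 ml/s, MTT 11.0 s, HR 56), 2-min
apnea (40.0 ml/s, 16.5 s, HR 50), 4-min apnea (26.5 ml/s, 17.5 s, HR 55) —
with 10 % between-subject CO variation and 5 % MTT variation, rebins onto
the 20-frame dynamic scheme, isolates first passes, estimates CO/MTT/PBV
for RV→LV and SVC→AAo, and runs a one-way repeated-measures ANOVA on PBV
across conditions.  All child seeds derive from the study seed.

The RM-ANOVA uses the textbook sum-of-squares decomposition with subject as
block, `F = MS_condition/MS_error`, no sphericity correction by default
(Greenhouse–Geisser available behind a flag); it is cross-checked in the
tests against an independent residual-decomposition oracle and against
pingouin.  Post hoc comparisons are paired t-tests over all condition
pairs — the source protocol does not say whether all pairs or only
versus-rest were compared, so all pairs are reported — with Holm–Šidák
step-down adjustment (`1−(1−p_(k))^(m−k+1)`, running-maximum monotonicity,
capped at 1).  Identical-column inputs yield F = 0, p = 1 and post hoc
p = 1.  Percent decreases are rounded half-away-from-zero to whole percent
for comparison with printed integers; unrounded values are always
retained.  Simulation sizes (100 recovery phantoms; 2000 null replicates
for type-I calibration; 500 replicates for power at the printed effect
size) were chosen so Monte-Carlo error is small against the margins being
checked while the whole suite stays quick on a single CPU.

## Known limitations

* Curves are assumed decay-corrected; an O-15 decay correction
  (t½ = 122.24 s) is provided but off by default, since whether the source
  data were decay-corrected is unstated.
* Units are carried, never converted; CO units follow dose/AUC dimensional
  analysis (MBq with MBq/ml·s gives ml/s).
* The reported frame count of the dynamic protocol (21) contradicts its
  own printed blocks (20 frames / 240 s); the package follows the blocks
  and surfaces the mismatch in the reproduction report.
* Whether the printed SVC→AAo volumes used the LV or aortic first pass for
  CO is not fully explicit; the pipeline computes both spans and labels
  them.
* No myocardial perfusion quantification, no partial-volume or spill-over
  correction, no ventricular segmentation — out of scope by design.
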