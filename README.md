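# bolustransit

Indicator-dilution analysis of cardiopulmonary bolus transit: first-pass
isolation by down-slope fitting, Stewart–Hamilton cardiac output, centroid
mean transit times, and pulmonary blood volume, across the three imaging
modalities that measure them — dynamic PET time-activity curves, cardiac-MR
first-pass perfusion time-intensity curves, and contrast-echo arrival
curves — together with the accompanying study statistics (repeated-measures
ANOVA with Holm–Šidák post hoc, mean ± SEM summaries).

## The problem

When a tracer or contrast bolus is injected intravenously, its passage
through the central circulation encodes hemodynamics.  For a region with
concentration–time curve C(t), the classical indicator-dilution relations
are

* **Stewart–Hamilton flow**: `CO = D / ∫ C_fp(t) dt`, the injected dose D
  divided by the area under the *first-pass* curve;
* **mean transit time** between two regions: the difference of the
  first-pass curves' centroids `t̄ = ∫ t·C_fp dt / ∫ C_fp dt`;
* **blood volume** between the regions (central volume principle):
  `PBV = CO × MTT`.

The catch is recirculation: after one loop through the body the tracer
re-enters the heart and contaminates the tail of C(t).  The first pass is
isolated by *down-slope fitting* — a gamma-variate
`g(t) = A·((t−t0)/β)^α · exp(α−(t−t0)/β)` is fitted from bolus arrival to
the point where the down-slope falls below 30 % of the peak, and the fitted
model extrapolates the declining limb past the recirculation hump.  The fit
uses the exactly frame-integrated gamma-variate as its forward model, so
the coarse, uneven frames of a dynamic acquisition introduce no binning
bias; AUC and centroid then come from the model's closed forms
(`AUC = A·β·e^α·Γ(α+1)`, `t̄ = t0 + β(α+1)`).

Pulmonary transit by the other modalities uses simpler readings of the same
curves: peak-to-peak or half-maximum "midpoint" differences for per-beat CMR
intensity curves, and threshold arrival-time differences for contrast echo.
Chamber volumes give `SV = EDV − ESV` and `CO = SV × HR`.

Because the study the package reproduces deposits no public data, a
ground-truthed synthetic generator is a first-class component: a
gamma-variate venous bolus is transported through the SVC → RV → (lungs) →
LV → ascending-aorta cascade of delay + gamma-dispersion segments, with a
convergent recirculation loop and seeded measurement noise, scaled so that
dose / first-pass area equals the prescribed cardiac output in every region.
Every estimator is scored against this exact truth.

## Worked example

```python
from bolustransit import (PhantomTruth, simulate_transit, build_framing,
                          PET_DYNAMIC_BLOCKS, rebin, isolate_first_pass,
                          stewart_hamilton_co, centroid_mtt, ptt_in_beats)

truth = PhantomTruth(seed=7)            # CO 108.3 ml/s, RV->LV MTT 11.0 s
curves = simulate_transit(truth)        # SVC, RV, LV, AAo time-activity curves
scheme = build_framing(PET_DYNAMIC_BLOCKS)
frames = {r: rebin(c, scheme, start=0.0) for r, c in curves.items()}

fits = {r: isolate_first_pass(frames[r]) for r in ("RV", "LV")}
co = stewart_hamilton_co(truth.dose, fits["LV"])
mtt = centroid_mtt(fits["RV"], fits["LV"])
beats = ptt_in_beats(mtt, truth.hr)

print(f"cardiac output : {co:6.1f} ml/s   (truth {truth.co_true})")
print(f"RV->LV MTT     : {mtt:6.2f} s     (truth {truth.mtt_true('RV', 'LV')})")
print(f"pulmonary blood volume: {co * mtt:6.0f} ml (truth {truth.pbv_true():.0f})")
print(f"transit in beats: {beats.beats:.1f} -> {beats.rounded}")
```

prints

```
cardiac output :  108.9 ml/s   (truth 108.3)
RV->LV MTT     :  11.21 s     (truth 11.0)
pulmonary blood volume:   1220 ml (truth 1191)
transit in beats: 10.5 -> 10
```

The simulated acquisition carries 5 % multiplicative noise and a 0.3
recirculation fraction; down-slope fitting recovers cardiac output and
transit time to about half a percent at the median over many seeds.

The same machinery is exposed as a CLI — `bolustransit simulate | rebin |
firstpass | ptt | pbv | stats | run | report` — with curves as delimited
text (`t_start,t_end,region,value,units`; UTF-8, comma, '.' decimal) and
configs, truths and results as JSON.

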