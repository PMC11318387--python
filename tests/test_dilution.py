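"""First-pass isolation, Stewart-Hamilton CO, centroid MTT, PBV, beats."""

import dataclasses

import numpy as np
import pytest

from bolustransit import synthetic, tac
from bolustransit.dilution import (
    FirstPassResult,
    HemodynamicEstimate,
    NoBolusError,
    centroid_mtt,
    detect_arrival,
    isolate_first_pass,
    ptt_in_beats,
    pulmonary_blood_volume,
    stewart_hamilton_co,
)
from bolustransit.synthetic import BolusModel, PhantomTruth, simulate_bolus, simulate_transit


def _rect_first_pass(value=1.0, duration=10.0):
    """A rectangular first pass, for plain-arithmetic checks."""
    t = np.linspace(0, duration, 11)
    return FirstPassResult(model=None, baseline=0.0, fit_start=0.0,
                           fit_stop=duration, t=t, first_pass=np.full_like(t, value),
                           auc=value * duration, centroid=duration / 2,
                           residual_rms=0.0)


class TestIsolateFirstPass:
    def test_pure_gamma_identity(self, fine_grid):
        m = BolusModel(amplitude=0.02, alpha=3.0, beta=3.0, t0=6.0)
        fp = isolate_first_pass(simulate_bolus(m, fine_grid))
        assert fp.auc == pytest.approx(m.auc, rel=0.01)
        assert fp.centroid == pytest.approx(m.centroid, abs=0.2)
        assert fp.model.alpha == pytest.approx(m.alpha, rel=0.05)

    @pytest.mark.parametrize("auc_mode", ["model", "hybrid"])
    def test_recirculation_rejected_by_downslope_fitting(self, fine_grid, auc_mode,
                                                         pet_scheme):
        truth = PhantomTruth(noise_sigma=0.0, recirc_fraction=0.3, seed=0)
        oracle = simulate_transit(
            dataclasses.replace(truth, recirc_fraction=0.0), fine_grid)
        curves = simulate_transit(truth, fine_grid)
        for region in ("RV", "LV"):
            reb = tac.rebin(curves[region], pet_scheme, start=0.0)
            fp = isolate_first_pass(reb, auc_mode=auc_mode)
            assert fp.auc == pytest.approx(oracle[region].integral(), rel=0.02)

    def test_noisy_centroid_close_to_truth(self, fine_grid, pet_scheme):
        truth = PhantomTruth(noise_sigma=0.05, recirc_fraction=0.3, seed=7)
        oracle = synthetic.simulate_first_pass(truth, fine_grid)
        curves = simulate_transit(truth, fine_grid)
        for region in ("RV", "LV"):
            fp = isolate_first_pass(tac.rebin(curves[region], pet_scheme, start=0.0))
            assert fp.centroid == pytest.approx(oracle[region].centroid(), abs=0.5)

    def test_flat_curve_raises(self):
        flat = tac.TimeCurve.from_samples(np.arange(0.5, 100, 1.0), np.full(100, 2.0))
        with pytest.raises(NoBolusError):
            isolate_first_pass(flat)

    def test_first_pass_tracks_observed_upslope(self, clean_curves, pet_scheme):
        # the fitted first pass cannot exceed the measured frames on the
        # upslope (recirculation only ever adds signal)
        reb = tac.rebin(clean_curves["LV"], pet_scheme, start=0.0)
        fp = isolate_first_pass(reb)
        peak_i = int(np.argmax(reb.values))
        from bolustransit.dilution import _frame_mass

        params = (fp.model.amplitude, fp.model.alpha, fp.model.beta, fp.model.t0)
        model_frames = _frame_mass(params, reb.t_start, reb.t_end) / reb.duration
        observed = reb.values - fp.baseline
        tol = 0.02 * reb.values.max()
        assert np.all(model_frames[:peak_i + 1] <= observed[:peak_i + 1] + tol)

    def test_exp_tail_alternative(self, clean_curves, pet_scheme):
        reb = tac.rebin(clean_curves["LV"], pet_scheme, start=0.0)
        fp = isolate_first_pass(reb, fit_method="exp_tail")
        assert fp.mode == "exp_tail"
        assert fp.auc == pytest.approx(clean_curves["LV"].integral(), rel=0.05)

    def test_arrival_detection_with_nonzero_baseline(self, rng):
        t = np.arange(0.5, 120, 1.0)
        signal = BolusModel(amplitude=1.0, alpha=3.0, beta=3.0, t0=40.0)(t)
        v = 0.5 + signal + 0.002 * rng.standard_normal(t.size)
        idx, base, sd = detect_arrival(v)
        assert base == pytest.approx(0.5, abs=0.01)
        assert 35 <= t[idx] <= 42


class TestStewartHamilton:
    def test_rectangular_first_pass_arithmetic(self):
        # 400 MBq over a 1 MBq/ml x 10 s first pass -> 40 ml/s
        assert stewart_hamilton_co(400.0, _rect_first_pass(1.0, 10.0)) == pytest.approx(40.0)

    def test_dose_linearity(self):
        fp = _rect_first_pass(0.7, 13.0)
        assert stewart_hamilton_co(800.0, fp) == pytest.approx(
            2.0 * stewart_hamilton_co(400.0, fp))

    def test_recovers_generator_cardiac_output(self, clean_truth, clean_curves,
                                               pet_scheme):
        reb = tac.rebin(clean_curves["LV"], pet_scheme, start=0.0)
        co = stewart_hamilton_co(clean_truth.dose, isolate_first_pass(reb))
        assert co == pytest.approx(clean_truth.co_true, rel=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            stewart_hamilton_co(0.0, _rect_first_pass())
        bad = _rect_first_pass()
        bad.auc = 0.0
        with pytest.raises(ValueError):
            stewart_hamilton_co(400.0, bad)


class TestCentroidMtt:
    def test_shifted_identical_curves(self, fine_grid):
        m = BolusModel(amplitude=0.02, alpha=3.0, beta=3.0, t0=5.0)
        shifted = dataclasses.replace(m, t0=m.t0 + 7.6)
        fp_a = isolate_first_pass(simulate_bolus(m, fine_grid))
        fp_b = isolate_first_pass(simulate_bolus(shifted, fine_grid))
        assert centroid_mtt(fp_a, fp_b) == pytest.approx(7.6, abs=0.05)

    def test_identical_curves_give_zero(self, clean_curves, pet_scheme):
        fp = isolate_first_pass(tac.rebin(clean_curves["RV"], pet_scheme, start=0.0))
        assert centroid_mtt(fp, fp) == 0.0

    def test_recovers_generator_transit_time(self, clean_truth, clean_curves,
                                             pet_scheme):
        fps = {r: isolate_first_pass(tac.rebin(clean_curves[r], pet_scheme, start=0.0))
               for r in ("RV", "LV")}
        mtt = centroid_mtt(fps["RV"], fps["LV"])
        assert mtt == pytest.approx(clean_truth.mtt_true("RV", "LV"), abs=0.5)

    def test_negative_transit_warns_not_clips(self):
        a = _rect_first_pass()
        b = dataclasses.replace(a, centroid=a.centroid - 2.0)
        with pytest.warns(RuntimeWarning, match="negative transit"):
            assert centroid_mtt(a, b) == pytest.approx(-2.0)


class TestDownslopeBeatsNaiveIntegration:
    def test_naive_auc_overestimates_with_recirculation(self, fine_grid, pet_scheme):
        truth = PhantomTruth(noise_sigma=0.0, recirc_fraction=0.3, seed=0)
        curve = simulate_transit(truth, fine_grid)["LV"]
        naive_auc = curve.integral()
        fp = isolate_first_pass(tac.rebin(curve, pet_scheme, start=0.0))
        assert naive_auc > fp.auc
        co_naive = truth.dose / naive_auc
        co_fp = stewart_hamilton_co(truth.dose, fp)
        assert co_naive < co_fp
        assert abs(co_fp - truth.co_true) < abs(co_naive - truth.co_true)


class TestVolumeAndBeats:
    def test_pbv_examples(self):
        assert pulmonary_blood_volume(55.0, 7.6) == pytest.approx(418.0)
        assert pulmonary_blood_volume(0.0, 123.0) == 0.0
        prod = pulmonary_blood_volume(108.3, 12.0)
        assert prod == pytest.approx(1299.6)
        assert abs(prod - 1295.0) <= 88.0   # one SEM of the reported volume
        with pytest.raises(ValueError):
            pulmonary_blood_volume(-1.0, 5.0)

    def test_pbv_identity_by_construction(self):
        est = HemodynamicEstimate(co=55.0, mtt=7.6, hr=61.0)
        assert est.pbv == est.co * est.mtt

    @pytest.mark.parametrize("ptt, hr, beats, rounded", [
        (11.0, 56.0, 10.2667, 10),
        (16.5, 50.0, 13.75, 14),
        (60.0, 60.0, 60.0, 60),
    ])
    def test_beats_conversion(self, ptt, hr, beats, rounded):
        got = ptt_in_beats(ptt, hr)
        assert got.beats == pytest.approx(beats, abs=1e-3)
        assert got.rounded == rounded

    def test_beats_requires_positive_hr(self):
        with pytest.raises(ValueError):
            ptt_in_beats(10.0, 0.0)
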