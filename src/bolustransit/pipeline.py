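"""Config-driven end-to-end runs on synthetic acquisitions.

A study configuration describes the conditions (rest, 2-min apnea, 4-min
apnea by default), the acquisition framing, fit switches and seeds.
``run_pipeline`` simulates each subject's bolus transit per condition,
rebins the curves onto the acquisition framing, isolates the first passes,
estimates CO, MTT and PBV, and closes with a repeated-measures ANOVA on PBV
across conditions.  Every stochastic step derives its seed from the study
seed, so reruns are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import dilution, synthetic, tac
from .stats import rm_anova

logger = logging.getLogger(__name__)

__all__ = ["ConditionConfig", "FitConfig", "StudyConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class ConditionConfig(BaseModel):
    """Ground-truth hemodynamics of one study condition."""

    co_ml_s: float = Field(gt=0, description="true forward cardiac output, ml/s")
    hr_bpm: float = Field(gt=0, description="heart rate, beats/min")
    mtt_svc_rv_s: float = Field(default=0.5, gt=0)
    mtt_rv_lv_s: float = Field(gt=0, description="pulmonary mean transit time, s")
    mtt_lv_aao_s: float = Field(default=0.5, gt=0)
    delay_fraction: float = Field(default=0.2, ge=0, lt=1,
                                  description="share of each segment MTT that is pure delay")

    def segments(self) -> tuple[synthetic.TransportSegment, ...]:
        out = []
        for label, mtt in (("SVC-RV", self.mtt_svc_rv_s),
                           ("RV-LV", self.mtt_rv_lv_s),
                           ("LV-AAo", self.mtt_lv_aao_s)):
            out.append(synthetic.TransportSegment(
                label, delay=self.delay_fraction * mtt,
                kernel_mean=(1.0 - self.delay_fraction) * mtt))
        return tuple(out)


class FitConfig(BaseModel):
    """Switches for first-pass isolation and arrival detection."""

    method: str = "gamma"             # "gamma" | "exp_tail"
    auc_mode: str = "model"           # "model" | "hybrid"
    downslope_frac: float = Field(default=0.3, gt=0, lt=1)
    arrival_k: float = Field(default=0.1, gt=0, lt=1)

    @field_validator("method")
    @classmethod
    def _method(cls, v):
        if v not in ("gamma", "exp_tail"):
            raise ValueError(f"unknown fit method {v!r}")
        return v

    @field_validator("auc_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("hybrid", "model"):
            raise ValueError(f"unknown auc mode {v!r}")
        return v


def _default_conditions() -> dict[str, "ConditionConfig"]:
    # Truth values mirror the printed resting and apnea hemodynamics:
    # CO 108.3 -> 40 -> 26.5 ml/s, RV->LV MTT 11.0 -> 16.5 s, with heart
    # rates 56 -> 50 -> 55 beats/min.
    return {
        "rest": ConditionConfig(co_ml_s=108.3, hr_bpm=56, mtt_rv_lv_s=11.0),
        "apnea_2min": ConditionConfig(co_ml_s=40.0, hr_bpm=50, mtt_rv_lv_s=16.5),
        "apnea_4min": ConditionConfig(co_ml_s=26.5, hr_bpm=55, mtt_rv_lv_s=17.5),
    }


class StudyConfig(BaseModel):
    """Everything an end-to-end synthetic study run needs."""

    modality: str = "PET"
    seed: int = 0
    n_subjects: int = Field(default=6, ge=1)
    dose_mbq: float = Field(default=400.0, gt=0)
    noise_sigma: float = Field(default=0.05, ge=0)
    recirc_fraction: float = Field(default=0.3, ge=0)
    recirc_delay_s: float = Field(default=35.0, ge=0)
    subject_cv: float = Field(default=0.1, ge=0,
                              description="between-subject relative spread of CO and MTT")
    grid_dt_s: float = Field(default=0.5, gt=0)
    span_s: float = Field(default=240.0, gt=0)
    framing_blocks: list[tuple[int, float]] = Field(
        default_factory=lambda: [list(b) for b in tac.PET_DYNAMIC_BLOCKS])
    fit: FitConfig = Field(default_factory=FitConfig)
    conditions: dict[str, ConditionConfig] = Field(default_factory=_default_conditions)

    @field_validator("modality")
    @classmethod
    def _modality(cls, v):
        if v not in ("PET", "CMR", "echo"):
            raise ValueError(f"unknown modality {v!r}")
        return v


def analyze_subject(curves: dict[str, tac.TimeCurve], dose: float, hr: float,
                    scheme: tac.FramingScheme | None, fit: FitConfig,
                    spans=(("RV", "LV"), ("SVC", "AAo"))) -> dict:
    """Rebin, isolate first passes and estimate CO/MTT/PBV for one acquisition."""
    if scheme is not None:
        curves = {r: tac.rebin(c, scheme, start=0.0) for r, c in curves.items()}
    fits = {}
    for region in set(r for pair in spans for r in pair):
        fits[region] = dilution.isolate_first_pass(
            curves[region], downslope_frac=fit.downslope_frac,
            auc_mode=fit.auc_mode, fit_method=fit.method)
    out: dict[str, dict] = {}
    for up, down in spans:
        co = dilution.stewart_hamilton_co(dose, fits[down])
        mtt = dilution.centroid_mtt(fits[up], fits[down])
        est = dilution.HemodynamicEstimate(co=co, mtt=mtt, hr=hr, span=f"{up}-{down}")
        out[f"{up}-{down}"] = {
            "co_ml_s": est.co, "mtt_s": est.mtt, "pbv_ml": est.pbv,
            "hr_bpm": est.hr, "ptt_beats": est.ptt_beats.beats,
            "ptt_beats_rounded": est.ptt_beats.rounded,
        }
    return out


def run_pipeline(config: StudyConfig) -> dict:
    """Run the full synthetic study and return a machine-readable summary."""
    rng = np.random.default_rng(config.seed)
    grid = synthetic.default_grid(config.grid_dt_s, config.span_s)
    scheme = tac.build_framing(config.framing_blocks)
    if scheme.span > config.span_s + 1e-9:
        raise PipelineError("framing: scheme span exceeds the simulated acquisition")

    results: dict = {"seed": config.seed, "modality": config.modality, "conditions": {}}
    pbv_matrix = np.empty((config.n_subjects, len(config.conditions)))
    subject_factors = 1.0 + config.subject_cv * rng.standard_normal(config.n_subjects)
    subject_factors = np.clip(subject_factors, 0.5, 1.5)
    mtt_factors = np.clip(1.0 + 0.5 * config.subject_cv * rng.standard_normal(config.n_subjects),
                          0.6, 1.4)

    for j, (cond, cc) in enumerate(config.conditions.items()):
        per_subject = []
        for i in range(config.n_subjects):
            seed_i = int(rng.integers(0, 2**31 - 1))
            scaled = ConditionConfig(
                co_ml_s=cc.co_ml_s * subject_factors[i], hr_bpm=cc.hr_bpm,
                mtt_svc_rv_s=cc.mtt_svc_rv_s * mtt_factors[i],
                mtt_rv_lv_s=cc.mtt_rv_lv_s * mtt_factors[i],
                mtt_lv_aao_s=cc.mtt_lv_aao_s * mtt_factors[i],
                delay_fraction=cc.delay_fraction)
            truth = synthetic.PhantomTruth(
                co_true=scaled.co_ml_s, dose=config.dose_mbq, hr=cc.hr_bpm,
                segments=scaled.segments(), recirc_fraction=config.recirc_fraction,
                recirc_delay=config.recirc_delay_s, noise_sigma=config.noise_sigma,
                seed=seed_i)
            try:
                curves = synthetic.simulate_transit(truth, grid)
            except Exception as exc:   # pragma: no cover - structured stage error
                raise PipelineError(f"simulate[{cond}/subj{i}]: {exc}") from exc
            try:
                est = analyze_subject(curves, config.dose_mbq, cc.hr_bpm, scheme, config.fit)
            except Exception as exc:
                raise PipelineError(f"firstpass[{cond}/subj{i}]: {exc}") from exc
            rvlv = est["RV-LV"]
            rvlv["truth"] = {"co_ml_s": truth.co_true,
                             "mtt_s": truth.mtt_true("RV", "LV"),
                             "pbv_ml": truth.pbv_true("RV", "LV")}
            per_subject.append(est)
            pbv_matrix[i, j] = rvlv["pbv_ml"]

        summary = {}
        for key in ("co_ml_s", "mtt_s", "pbv_ml"):
            vals = np.array([s["RV-LV"][key] for s in per_subject])
            summary[key] = {"mean": float(vals.mean()),
                            "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                            if len(vals) > 1 else 0.0}
        results["conditions"][cond] = {"summary": summary, "subjects": per_subject,
                                       "hr_bpm": cc.hr_bpm}

    if config.n_subjects >= 2 and len(config.conditions) >= 2:
        anova = rm_anova(pbv_matrix, conditions=list(config.conditions))
        results["pbv_anova"] = {
            "F": anova.F, "df_between": anova.df_between, "df_error": anova.df_error,
            "p": anova.p,
            "posthoc": [dataclasses.asdict(c) for c in anova.comparisons],
        }
    return results
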