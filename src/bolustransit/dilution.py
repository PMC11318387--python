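"""Indicator-dilution hemodynamics from first-pass bolus curves.

The first pass of the bolus is isolated from a region's time-activity curve
by down-slope fitting: a gamma-variate is fitted from bolus arrival to the
point where the down-slope first falls below a fraction (default 30%) of the
peak, and the fitted model extrapolates the declining limb past recirculating
tracer.  From the isolated first pass:

* forward cardiac output follows the Stewart-Hamilton principle,
  ``CO = dose / AUC(first pass)``;
* mean transit time between two regions is the difference of their
  first-pass centroids;
* the blood volume between the regions is ``CO x MTT``.

Two area/centroid conventions are provided.  The default,
``auc_mode="model"``, evaluates area and centroid in closed form on the
fitted, extrapolated model.  ``auc_mode="hybrid"`` instead integrates the
measured frames up to the down-slope cut-off and adds the analytic tail of
the fitted model beyond it, so the model only contributes where
extrapolation is unavoidable.  Because the fit itself uses the
frame-averaged (exactly frame-integrated) gamma-variate as its forward
model, both conventions are free of frame-binning bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq, curve_fit
from scipy.special import gammaincc, gammaln

from .synthetic import BolusModel
from .tac import TimeCurve

__all__ = [
    "NoBolusError",
    "FitError",
    "FirstPassResult",
    "HemodynamicEstimate",
    "BeatCount",
    "gamma_variate",
    "detect_arrival",
    "isolate_first_pass",
    "stewart_hamilton_co",
    "centroid_mtt",
    "pulmonary_blood_volume",
    "ptt_in_beats",
]


class NoBolusError(ValueError):
    """No detectable bolus peak above baseline."""


class FitError(RuntimeError):
    """Down-slope fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def gamma_variate(t, amplitude, alpha, beta, t0):
    """Gamma-variate ``A * u^alpha * exp(alpha - u)``, ``u = (t-t0)/beta``."""
    t = np.asarray(t, dtype=float)
    u = (t - t0) / beta
    out = np.zeros_like(u)
    pos = u > 0
    out[pos] = amplitude * np.exp(alpha * np.log(u[pos]) + alpha - u[pos])
    return out


@dataclass
class FirstPassResult:
    """Isolated first pass of a bolus through one region.

    ``auc`` (units*s) and ``centroid`` (s) are the quantities the
    hemodynamic estimators consume; ``model`` is the fitted gamma-variate
    (None for the mono-exponential tail method), ``t``/``first_pass`` sample
    the isolated curve on a fine analysis grid, and ``residual_rms`` is the
    root-mean-square misfit over the fit window.
    """

    model: BolusModel | None
    baseline: float
    fit_start: float
    fit_stop: float
    t: np.ndarray
    first_pass: np.ndarray
    auc: float
    centroid: float
    residual_rms: float
    region: str = ""
    mode: str = "model"


class BeatCount(NamedTuple):
    """Transit time expressed in heart beats, raw and rounded."""

    beats: float
    rounded: int


@dataclass
class HemodynamicEstimate:
    """CO/MTT/PBV bundle for one subject, condition and region span.

    ``pbv`` is a derived property (``co * mtt``), never stored, so the
    identity PBV = CO x MTT holds by construction.
    """

    co: float          # ml/s
    mtt: float         # s
    hr: float          # beats/min
    span: str = "RV-LV"
    condition: str = ""

    @property
    def pbv(self) -> float:
        return self.co * self.mtt

    @property
    def ptt_beats(self) -> BeatCount:
        return ptt_in_beats(self.mtt, self.hr)


# ---------------------------------------------------------------------------
# arrival detection and fitting
# ---------------------------------------------------------------------------

def detect_arrival(values: np.ndarray, nsd: float = 5.0,
                   floor_frac: float = 0.01) -> tuple[int, float, float]:
    """Locate bolus arrival in a sampled curve.

    Baseline is estimated from the leading pre-bolus samples; arrival is the
    first sample exceeding baseline + ``nsd`` baseline noise SDs (with a
    floor of ``floor_frac`` of the peak excursion for noise-free input),
    backtracked to the preceding local minimum.

    Returns ``(arrival_index, baseline, baseline_sd)``.
    """
    v = np.asarray(values, float)
    peak_i = int(np.argmax(v))
    vp = v[peak_i]
    if peak_i == 0:
        raise NoBolusError("curve peaks at the first sample; no arrival visible")
    pre = v[:peak_i]
    lo = pre.min()
    if vp <= lo:
        raise NoBolusError("flat curve: no bolus peak above baseline")
    # first estimate: leading run of samples near the pre-peak minimum
    quiet = pre < lo + 0.1 * (vp - lo)
    nonquiet = np.flatnonzero(~quiet)
    n_base = max(int(nonquiet[0]) if nonquiet.size else len(pre), 1)
    base = float(pre[:n_base].mean())
    sd = float(pre[:n_base].std(ddof=1)) if n_base > 1 else 0.0

    def crossing(b, s):
        thr = b + max(nsd * s, floor_frac * (vp - b))
        if vp <= thr:
            raise NoBolusError("no bolus peak above baseline + noise threshold")
        return int(np.flatnonzero(v > thr)[0])

    # refine: baseline = samples strictly before the threshold crossing,
    # excluding the sample adjacent to it (it may straddle bolus arrival)
    cross = crossing(base, sd)
    n_base = max(cross - 1, 0)
    if n_base >= 1:
        base = float(v[:n_base].mean())
        sd = float(v[:n_base].std(ddof=1)) if n_base > 1 else 0.0
    else:
        base, sd = 0.0, 0.0
    cross = crossing(base, sd)
    arrival = cross
    while arrival > 0 and v[arrival - 1] <= v[arrival]:
        arrival -= 1
    return arrival, base, sd


def _frame_mass(params, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Exact per-frame integral of a gamma-variate (incomplete-gamma form)."""
    amplitude, alpha, beta, t0 = params
    total = amplitude * beta * np.exp(alpha + gammaln(alpha + 1.0))
    ua = np.clip((starts - t0) / beta, 0.0, None)
    ub = np.clip((ends - t0) / beta, 0.0, None)
    return total * (gammaincc(alpha + 1.0, ua) - gammaincc(alpha + 1.0, ub))


def _frame_moment(params, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Exact per-frame first moment (integral of t * g) of a gamma-variate."""
    amplitude, alpha, beta, t0 = params
    total = amplitude * beta * np.exp(alpha + gammaln(alpha + 1.0))
    ua = np.clip((starts - t0) / beta, 0.0, None)
    ub = np.clip((ends - t0) / beta, 0.0, None)
    mass = total * (gammaincc(alpha + 1.0, ua) - gammaincc(alpha + 1.0, ub))
    shifted = beta * (alpha + 1.0) * total * (
        gammaincc(alpha + 2.0, ua) - gammaincc(alpha + 2.0, ub))
    return t0 * mass + shifted


def _loglinear_init(t: np.ndarray, y: np.ndarray, t0: float) -> tuple | None:
    """Moment-free initial estimate: linear regression of log(y)."""
    yp = y.max()
    mask = (t > t0 + 1e-9) & (y > 0.02 * yp)
    if mask.sum() < 4:
        return None
    dt_ = t[mask] - t0
    X = np.column_stack([np.ones(mask.sum()), np.log(dt_), -dt_])
    try:
        coef, *_ = np.linalg.lstsq(X, np.log(y[mask]), rcond=None)
    except np.linalg.LinAlgError:
        return None
    c0, alpha, inv_beta = coef
    if not (0.05 < alpha < 80) or inv_beta <= 0:
        return None
    beta = 1.0 / inv_beta
    amplitude = float(np.exp(c0 + alpha * np.log(beta) - alpha))
    return amplitude, float(alpha), float(beta), float(t0)


def _fit_gamma(starts: np.ndarray, ends: np.ndarray, y: np.ndarray
               ) -> tuple[BolusModel, float]:
    """Multi-start gamma-variate least squares over the fit window.

    The forward model is the frame-averaged gamma-variate (exact per-frame
    integral divided by frame duration), not the point value at the frame
    mid-time, so coarse frames introduce no binning bias.  Starts are
    log-linear solutions at a fixed ladder of onset candidates; the ladder is
    deterministic so the whole pipeline is too.
    """
    if len(y) < 5:
        raise FitError("too few samples between arrival and the down-slope "
                       "cut-off for a four-parameter fit",
                       {"n_points": len(y)})
    t = 0.5 * (starts + ends)
    dur = ends - starts
    peak_i = int(np.argmax(y))
    tp, yp = t[peak_i], y[peak_i]
    step = t[1] - t[0] if len(t) > 1 else 1.0
    lo_t0 = t[0] - 2.0 * step
    hi_t0 = 0.5 * (t[0] + tp)
    candidates = np.unique(np.linspace(lo_t0, hi_t0, 6))

    def frame_avg(_x, amplitude, alpha, beta, t0):
        return _frame_mass((amplitude, alpha, beta, t0), starts, ends) / dur

    bounds = ([0.0, 0.05, 1e-3, lo_t0 - 3.0 * step], [np.inf, 80.0, 1e4, tp - 1e-6])
    best: tuple[float, np.ndarray] | None = None
    tried = 0
    for t0c in candidates:
        p0 = _loglinear_init(t, y, t0c)
        if p0 is None:
            p0 = (yp * np.exp(-3.0 * np.log(3.0)), 3.0,
                  max((tp - t0c) / 3.0, 1e-2), t0c)
        p0 = np.clip(p0, [b + 1e-9 if np.isfinite(b) else 0 for b in bounds[0]],
                     [b - 1e-9 if np.isfinite(b) else np.inf for b in bounds[1]])
        tried += 1
        try:
            popt, _ = curve_fit(frame_avg, t, y, p0=p0, bounds=bounds, maxfev=4000)
        except (RuntimeError, ValueError):
            continue
        peak_time = popt[3] + popt[1] * popt[2]
        if not (t[0] - 2.0 * step <= peak_time <= t[-1] + step):
            continue  # implausible: fitted peak outside the bolus window
        sse = float(np.sum((frame_avg(t, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError("gamma-variate fit did not converge from any start",
                       {"n_points": len(y), "n_starts": tried, "peak": float(yp)})
    sse, popt = best
    model = BolusModel(amplitude=float(popt[0]), alpha=float(popt[1]),
                       beta=float(popt[2]), t0=float(max(popt[3], 0.0)))
    return model, float(np.sqrt(sse / len(y)))


def _model_extrap_end(model: BolusModel, frac: float) -> float:
    """Time at which the model decays below ``frac`` of its peak."""
    a = model.alpha

    def f(u):
        return a * (np.log(u) - np.log(a)) + (a - u) - np.log(frac)

    hi = a + 10.0
    while f(hi) > 0:
        hi *= 2.0
    u_end = brentq(f, a, hi)
    return model.t0 + model.beta * u_end


def isolate_first_pass(curve: TimeCurve, *, downslope_frac: float = 0.3,
                       extrap_frac: float = 1e-3, auc_mode: str = "model",
                       fit_method: str = "gamma", grid_dt: float = 0.25
                       ) -> FirstPassResult:
    """Isolate the first pass of a bolus curve by down-slope fitting.

    Parameters
    ----------
    curve
        Region time-activity/intensity curve (any framing).
    downslope_frac
        The fit window runs from arrival to the first post-peak sample below
        this fraction of the baseline-corrected peak.
    extrap_frac
        The reported first-pass curve is extrapolated until the fitted model
        falls below this fraction of its peak.
    auc_mode
        ``"model"`` (closed form on the fitted, extrapolated model, default)
        or ``"hybrid"`` (measured frames + analytic model tail).
    fit_method
        ``"gamma"`` (gamma-variate, default) or ``"exp_tail"``
        (mono-exponential down-slope extrapolation; implies hybrid area).
    """
    if auc_mode not in ("hybrid", "model"):
        raise ValueError(f"unknown auc_mode {auc_mode!r}")
    if fit_method not in ("gamma", "exp_tail"):
        raise ValueError(f"unknown fit_method {fit_method!r}")

    t = curve.mid
    v = curve.values
    arrival, base, _sd = detect_arrival(v)
    y = np.clip(v - base, 0.0, None)
    peak_i = int(np.argmax(y))
    ypk = y[peak_i]

    post = np.flatnonzero(y[peak_i + 1:] < downslope_frac * ypk)
    if post.size:
        stop = peak_i + 1 + int(post[0])
    else:
        stop = len(y) - 1
        warnings.warn("down-slope never fell below the cut-off within the "
                      "acquisition; first pass may include recirculation",
                      RuntimeWarning, stacklevel=2)
    tw, yw = t[arrival:stop + 1], y[arrival:stop + 1]

    if fit_method == "gamma":
        model, rms = _fit_gamma(curve.t_start[arrival:stop + 1],
                                curve.t_end[arrival:stop + 1], yw)
        cut = float(curve.t_start[stop])  # frame boundary before the cut-off frame

        if auc_mode == "model":
            auc, centroid = model.auc, model.centroid
        else:
            obs = slice(arrival, stop)
            starts, ends = curve.t_start[obs], curve.t_end[obs]
            dur = curve.duration[obs]
            auc_obs = float(np.sum(y[obs] * dur))
            # measured frame masses, placed at the fitted model's
            # within-frame mass centre (falls back to the frame mid-time
            # where the model carries no mass)
            params = (model.amplitude, model.alpha, model.beta, model.t0)
            m_mass = _frame_mass(params, starts, ends)
            m_mom = _frame_moment(params, starts, ends)
            tbar = np.where(m_mass > 1e-12 * max(m_mass.max(), 1e-300),
                            m_mom / np.maximum(m_mass, 1e-300), t[obs])
            mom_obs = float(np.sum(y[obs] * dur * tbar))
            u_c = max((cut - model.t0) / model.beta, 0.0)
            a = model.alpha
            tail_auc = model.auc * float(gammaincc(a + 1.0, u_c))
            tail_mom = (model.t0 * tail_auc
                        + model.beta * (a + 1.0) * model.auc * float(gammaincc(a + 2.0, u_c)))
            auc = auc_obs + tail_auc
            centroid = (mom_obs + tail_mom) / auc

        t_end = max(_model_extrap_end(model, extrap_frac), cut + grid_dt)
        tg = np.arange(max(model.t0, t[0] if arrival == 0 else t[arrival - 1]),
                       t_end + grid_dt, grid_dt)
        fp = gamma_variate(tg, model.amplitude, model.alpha, model.beta, model.t0)
        if auc_mode == "hybrid":
            pre = tg <= cut
            fp[pre] = np.interp(tg[pre], t, y)
        return FirstPassResult(model=model, baseline=base, fit_start=float(tw[0]),
                               fit_stop=float(tw[-1]), t=tg, first_pass=fp,
                               auc=float(auc), centroid=float(centroid),
                               residual_rms=rms, region=curve.region, mode=auc_mode)

    # mono-exponential tail: fit the log-linear decline strictly after the
    # peak (the curve is not yet exponential at the peak itself)
    first = peak_i + 1 if stop - peak_i >= 2 else peak_i
    dsl = slice(first, stop + 1)
    tm, ym = t[dsl], y[dsl]
    ok = ym > 0
    if ok.sum() < 2:
        raise FitError("too few positive down-slope samples for exp tail",
                       {"n_points": int(ok.sum())})
    coef = np.polyfit(tm[ok], np.log(ym[ok]), 1)
    slope, intercept = coef[0], coef[1]
    if slope >= 0:
        raise FitError("down-slope is not declining; cannot extrapolate",
                       {"slope": float(slope)})
    tau = -1.0 / slope
    cut = float(curve.t_start[stop])
    v_cut = float(np.exp(intercept + slope * cut))
    obs = slice(arrival, stop)
    dur = curve.duration[obs]
    auc = float(np.sum(y[obs] * dur)) + v_cut * tau
    mom = float(np.sum(y[obs] * dur * t[obs])) + v_cut * tau * (cut + tau)
    rms = float(np.sqrt(np.mean((np.exp(intercept + slope * tm[ok]) - ym[ok]) ** 2)))
    t_end = cut + tau * np.log(max(v_cut, 1e-300) / (extrap_frac * ypk)) if v_cut > 0 else cut
    tg = np.arange(t[arrival], max(t_end, cut + grid_dt) + grid_dt, grid_dt)
    fp = np.where(tg <= cut, np.interp(tg, t, y), np.exp(intercept + slope * tg))
    return FirstPassResult(model=None, baseline=base, fit_start=float(tm[0]),
                           fit_stop=float(tm[-1]), t=tg, first_pass=fp,
                           auc=auc, centroid=float(mom / auc), residual_rms=rms,
                           region=curve.region, mode="exp_tail")


# ---------------------------------------------------------------------------
# hemodynamic estimators
# ---------------------------------------------------------------------------

def stewart_hamilton_co(dose: float, first_pass: FirstPassResult) -> float:
    """Forward cardiac output: injected dose / first-pass area (ml/s).

    With dose in MBq and the curve in MBq/ml, the ratio has units ml/s.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    if first_pass.auc <= 0:
        raise ValueError("first-pass AUC must be positive")
    return dose / first_pass.auc


def centroid_mtt(upstream: FirstPassResult, downstream: FirstPassResult) -> float:
    """Mean transit time: centroid(downstream) - centroid(upstream), seconds.

    A negative result is reported as-is with a warning, never clipped.
    """
    mtt = downstream.centroid - upstream.centroid
    if mtt < 0:
        warnings.warn(
            f"negative transit time ({mtt:.3g} s) between "
            f"{upstream.region or 'upstream'} and {downstream.region or 'downstream'}",
            RuntimeWarning, stacklevel=2)
    return mtt


def pulmonary_blood_volume(co: float, mtt: float) -> float:
    """Blood volume between two regions: CO (ml/s) x MTT (s), in ml."""
    if co < 0 or mtt < 0:
        raise ValueError("co and mtt must be nonnegative")
    return co * mtt


def ptt_in_beats(ptt: float, hr: float) -> BeatCount:
    """Transit time in heart beats: ``ptt * hr / 60``.

    Returns both the unrounded value and the nearest integer
    (round-half-to-even).
    """
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    beats = ptt * hr / 60.0
    return BeatCount(beats=beats, rounded=int(round(beats)))
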