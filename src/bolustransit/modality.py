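"""Transit-time and chamber-volume hemodynamics for CMR and contrast echo.

CMR first-pass perfusion gives one intensity sample per heartbeat in the
right-ventricular outflow tract and the left ventricle; pulmonary transit
time (PTT) is read as the difference between the two curves' peaks, or --
when the peak is poorly delineated -- between their half-maximum up-slope
crossings ("midpoints").  Contrast echo measures PTT as the difference in
contrast arrival time between the ventricles.  Chamber volumes give stroke
volume (EDV - ESV) and cardiac output (SV x HR), and pulmonary blood volume
is cardiac output times PTT, with the CO source chamber recorded (RV for
CMR, LV for echo).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tac import TimeCurve

__all__ = [
    "FlatCurveError",
    "ChamberVolumes",
    "IntensityCurve",
    "PbvEstimate",
    "stroke_volume",
    "cardiac_output",
    "ptt_peak_to_peak",
    "ptt_midpoint",
    "echo_ptt",
    "modality_pbv",
]


class FlatCurveError(ValueError):
    """Curve has no usable bolus signal (flat, or no opacification)."""


@dataclass(frozen=True)
class ChamberVolumes:
    """End-diastolic/end-systolic volume (ml) and heart rate (beats/min)."""

    edv: float
    esv: float
    hr: float

    def __post_init__(self) -> None:
        if self.esv < 0:
            raise ValueError("end-systolic volume must be nonnegative")
        if self.edv < self.esv:
            raise ValueError(f"EDV ({self.edv}) < ESV ({self.esv})")


@dataclass
class IntensityCurve:
    """Time-stamped signal-intensity samples for one region.

    ``t`` is per-beat (CMR) or continuous (echo) and must be increasing.
    """

    t: np.ndarray
    values: np.ndarray
    region: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.values = np.asarray(self.values, float)
        if self.t.ndim != 1 or self.t.shape != self.values.shape:
            raise ValueError("t and values must be 1-D arrays of equal length")
        if len(self.t) < 2:
            raise ValueError("need at least two samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensities must be finite")

    @classmethod
    def from_timecurve(cls, curve: TimeCurve) -> "IntensityCurve":
        return cls(curve.mid, curve.values, region=curve.region)

    @classmethod
    def beat_sampled(cls, curve: TimeCurve, hr: float, start: float | None = None
                     ) -> "IntensityCurve":
        """Sample a fine curve once per heartbeat (CMR temporal resolution)."""
        if hr <= 0:
            raise ValueError("heart rate must be positive")
        beat = 60.0 / hr
        m = curve.mid
        t0 = m[0] if start is None else start
        t = np.arange(t0, m[-1], beat)
        return cls(t, np.interp(t, m, curve.values), region=curve.region)


@dataclass(frozen=True)
class PbvEstimate:
    """Pulmonary blood volume with the cardiac-output source recorded."""

    pbv: float
    co: float
    ptt: float
    co_source: str


def stroke_volume(v: ChamberVolumes) -> float:
    """Stroke volume = EDV - ESV, ml."""
    return v.edv - v.esv


def cardiac_output(sv: float, hr: float) -> float:
    """Cardiac output = SV x HR, returned in ml/s."""
    if hr <= 0:
        raise ValueError("heart rate must be positive")
    if sv < 0:
        raise ValueError("stroke volume must be nonnegative")
    return sv * hr / 60.0


def _peak(curve: IntensityCurve) -> tuple[int, float, float]:
    """Index, time and value of the global maximum; ties take the earliest."""
    v = curve.values
    if np.ptp(v) == 0:
        raise FlatCurveError(f"flat curve in {curve.region or 'region'}")
    vmax = v.max()
    ties = np.flatnonzero(v == vmax)
    if ties.size > 1:
        warnings.warn(f"{ties.size} tied maxima in {curve.region or 'curve'}; "
                      "using the earliest", RuntimeWarning, stacklevel=3)
    i = int(ties[0])
    return i, float(curve.t[i]), float(vmax)


def _upslope_crossing(curve: IntensityCurve, level: float, peak_i: int) -> float:
    """First up-slope crossing of ``level`` before the peak, linearly interpolated."""
    t, v = curve.t, curve.values
    above = np.flatnonzero(v[:peak_i + 1] >= level)
    if above.size == 0:
        raise FlatCurveError(f"curve never reaches the threshold in {curve.region or 'region'}")
    i = int(above[0])
    if i == 0 or v[i] == v[i - 1]:
        return float(t[i])
    frac = (level - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def ptt_peak_to_peak(rv: IntensityCurve, lv: IntensityCurve) -> float:
    """PTT as the time difference between the LV and RV intensity peaks (s)."""
    _, t_rv, _ = _peak(rv)
    _, t_lv, _ = _peak(lv)
    return t_lv - t_rv


def _midpoint_time(curve: IntensityCurve, definition: str) -> float:
    peak_i, t_pk, v_pk = _peak(curve)
    base = float(curve.values[:peak_i + 1].min())
    half = base + 0.5 * (v_pk - base)
    up = _upslope_crossing(curve, half, peak_i)
    if definition == "half_max":
        return up
    if definition == "temporal_midpoint":
        # midpoint in time between the half-max up- and down-crossings
        t, v = curve.t, curve.values
        below = np.flatnonzero(v[peak_i:] <= half)
        if below.size == 0:
            warnings.warn("no half-max down-crossing; using last sample",
                          RuntimeWarning, stacklevel=3)
            down = float(t[-1])
        else:
            j = peak_i + int(below[0])
            frac = (half - v[j - 1]) / (v[j] - v[j - 1])
            down = float(t[j - 1] + frac * (t[j] - t[j - 1]))
        return 0.5 * (up + down)
    raise ValueError(f"unknown midpoint definition {definition!r}")


def ptt_midpoint(rv: IntensityCurve, lv: IntensityCurve,
                 definition: str = "half_max") -> float:
    """PTT as the difference between curve midpoints (s).

    ``definition="half_max"`` (default) uses the half-maximum crossing on the
    up-slope; ``"temporal_midpoint"`` uses the time midway between the
    half-maximum up- and down-crossings.
    """
    return _midpoint_time(lv, definition) - _midpoint_time(rv, definition)


def arrival_time(curve: IntensityCurve, k: float = 0.1) -> float:
    """Contrast arrival: first up-slope crossing of baseline + k*(peak-baseline)."""
    if not 0 < k < 1:
        raise ValueError("threshold fraction k must be in (0, 1)")
    peak_i, _, v_pk = _peak(curve)
    base = float(curve.values[:peak_i + 1].min())
    return _upslope_crossing(curve, base + k * (v_pk - base), peak_i)


def echo_ptt(rv: IntensityCurve, lv: IntensityCurve, k: float = 0.1) -> float:
    """PTT as the contrast arrival-time difference LV - RV (s).

    Raises :class:`FlatCurveError` when a chamber never opacifies.
    """
    return arrival_time(lv, k) - arrival_time(rv, k)


def modality_pbv(co: float, ptt: float, co_source: str = "RV") -> PbvEstimate:
    """Pulmonary blood volume CO x PTT with the CO source chamber recorded.

    CMR uses right-ventricular CO; echo uses left-ventricular CO.
    """
    if co < 0 or ptt < 0:
        raise ValueError("co and ptt must be nonnegative")
    return PbvEstimate(pbv=co * ptt, co=co, ptt=ptt, co_source=co_source)
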