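"""Dynamic-frame time-curve handling.

Framing schemes, frame rebinning, ROI curve extraction and resampling for
tracer time-activity curves and contrast time-intensity curves.

Frames are half-open intervals ``[t_start, t_end)``.  A frame's value is the
duration-weighted mean of the underlying signal over the frame; when a point
sample is needed (interpolation, model fitting) the value is attributed to
the frame mid-time, the usual dynamic-PET convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CurveError",
    "TimeCurve",
    "FramingScheme",
    "PET_DYNAMIC_BLOCKS",
    "build_framing",
    "rebin",
    "extract_roi",
    "resample_uniform",
    "decay_correct",
    "O15_HALF_LIFE_S",
]

#: physical half-life of oxygen-15, seconds
O15_HALF_LIFE_S = 122.24

#: framing blocks of the 4-minute dynamic cardiac water-PET protocol:
#: (count, duration_s) pairs
PET_DYNAMIC_BLOCKS: tuple[tuple[int, float], ...] = (
    (1, 10.0),
    (8, 5.0),
    (4, 10.0),
    (2, 15.0),
    (3, 20.0),
    (2, 30.0),
)


class CurveError(ValueError):
    """Structurally invalid curve, scheme, or incompatible grids."""


@dataclass
class TimeCurve:
    """A region-labelled curve on a frame grid.

    Parameters
    ----------
    t_start, t_end
        Frame start/end times in seconds; frames must be sorted and
        non-overlapping.
    values
        One value per frame (activity concentration or signal intensity).
    region
        Region label, e.g. ``"SVC"``, ``"RV"``, ``"LV"``, ``"AAo"``.
    units
        Free-form units tag, carried through all operations unchanged.
    """

    t_start: np.ndarray
    t_end: np.ndarray
    values: np.ndarray
    region: str = ""
    units: str = "arb"

    def __post_init__(self) -> None:
        self.t_start = np.atleast_1d(np.asarray(self.t_start, dtype=float))
        self.t_end = np.atleast_1d(np.asarray(self.t_end, dtype=float))
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if not (self.t_start.ndim == self.t_end.ndim == self.values.ndim == 1):
            raise CurveError("curve fields must be one-dimensional")
        if not (len(self.t_start) == len(self.t_end) == len(self.values)):
            raise CurveError("t_start, t_end and values must have equal length")
        if len(self.t_start) == 0:
            raise CurveError("empty curve")
        if not np.all(self.t_end > self.t_start):
            raise CurveError("every frame needs t_end > t_start")
        if not np.all(self.t_start[1:] >= self.t_end[:-1] - 1e-9):
            raise CurveError("frames must be sorted and non-overlapping")
        if not np.all(np.isfinite(self.values)):
            raise CurveError("curve values must be finite")

    # -- basic geometry ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> np.ndarray:
        return self.t_end - self.t_start

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.t_start + self.t_end)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t_start[0]), float(self.t_end[-1])

    # -- summary quantities ------------------------------------------------

    def integral(self) -> float:
        """Time integral sum(value * duration) over all frames."""
        return float(np.sum(self.values * self.duration))

    def centroid(self) -> float:
        """First moment int(t*C)/int(C) with frame values at mid-times."""
        area = self.integral()
        if area <= 0:
            raise CurveError("centroid undefined for non-positive total area")
        return float(np.sum(self.values * self.duration * self.mid) / area)

    def with_values(self, values: np.ndarray, **kw) -> "TimeCurve":
        return dataclasses.replace(self, values=np.asarray(values, float), **kw)

    @classmethod
    def from_samples(
        cls, t: np.ndarray, values: np.ndarray, region: str = "", units: str = "arb"
    ) -> "TimeCurve":
        """Wrap point samples as thin frames centred on the sample times."""
        t = np.asarray(t, float)
        if t.ndim != 1 or len(t) < 2:
            raise CurveError("need at least two samples")
        if not np.all(np.diff(t) > 0):
            raise CurveError("sample times must be strictly increasing")
        inner = 0.5 * (t[:-1] + t[1:])
        starts = np.concatenate([[t[0] - (inner[0] - t[0])], inner])
        ends = np.concatenate([inner, [t[-1] + (t[-1] - inner[-1])]])
        return cls(starts, ends, values, region=region, units=units)


@dataclass(frozen=True)
class FramingScheme:
    """An ordered list of (count, duration) frame blocks."""

    blocks: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise CurveError("framing scheme needs at least one block")
        for count, dur in self.blocks:
            if int(count) != count or count < 1:
                raise CurveError(f"frame count must be a positive integer, got {count}")
            if dur <= 0:
                raise CurveError(f"frame duration must be positive, got {dur}")

    @property
    def n_frames(self) -> int:
        return int(sum(c for c, _ in self.blocks))

    @property
    def span(self) -> float:
        return float(sum(c * d for c, d in self.blocks))

    @property
    def durations(self) -> np.ndarray:
        return np.concatenate([np.full(int(c), float(d)) for c, d in self.blocks])

    def edges(self, start: float = 0.0) -> np.ndarray:
        """Explicit frame edges, length ``n_frames + 1``."""
        return start + np.concatenate([[0.0], np.cumsum(self.durations)])


def build_framing(blocks: Iterable[Sequence[float]]) -> FramingScheme:
    """Build a validated framing scheme from (count, duration) pairs."""
    return FramingScheme(tuple((int(c), float(d)) for c, d in blocks))


def rebin(curve: TimeCurve, scheme: FramingScheme, start: float | None = None) -> TimeCurve:
    """Rebin a finely sampled curve onto a framing scheme.

    Each output frame value is the duration-weighted mean of the input
    frames overlapping it, so the time integral is conserved wherever the
    input tiles the output frames completely.
    """
    if start is None:
        start = float(curve.t_start[0])
    edges = scheme.edges(start)
    if edges[0] < curve.t_start[0] - 1e-9 or edges[-1] > curve.t_end[-1] + 1e-9:
        raise CurveError(
            f"scheme span [{edges[0]:g}, {edges[-1]:g}] s extends past curve "
            f"coverage [{curve.t_start[0]:g}, {curve.t_end[-1]:g}] s"
        )
    starts, ends = edges[:-1], edges[1:]
    out = np.empty(scheme.n_frames)
    for j in range(scheme.n_frames):
        overlap = np.minimum(ends[j], curve.t_end) - np.maximum(starts[j], curve.t_start)
        np.clip(overlap, 0.0, None, out=overlap)
        total = overlap.sum()
        if total <= 0:
            raise CurveError(f"no input samples cover frame [{starts[j]:g}, {ends[j]:g}) s")
        out[j] = float(np.dot(curve.values, overlap) / total)
    return TimeCurve(starts, ends, out, region=curve.region, units=curve.units)


def extract_roi(phantom, region: str) -> TimeCurve:
    """Mean curve over the voxels labelled ``region`` in a 4-D phantom."""
    try:
        code = phantom.region_codes[region]
    except KeyError:
        raise CurveError(f"region {region!r} not in label map") from None
    mask = phantom.labels == code
    if not mask.any():
        raise CurveError(f"region {region!r} labels no voxels")
    vals = phantom.values[:, mask].mean(axis=1)
    return TimeCurve(phantom.t_start, phantom.t_end, vals, region=region, units=phantom.units)


def resample_uniform(curve: TimeCurve, dt: float) -> TimeCurve:
    """Resample to a uniform grid by linear interpolation at frame mid-times.

    Endpoints are held (constant extrapolation within the first/last frame).
    """
    if dt <= 0:
        raise CurveError("dt must be positive")
    if curve.n < 2:
        raise CurveError("cannot resample a single-frame curve")
    m = curve.mid
    t = m[0] + dt * np.arange(int(np.floor((m[-1] - m[0]) / dt)) + 1)
    v = np.interp(t, m, curve.values)
    return TimeCurve.from_samples(t, v, region=curve.region, units=curve.units)


def decay_correct(curve: TimeCurve, half_life: float = O15_HALF_LIFE_S) -> TimeCurve:
    """Correct frame values for physical decay back to t = 0.

    Off by default throughout the pipeline: input curves are assumed
    decay-corrected already, as delivered by clinical reconstructions.
    """
    if half_life <= 0:
        raise CurveError("half-life must be positive")
    lam = np.log(2.0) / half_life
    # exact frame-average correction factor rather than mid-time exponential
    s, e = curve.t_start, curve.t_end
    factor = lam * (e - s) / (np.exp(-lam * s) - np.exp(-lam * e))
    return curve.with_values(curve.values * factor)
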