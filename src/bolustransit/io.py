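"""Delimited-text curve format and JSON sidecars.

Curves travel as UTF-8 comma-separated text with a header row and '.' decimal
separator, one row per frame::

    t_start,t_end,region,value,units

Ground truth and framing schemes are carried in JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .synthetic import BolusModel, PhantomTruth, TransportSegment
from .tac import CurveError, FramingScheme, TimeCurve, build_framing

__all__ = [
    "write_curves",
    "read_curves",
    "write_truth",
    "read_truth",
    "write_scheme",
    "read_scheme",
]

_COLUMNS = ["t_start", "t_end", "region", "value", "units"]


def write_curves(curves: Mapping[str, TimeCurve], path) -> None:
    """Write one or more region curves to a single delimited-text file."""
    frames = []
    for region, c in curves.items():
        frames.append(pd.DataFrame({
            "t_start": c.t_start, "t_end": c.t_end,
            "region": region or c.region, "value": c.values, "units": c.units,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, columns=_COLUMNS)


def read_curves(path) -> dict[str, TimeCurve]:
    """Read region curves from the delimited-text format."""
    df = pd.read_csv(path)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise CurveError(f"curve file {path} lacks columns {sorted(missing)}")
    out: dict[str, TimeCurve] = {}
    for region, grp in df.groupby("region", sort=False):
        grp = grp.sort_values("t_start")
        units = grp["units"].iloc[0]
        out[str(region)] = TimeCurve(grp["t_start"].to_numpy(),
                                     grp["t_end"].to_numpy(),
                                     grp["value"].to_numpy(),
                                     region=str(region), units=str(units))
    return out


def write_truth(truth: PhantomTruth, path) -> None:
    """JSON sidecar with the full generator ground truth."""
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=2))


def read_truth(path) -> PhantomTruth:
    d = json.loads(Path(path).read_text())
    d["bolus"] = BolusModel(**d["bolus"])
    d["segments"] = tuple(TransportSegment(**s) for s in d["segments"])
    return PhantomTruth(**d)


def write_scheme(scheme: FramingScheme, path) -> None:
    Path(path).write_text(json.dumps({"blocks": [list(b) for b in scheme.blocks]}, indent=2))


def read_scheme(path) -> FramingScheme:
    d = json.loads(Path(path).read_text())
    return build_framing(d["blocks"])
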