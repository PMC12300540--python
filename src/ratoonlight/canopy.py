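"""Canopy light interception, intercepted PAR, and radiation use efficiency.

Light-bar readings taken at four stages (mid-tillering MT, panicle
initiation PI, heading HD, maturity MA) are converted to an interception
percentage IP; stage-wise intercepted photosynthetically active
radiation (IPAR) is the trapezoid of the two bounding IPs times the PAR
fraction of cumulative solar radiation over the stage; season IPAR sums
the four stage values; radiation use efficiency RUE is above-ground
total dry weight per unit season IPAR (g MJ⁻¹).
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, InvalidReadingError, PhenologyError, SchemaError
from .thermal import GrowthWindow, _window_slice

#: PAR as a fraction of global solar radiation.
PAR_FRACTION = 0.45

#: Measurement stages, in phenological order.
STAGES = ("MT", "PI", "HD", "MA")

#: Number of below-canopy readings per observation (3 between-row + 3 within-row).
N_BELOW_READINGS = 6


def interception_pct(incoming: float, below: Sequence[float]) -> float:
    """Canopy light interception percentage from one light-bar observation.

    ``100 · (incoming − mean(below)) / incoming`` where ``below`` holds
    the six below-canopy intensities (three between rows, three within
    rows), averaged with equal weight.  Values outside [0, 100] (sensor
    noise can make below-canopy exceed incoming) are clamped with a
    warning.
    """
    if incoming <= 0:
        raise InvalidReadingError(f"incoming light intensity must be > 0, got {incoming}")
    below = np.asarray(below, dtype=float)
    if below.size != N_BELOW_READINGS:
        raise SchemaError(
            f"expected {N_BELOW_READINGS} below-canopy readings, got {below.size}"
        )
    if (below < 0).any():
        raise InvalidReadingError("below-canopy readings must be >= 0")
    ip = 100.0 * (incoming - float(below.mean())) / incoming
    if ip < 0.0 or ip > 100.0:
        warnings.warn(
            f"interception {ip:.2f}% outside [0, 100]; clamped", stacklevel=2
        )
        ip = min(max(ip, 0.0), 100.0)
    return ip


def stage_ipar(
    ip_start: float,
    ip_end: float,
    sr_stage: float,
    par_fraction: float = PAR_FRACTION,
) -> float:
    """Intercepted PAR over one development stage, MJ m⁻².

    Trapezoidal rule on interception: the mean of the stage's bounding
    interception percentages, times the PAR fraction of the cumulative
    solar radiation received during the stage.
    """
    for name, ip in (("ip_start", ip_start), ("ip_end", ip_end)):
        if not 0.0 <= ip <= 100.0:
            raise InvalidParameterError(f"{name} must be in [0, 100], got {ip}")
    if sr_stage < 0:
        raise InvalidParameterError(f"stage solar radiation must be >= 0, got {sr_stage}")
    return 0.5 * (ip_start + ip_end) / 100.0 * par_fraction * sr_stage


def season_ipar(
    stage_ip: Mapping[str, float],
    stage_dates: Mapping[str, dt.date],
    weather: pd.DataFrame,
    window: GrowthWindow,
    initial_ip: float = 0.0,
    par_fraction: float = PAR_FRACTION,
) -> float:
    """Season-total intercepted PAR by stage-wise trapezoidal integration.

    The window is partitioned into [start, MT), [MT, PI), [PI, HD),
    [HD, MA] (half-open day assignment; the final day belongs to the
    last interval) so each day's radiation is counted exactly once.
    Interception at the window start is ``initial_ip`` — 0 for a main
    season transplanted into bare paddy, configurable for the ratoon
    season where stubble may intercept light at regrowth.

    Inputs beyond MA are refused rather than extrapolated: MA must equal
    the window end.
    """
    missing = [s for s in STAGES if s not in stage_ip or s not in stage_dates]
    if missing:
        raise SchemaError(f"incomplete stage profile; missing stages: {missing}")
    dates = [stage_dates[s] for s in STAGES]
    bounds = [window.start, *dates]
    if any(b2 < b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise PhenologyError(
            f"stage dates out of order for window {window.label!r}: "
            f"start={window.start}, " + ", ".join(f"{s}={stage_dates[s]}" for s in STAGES)
        )
    if dates[-1] != window.end:
        raise PhenologyError(
            f"MA date {dates[-1]} must equal window end {window.end} "
            f"(window {window.label!r}); refusing to extrapolate interception"
        )

    sub = _window_slice(weather, window)
    day = pd.DatetimeIndex(sub["date"])
    srad = sub["srad"].to_numpy(dtype=float)

    ips = [float(initial_ip)] + [float(stage_ip[s]) for s in STAGES]
    total = 0.0
    for i in range(4):
        lo, hi = pd.Timestamp(bounds[i]), pd.Timestamp(bounds[i + 1])
        if i < 3:
            mask = (day >= lo) & (day < hi)
        else:  # last interval keeps its right endpoint
            mask = (day >= lo) & (day <= hi)
        sr_stage = float(srad[mask].sum())
        total += stage_ipar(ips[i], ips[i + 1], sr_stage, par_fraction)
    return total


def rue(tdw: float, ipar: float) -> float:
    """Radiation use efficiency: above-ground dry weight per unit IPAR.

    Returns NaN (flagged, with a warning) when IPAR is non-positive.
    """
    if tdw < 0:
        raise InvalidParameterError(f"total dry weight must be >= 0, got {tdw}")
    if ipar <= 0:
        warnings.warn(f"RUE undefined for IPAR = {ipar}; returning NaN", stacklevel=2)
        return math.nan
    return tdw / ipar


def annual_totals(ms: Mapping[str, float], rs: Mapping[str, float]) -> dict[str, float]:
    """Combine main- and ratoon-season records into the annual (TS) record.

    TDW and IPAR add; annual RUE is the ratio of the sums (total dry
    weight over total IPAR), not the mean of the two season RUEs.
    ``ms`` and ``rs`` need keys ``tdw`` and ``ipar``.
    """
    for name, rec in (("ms", ms), ("rs", rs)):
        for key in ("tdw", "ipar"):
            if key not in rec:
                raise SchemaError(f"{name} record missing {key!r}")
    tdw = float(ms["tdw"]) + float(rs["tdw"])
    ipar = float(ms["ipar"]) + float(rs["ipar"])
    return {"tdw": tdw, "ipar": ipar, "rue": rue(tdw, ipar) if ipar > 0 else math.nan}
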