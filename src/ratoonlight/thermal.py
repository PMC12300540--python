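"""Thermal-time and radiation accumulation over crop growth windows.

Implements the agroclimatic indices used to compare ratoon-rice seasons:

* **EAT** — effective accumulated temperature, the thermal time above a
  base temperature ``t0`` (10 °C for rice) summed over a growth window,
  in °C d: ``EAT = Σ (Tmean − t0)`` over days with ``Tmean ≥ t0``.
* **Total accumulated temperature** — ``Σ Tmean`` over the same
  effective days.
* **TUE** — effective-accumulated-temperature use efficiency,
  ``100 · EAT / total``, in percent.
* **SR** — cumulative solar radiation over the window, MJ m⁻².
* **PQ** — photothermal quotient, solar radiation per unit effective
  thermal time, MJ m⁻² d⁻¹ °C⁻¹.  At the season level this is the ratio
  of totals, equivalently mean daily radiation over mean (Tmean − t0).

Daily mean temperature is the midrange (Tmax + Tmin)/2.  Windows are
inclusive on both ends at daily resolution.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, MissingWeatherError

#: Base temperature for rice thermal-time accumulation, °C.
BASE_TEMP = 10.0

WEATHER_COLUMNS = ("date", "tmax", "tmin", "srad")


@dataclasses.dataclass(frozen=True)
class GrowthWindow:
    """A dated, inclusive season segment over which indices accumulate.

    ``label`` conventionally is "MS" (main season), "RS" (ratoon season)
    or "TS" (the annual total, the union of contiguous MS and RS).
    """

    label: str
    start: dt.date
    end: dt.date

    def __post_init__(self):
        if self.start > self.end:
            raise InvalidParameterError(
                f"window {self.label!r}: start {self.start} is after end {self.end}"
            )

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


@dataclasses.dataclass(frozen=True)
class ThermalSummary:
    """Accumulated thermal and radiative indices for one growth window.

    ``tue`` and ``pq`` are NaN (flagged undefined, not an exception) when
    the window has no effective days, so batch runs survive degenerate
    plots.  ``sr_sum`` counts every window day; ``sr_sum_effective`` only
    days with Tmean ≥ t0 and is the PQ numerator.
    """

    eat: float
    total_at: float
    sr_sum: float
    sr_sum_effective: float
    tue: float
    pq: float
    n_days: int
    n_effective_days: int

    @property
    def pq_defined(self) -> bool:
        return not math.isnan(self.pq)

    @property
    def tue_defined(self) -> bool:
        return not math.isnan(self.tue)


def daily_mean_temp(tmax, tmin):
    """Daily average temperature as the midrange (tmax + tmin)/2.

    Accepts scalars or array-likes and broadcasts.
    """
    return (np.asarray(tmax, dtype=float) + np.asarray(tmin, dtype=float)) / 2.0


def _window_slice(series: pd.DataFrame, window: GrowthWindow) -> pd.DataFrame:
    dates = pd.to_datetime(series["date"])
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0].date()
        raise InvalidParameterError(f"duplicate weather record for {dup}")
    mask = (dates >= pd.Timestamp(window.start)) & (dates <= pd.Timestamp(window.end))
    sub = series.loc[mask].copy()
    sub["date"] = dates[mask]
    expected = window.dates()
    present = pd.DatetimeIndex(sub["date"])
    missing = expected.difference(present)
    if len(missing):
        raise MissingWeatherError(missing[0].date(), window.label)
    return sub.sort_values("date")


def accumulate(
    series: pd.DataFrame, window: GrowthWindow, t0: float = BASE_TEMP
) -> ThermalSummary:
    """Accumulate EAT, total temperature, SR, TUE and PQ over ``window``.

    Parameters
    ----------
    series
        Daily weather with columns ``date, tmax, tmin, srad`` (srad in
        MJ m⁻² d⁻¹).  Must cover every day of the window; a gap raises
        :class:`~ratoonlight.errors.MissingWeatherError` naming the first
        missing date.
    window
        Inclusive growth window.
    t0
        Base temperature, °C (default 10, the rice convention).
    """
    sub = _window_slice(series, window)
    tmean = daily_mean_temp(sub["tmax"].to_numpy(), sub["tmin"].to_numpy())
    srad = sub["srad"].to_numpy(dtype=float)
    effective = tmean >= t0

    eat = float(np.sum(tmean[effective] - t0))
    total_at = float(np.sum(tmean[effective]))
    sr_sum = float(np.sum(srad))
    sr_eff = float(np.sum(srad[effective]))

    tue = 100.0 * eat / total_at if total_at > 0 else math.nan
    pq = sr_eff / eat if eat > 0 else math.nan

    return ThermalSummary(
        eat=eat,
        total_at=total_at,
        sr_sum=sr_sum,
        sr_sum_effective=sr_eff,
        tue=tue,
        pq=pq,
        n_days=len(sub),
        n_effective_days=int(effective.sum()),
    )


def pq_from_totals(sr_sum: float, eat: float) -> float:
    """Photothermal quotient from season totals: ``sr_sum / eat``.

    Identical to mean daily solar radiation over mean daily (Tmean − t0)
    when every day of the window is effective.
    """
    if eat <= 0:
        raise InvalidParameterError(
            f"PQ undefined: effective accumulated temperature must be > 0, got {eat}"
        )
    return sr_sum / eat


def window_partition_check(
    ms: ThermalSummary,
    rs: ThermalSummary,
    ts: ThermalSummary,
    tol: float = 1e-6,
) -> bool:
    """True iff the annual summary is the exact sum of the two seasons.

    Checks EAT, total accumulated temperature and cumulative SR to
    within ``tol``; valid only for summaries computed from the same
    weather series over contiguous windows.
    """
    return (
        abs(ts.eat - (ms.eat + rs.eat)) <= tol
        and abs(ts.total_at - (ms.total_at + rs.total_at)) <= tol
        and abs(ts.sr_sum - (ms.sr_sum + rs.sr_sum)) <= tol
    )


def combine_summaries(parts: Iterable[ThermalSummary]) -> ThermalSummary:
    """Sum summaries of contiguous windows into a whole-period summary.

    TUE and PQ are recomputed from the summed totals (a ratio of sums,
    not a mean of ratios).
    """
    parts = list(parts)
    if not parts:
        raise InvalidParameterError("cannot combine an empty set of summaries")
    eat = sum(p.eat for p in parts)
    total_at = sum(p.total_at for p in parts)
    sr_sum = sum(p.sr_sum for p in parts)
    sr_eff = sum(p.sr_sum_effective for p in parts)
    return ThermalSummary(
        eat=eat,
        total_at=total_at,
        sr_sum=sr_sum,
        sr_sum_effective=sr_eff,
        tue=100.0 * eat / total_at if total_at > 0 else math.nan,
        pq=sr_eff / eat if eat > 0 else math.nan,
        n_days=sum(p.n_days for p in parts),
        n_effective_days=sum(p.n_effective_days for p in parts),
    )
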