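"""Synthetic weather and field-trial generator for the analysis pipeline.

Emulates a two-year-style ratoon-rice stubble-height experiment —
subtropical mid-season weather with an autumn decline, a split-plot
trial of 2 stubble heights × 6 varieties × 3 replicates, stage-wise
canopy interception, and biomass/yield built as RUE × IPAR with
multiplicative lognormal observation noise — so every downstream stage
of the pipeline is testable without external data.

Biomass is RUE × IPAR *by construction* (no mechanistic crop growth),
which makes the generator invertible: with zero observation noise the
pipeline recovers the configured radiation use efficiency exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import pathlib
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from . import canopy
from .errors import CoverageError, InvalidParameterError
from .thermal import GrowthWindow

#: Fractions of each season window at which the four stages fall.
STAGE_FRACTIONS = {"MT": 0.25, "PI": 0.5, "HD": 0.7, "MA": 1.0}

#: Instrument-scale incoming light intensity for generated light-bar rows.
INCOMING_INTENSITY = 2000.0


@dataclasses.dataclass(frozen=True)
class WeatherModelParams:
    """Plateau-plus-linear-autumn-decline daily weather model.

    Defaults emulate a subtropical middle-Yangtze rice season
    (late-April transplanting, ~200-day main + ratoon run): a summer
    plateau of Tmax 31 °C / Tmin 22.3 °C / 19 MJ m⁻² d⁻¹ with linear
    declines of 0.11 °C d⁻¹ and 0.12 MJ m⁻² d⁻² after day 120, which
    puts the season means near 29.2 / 20.5 °C and 17.1 MJ m⁻² d⁻¹.
    Gaussian daily noise on temperatures and radiation.
    """

    season_start: dt.date = dt.date(2022, 4, 28)
    n_days: int = 200
    tmax_mean: float = 31.0
    tmin_mean: float = 22.3
    decline_start_day: int = 120
    t_autumn_decline: float = 0.11
    sr_mean: float = 19.0
    sr_autumn_decline: float = 0.12
    t_noise_sd: float = 1.5
    sr_noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 1:
            raise InvalidParameterError(f"n_days must be >= 1, got {self.n_days}")
        if self.tmax_mean <= self.tmin_mean:
            raise InvalidParameterError("tmax_mean must exceed tmin_mean")
        if self.sr_mean <= 0:
            raise InvalidParameterError("sr_mean must be > 0")
        if self.t_noise_sd < 0 or self.sr_noise_sd < 0:
            raise InvalidParameterError("noise SDs must be >= 0")


def generate_weather(params: WeatherModelParams) -> pd.DataFrame:
    """Generate a daily weather series (columns date, tmax, tmin, srad).

    Deterministic for fixed (params, seed).  Tmax > Tmin is enforced
    every day (Tmin clamped just below Tmax on violation); radiation is
    clamped at 0.
    """
    rng = np.random.default_rng(params.seed)
    day = np.arange(params.n_days)
    excess = np.clip(day - params.decline_start_day, 0, None).astype(float)
    tmax = params.tmax_mean - params.t_autumn_decline * excess
    tmin = params.tmin_mean - params.t_autumn_decline * excess
    srad = params.sr_mean - params.sr_autumn_decline * excess
    tmax = tmax + rng.normal(0.0, params.t_noise_sd, params.n_days)
    tmin = tmin + rng.normal(0.0, params.t_noise_sd, params.n_days)
    srad = srad + rng.normal(0.0, params.sr_noise_sd, params.n_days)
    tmin = np.minimum(tmin, tmax - 0.1)
    srad = np.clip(srad, 0.0, None)
    dates = pd.date_range(params.season_start, periods=params.n_days, freq="D")
    return pd.DataFrame({"date": dates, "tmax": tmax, "tmin": tmin, "srad": srad})


@dataclasses.dataclass(frozen=True)
class VarietySpec:
    """Per-variety season durations (days from transplanting/regrowth)."""

    name: str
    ms_duration: int
    rs_duration: int

    def __post_init__(self):
        if self.ms_duration < 1 or self.rs_duration < 1:
            raise InvalidParameterError(
                f"variety {self.name!r}: durations must be >= 1 day"
            )


DEFAULT_VARIETIES: tuple[VarietySpec, ...] = (
    VarietySpec("LY6326", 100, 64),
    VarietySpec("YY4949", 99, 71),
    VarietySpec("YLY900", 104, 62),
    VarietySpec("XLY900", 106, 62),
    VarietySpec("TYXZ", 108, 57),
    VarietySpec("CLYHZ", 110, 54),
)

#: Stage interception trajectories (%) per season and stubble level.
#: High stubble retains more functional leaf area at ratoon regrowth, so
#: its ratoon-season canopy intercepts more at every stage; the main
#: season precedes the stubble cut and is treatment-independent.
DEFAULT_IP_PROFILE: dict[str, dict[str, dict[str, float]]] = {
    "MS": {
        "LS": {"MT": 60.0, "PI": 82.0, "HD": 90.0, "MA": 86.0},
        "HS": {"MT": 60.0, "PI": 82.0, "HD": 90.0, "MA": 86.0},
    },
    "RS": {
        "LS": {"MT": 40.0, "PI": 55.0, "HD": 66.0, "MA": 62.0},
        "HS": {"MT": 55.0, "PI": 70.0, "HD": 80.0, "MA": 76.0},
    },
}


@dataclasses.dataclass(frozen=True)
class TrialDesignParams:
    """Design and effect structure for one simulated trial year.

    ``obs_noise_cv`` — the coefficient of variation of the
    multiplicative lognormal (mean-1) noise applied to total dry weight
    and yield, and of the per-reading jitter on light-bar intensities —
    is deliberately a required argument: replicate-level variability has
    no anchored default and must be an explicit choice of the analyst.
    """

    obs_noise_cv: float
    n_reps: int = 3
    stubble_levels: tuple[str, ...] = ("LS", "HS")
    varieties: tuple[VarietySpec, ...] = DEFAULT_VARIETIES
    hs_ratoon_shortening: int = 3
    ip_profile: Mapping[str, Mapping[str, Mapping[str, float]]] = dataclasses.field(
        default_factory=lambda: DEFAULT_IP_PROFILE
    )
    rue_true: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"MS": 2.6, "RS": 2.4}
    )
    harvest_index_true: float = 0.45
    rs_initial_ip: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.obs_noise_cv < 0:
            raise InvalidParameterError("obs_noise_cv must be >= 0")
        if self.n_reps < 2:
            raise InvalidParameterError("n_reps must be >= 2")
        if self.hs_ratoon_shortening < 0:
            raise InvalidParameterError("hs_ratoon_shortening must be >= 0")
        for season, per_stubble in self.ip_profile.items():
            for stubble, stages in per_stubble.items():
                for stage, ip in stages.items():
                    if not 0.0 <= ip <= 100.0:
                        raise InvalidParameterError(
                            f"ip_profile[{season}][{stubble}][{stage}] = {ip} "
                            "outside [0, 100]"
                        )
        for season, v in self.rue_true.items():
            if v <= 0:
                raise InvalidParameterError(f"rue_true[{season}] must be > 0")
        if not 0.0 < self.harvest_index_true < 1.0:
            raise InvalidParameterError("harvest_index_true must be in (0, 1)")


def _stage_dates(window: GrowthWindow) -> dict[str, dt.date]:
    span = window.n_days - 1
    out = {}
    for stage, frac in STAGE_FRACTIONS.items():
        out[stage] = window.start + dt.timedelta(days=round(frac * span))
    return out


def _plot_windows(
    design: TrialDesignParams, season_start: dt.date
) -> dict[tuple[str, str], dict[str, GrowthWindow]]:
    """MS and RS windows per (variety, stubble); regrowth starts the day
    after main-season harvest."""
    out: dict[tuple[str, str], dict[str, GrowthWindow]] = {}
    for spec in design.varieties:
        ms = GrowthWindow(
            "MS", season_start, season_start + dt.timedelta(days=spec.ms_duration - 1)
        )
        for stubble in design.stubble_levels:
            rs_dur = spec.rs_duration - (
                design.hs_ratoon_shortening if stubble == "HS" else 0
            )
            if rs_dur < 1:
                raise InvalidParameterError(
                    f"variety {spec.name!r} under {stubble}: ratoon duration "
                    f"{rs_dur} after shortening"
                )
            rs_start = ms.end + dt.timedelta(days=1)
            rs = GrowthWindow("RS", rs_start, rs_start + dt.timedelta(days=rs_dur - 1))
            out[(spec.name, stubble)] = {"MS": ms, "RS": rs}
    return out


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2)))


def generate_trial(
    weather: pd.DataFrame,
    design: TrialDesignParams,
    year: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (phenology, light readings, plot observations) tables.

    The trial is the full factorial reps × stubble × varieties of
    plot-seasons.  Per plot-season, light-bar readings realise the
    configured interception trajectory (with multiplicative per-reading
    jitter scaled by ``obs_noise_cv``); total dry weight is
    ``rue_true × IPAR`` where IPAR is recomputed from the *emitted*
    readings and weather (so the noise-free generator inverts exactly),
    and yield is ``harvest_index_true × TDW``, both under lognormal
    mean-1 noise.  Yield is reported in t ha⁻¹ (1 g m⁻² = 0.01 t ha⁻¹).

    Deterministic for fixed (weather, design).  RNG sub-streams are
    derived per plot from stable (variety, stubble, rep, season)
    offsets, so adding a variety does not perturb other plots' draws.
    """
    dates = pd.to_datetime(weather["date"])
    season_start = dates.iloc[0].date()
    last_day = dates.iloc[-1].date()
    if year is None:
        year = season_start.year
    windows = _plot_windows(design, season_start)

    for (vname, stubble), wins in windows.items():
        if wins["RS"].end > last_day:
            raise CoverageError(
                f"weather ends {last_day} but plot (variety={vname}, "
                f"stubble={stubble}) needs ratoon coverage to {wins['RS'].end}"
            )

    phen_rows, light_rows, obs_rows = [], [], []
    stubble_idx = {s: i for i, s in enumerate(design.stubble_levels)}
    for vi, spec in enumerate(design.varieties):
        for stubble in design.stubble_levels:
            wins = windows[(spec.name, stubble)]
            for rep in range(1, design.n_reps + 1):
                for season_i, season in enumerate(("MS", "RS")):
                    window = wins[season]
                    sdates = _stage_dates(window)
                    key = dict(
                        year=year, variety=spec.name, stubble=stubble,
                        rep=rep, season=season,
                    )
                    phen_rows.append(
                        {**key, "start_date": window.start,
                         **{f"{s.lower()}_date": sdates[s] for s in canopy.STAGES}}
                    )
                    rng = np.random.default_rng(
                        [design.seed, vi, stubble_idx[stubble], rep, season_i]
                    )
                    profile = design.ip_profile[season][stubble]
                    realized_ip = {}
                    for stage in canopy.STAGES:
                        target_below = INCOMING_INTENSITY * (1 - profile[stage] / 100.0)
                        if design.obs_noise_cv > 0:
                            jitter = rng.normal(1.0, design.obs_noise_cv, 6)
                            below = np.clip(target_below * jitter, 0.0, None)
                        else:
                            below = np.full(6, target_below)
                        light_rows.append(
                            {**key, "stage": stage, "stage_date": sdates[stage],
                             "incoming": INCOMING_INTENSITY,
                             **{f"below{i+1}": below[i] for i in range(6)}}
                        )
                        realized_ip[stage] = canopy.interception_pct(
                            INCOMING_INTENSITY, below
                        )
                    initial_ip = design.rs_initial_ip if season == "RS" else 0.0
                    ipar = canopy.season_ipar(
                        realized_ip, sdates, weather, window, initial_ip=initial_ip
                    )
                    tdw = design.rue_true[season] * ipar * _lognormal_factor(
                        rng, design.obs_noise_cv
                    )
                    yield_t_ha = (
                        design.harvest_index_true * tdw
                        * _lognormal_factor(rng, design.obs_noise_cv) * 0.01
                    )
                    obs_rows.append(
                        {**key, "yield_t_ha": yield_t_ha, "tdw_g_m2": tdw}
                    )

    phenology = pd.DataFrame(phen_rows)
    light = pd.DataFrame(light_rows)
    observations = pd.DataFrame(obs_rows)
    return phenology, light, observations


def write_trial(
    out_dir: str | pathlib.Path,
    weather_params: WeatherModelParams,
    design: TrialDesignParams,
    year: int | None = None,
) -> dict[str, pathlib.Path]:
    """Generate a trial and write the four pipeline input CSVs plus a
    JSON sidecar recording all true parameters and seeds."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    weather = generate_weather(weather_params)
    phenology, light, observations = generate_trial(weather, design, year=year)

    paths = {}
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"]).dt.strftime("%Y-%m-%d")
    for name, df in (
        ("weather", w), ("phenology", phenology),
        ("light", light), ("observations", observations),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    def _jsonable(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dt.date):
            return obj.isoformat()
        if isinstance(obj, Mapping):
            return {k: _jsonable(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_jsonable(v) for v in obj]
        return obj

    truth = {
        "weather_params": _jsonable(weather_params),
        "design": _jsonable(design),
        "year": year if year is not None else weather_params.season_start.year,
    }
    tp = out / "truth.json"
    tp.write_text(json.dumps(truth, indent=2))
    paths["truth"] = tp
    return paths
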