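"""End-to-end pipeline: input CSVs → index table → statistical reports.

Input schemas (comma-separated, header required):

* ``weather.csv`` — ``date`` (ISO-8601), ``tmax``, ``tmin`` (°C),
  ``srad`` (MJ m⁻² d⁻¹).
* ``phenology.csv`` — ``year, variety, stubble, rep, season,
  start_date, mt_date, pi_date, hd_date, ma_date``; ``start_date`` is
  transplanting (MS) or the start of regrowth (RS).
* ``light.csv`` — ``year, variety, stubble, rep, season, stage,
  stage_date, incoming, below1..below6``.
* ``observations.csv`` — ``year, variety, stubble, rep, season,
  yield_t_ha`` (at the 14 % moisture convention), ``tdw_g_m2``.

``build_index_table`` joins these into one row per plot-season (plus the
annual TS row) carrying EAT, total accumulated temperature, TUE, SR,
PQ, per-stage IP, IPAR, RUE, TDW and yield.  ``report_tables`` then runs
the split-plot ANOVA, LSD letter groupings, high- vs low-stubble
percentage contrasts and yield-index correlations per year and season.

All rounding happens in the reporting layer only (one decimal for
accumulations and percentages, two for PQ).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
import pathlib
import warnings

import numpy as np
import pandas as pd
import yaml

from . import canopy, splitplot, thermal
from .errors import (
    ConfigError,
    InvalidParameterError,
    MissingWeatherError,
    PhenologyError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger("ratoonlight")

PLOT_KEY = ["year", "variety", "stubble", "rep"]
SEASON_KEY = PLOT_KEY + ["season"]

_PHEN_DATES = ["start_date", "mt_date", "pi_date", "hd_date", "ma_date"]


@dataclasses.dataclass
class RunConfig:
    """Run configuration for a pipeline invocation.

    Unknown keys in the config file are errors, not warnings, to catch
    typos in scientific parameters.
    """

    weather: str
    phenology: str
    light: str
    observations: str
    out_dir: str = "."
    t0: float = thermal.BASE_TEMP
    par_fraction: float = canopy.PAR_FRACTION
    rs_initial_ip: float = 0.0
    alpha: float = 0.05
    moisture_target: float = 0.14
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if not 0 < self.par_fraction <= 1:
            raise ConfigError(f"par_fraction must be in (0, 1], got {self.par_fraction}")
        if not 0 <= self.rs_initial_ip <= 100:
            raise ConfigError(f"rs_initial_ip must be in [0, 100], got {self.rs_initial_ip}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 <= self.moisture_target < 1:
            raise ConfigError(f"moisture_target must be in [0, 1), got {self.moisture_target}")

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} is not a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        missing = [k for k in ("weather", "phenology", "light", "observations") if k not in raw]
        if missing:
            raise ConfigError(f"missing required config keys: {missing}")
        return cls(**raw)

    def echo_defaults(self) -> None:
        """Log every scientific default actually in effect, so runs are
        self-describing."""
        logger.info(
            "conventions: EAT = sum(Tmean - t0) over days with Tmean >= t0; "
            "t0=%g degC; PAR fraction=%g; ratoon initial interception=%g%%; "
            "alpha=%g; yield moisture target=%g",
            self.t0, self.par_fraction, self.rs_initial_ip, self.alpha,
            self.moisture_target,
        )


def adjust_yield_moisture(
    weight: float, moisture_content: float, target: float = 0.14
) -> float:
    """Rescale a fresh grain weight to the standard moisture content.

    Dry matter is preserved: ``weight · (1 − moisture) / (1 − target)``.
    Units pass through (t ha⁻¹ in → t ha⁻¹ out).
    """
    if not 0 <= moisture_content < 1:
        raise InvalidParameterError(
            f"moisture content must be in [0, 1), got {moisture_content}"
        )
    if not 0 <= target < 1:
        raise InvalidParameterError(f"target moisture must be in [0, 1), got {target}")
    if weight < 0:
        raise InvalidParameterError(f"weight must be >= 0, got {weight}")
    return weight * (1.0 - moisture_content) / (1.0 - target)


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(thermal.WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"weather file missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"])
    if (df["tmax"] < df["tmin"]).any():
        bad = df.loc[df.tmax < df.tmin, "date"].iloc[0].date()
        raise SchemaError(f"tmax < tmin on {bad}")
    if (df["srad"] < 0).any():
        raise SchemaError("negative solar radiation in weather file")
    return df


def read_phenology(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = set(SEASON_KEY + _PHEN_DATES)
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"phenology file missing columns: {sorted(missing)}")
    for col in _PHEN_DATES:
        df[col] = pd.to_datetime(df[col]).dt.date
    return df


def read_light(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    below = [f"below{i}" for i in range(1, 7)]
    need = set(SEASON_KEY + ["stage", "stage_date", "incoming"] + below)
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"light file missing columns: {sorted(missing)}")
    df["stage_date"] = pd.to_datetime(df["stage_date"]).dt.date
    return df


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = set(SEASON_KEY + ["yield_t_ha", "tdw_g_m2"])
    missing = need - set(df.columns)
    if missing:
        raise SchemaError(f"observations file missing columns: {sorted(missing)}")
    if (df["yield_t_ha"] < 0).any() or (df["tdw_g_m2"] < 0).any():
        raise SchemaError("negative yield or dry weight in observations")
    return df


def build_index_table(
    weather: pd.DataFrame,
    phenology: pd.DataFrame,
    light: pd.DataFrame,
    observations: pd.DataFrame,
    t0: float = thermal.BASE_TEMP,
    par_fraction: float = canopy.PAR_FRACTION,
    rs_initial_ip: float = 0.0,
) -> pd.DataFrame:
    """Compute the per-plot-season index table, with annual (TS) rows.

    Every referential gap across the four inputs — an observation with
    no phenology, an incomplete light-stage profile, a weather series
    that does not cover a window — is collected into one aggregated
    :class:`~ratoonlight.errors.ValidationError` before aborting, so a
    single run reports every offending plot key.
    """
    phen_idx = phenology.set_index(SEASON_KEY)
    if phen_idx.index.has_duplicates:
        raise ValidationError(["duplicate phenology rows for "
                               + str(phen_idx.index[phen_idx.index.duplicated()][0])])
    light_grp = {k: g for k, g in light.groupby(SEASON_KEY)}

    problems: list[str] = []
    rows: list[dict] = []
    below_cols = [f"below{i}" for i in range(1, 7)]

    for _, obs in observations.iterrows():
        key = tuple(obs[k] for k in SEASON_KEY)
        keystr = f"(year={key[0]}, variety={key[1]}, stubble={key[2]}, rep={key[3]}, season={key[4]})"
        if key not in phen_idx.index:
            problems.append(f"no phenology for plot-season {keystr}")
            continue
        phen = phen_idx.loc[key]
        season = key[4]
        window = thermal.GrowthWindow(season, phen["start_date"], phen["ma_date"])

        lg = light_grp.get(key)
        if lg is None or sorted(lg["stage"]) != sorted(canopy.STAGES):
            got = sorted(lg["stage"]) if lg is not None else []
            problems.append(
                f"incomplete light profile for {keystr}: stages {got}"
            )
            continue
        try:
            stage_ip = {}
            stage_dates = {}
            for _, lrow in lg.iterrows():
                stage_ip[lrow["stage"]] = canopy.interception_pct(
                    lrow["incoming"], lrow[below_cols].to_numpy(dtype=float)
                )
                stage_dates[lrow["stage"]] = lrow["stage_date"]
            summary = thermal.accumulate(weather, window, t0=t0)
            initial_ip = rs_initial_ip if season == "RS" else 0.0
            ipar = canopy.season_ipar(
                stage_ip, stage_dates, weather, window,
                initial_ip=initial_ip, par_fraction=par_fraction,
            )
        except (MissingWeatherError, PhenologyError, SchemaError) as exc:
            problems.append(f"{keystr}: {exc}")
            continue

        tdw = float(obs["tdw_g_m2"])
        rows.append({
            **dict(zip(SEASON_KEY, key)),
            "n_days": summary.n_days,
            "eat": summary.eat,
            "total_at": summary.total_at,
            "tue": summary.tue,
            "sr_sum": summary.sr_sum,
            "sr_sum_effective": summary.sr_sum_effective,
            "pq": summary.pq,
            **{f"ip_{s.lower()}": stage_ip[s] for s in canopy.STAGES},
            "ipar": ipar,
            "tdw": tdw,
            "rue": canopy.rue(tdw, ipar),
            "yield_t_ha": float(obs["yield_t_ha"]),
        })

    if problems:
        raise ValidationError(problems)

    index = pd.DataFrame(rows)

    # Annual (TS) rows: additive accumulations, ratio-of-totals efficiencies.
    ts_rows = []
    for plot_key, grp in index.groupby(PLOT_KEY):
        if set(grp["season"]) != {"MS", "RS"}:
            problems.append(
                f"plot {plot_key}: need both MS and RS for the annual row, "
                f"got {sorted(grp['season'])}"
            )
            continue
        ms = grp[grp.season == "MS"].iloc[0]
        rs = grp[grp.season == "RS"].iloc[0]
        eat = ms.eat + rs.eat
        total_at = ms.total_at + rs.total_at
        sr_eff = ms.sr_sum_effective + rs.sr_sum_effective
        tdw = ms.tdw + rs.tdw
        ipar = ms.ipar + rs.ipar
        ts_rows.append({
            **dict(zip(PLOT_KEY, plot_key)), "season": "TS",
            "n_days": int(ms.n_days + rs.n_days),
            "eat": eat,
            "total_at": total_at,
            "tue": 100.0 * eat / total_at if total_at > 0 else math.nan,
            "sr_sum": ms.sr_sum + rs.sr_sum,
            "sr_sum_effective": sr_eff,
            "pq": sr_eff / eat if eat > 0 else math.nan,
            **{f"ip_{s.lower()}": math.nan for s in canopy.STAGES},
            "ipar": ipar,
            "tdw": tdw,
            "rue": tdw / ipar if ipar > 0 else math.nan,
            "yield_t_ha": ms.yield_t_ha + rs.yield_t_ha,
        })
    if problems:
        raise ValidationError(problems)

    out = pd.concat([index, pd.DataFrame(ts_rows)], ignore_index=True)
    season_order = {"MS": 0, "RS": 1, "TS": 2}
    out = out.sort_values(
        PLOT_KEY + ["season"], key=lambda c: c.map(season_order) if c.name == "season" else c
    ).reset_index(drop=True)
    return out


def build_index_table_from_config(config: RunConfig) -> pd.DataFrame:
    config.echo_defaults()
    return build_index_table(
        read_weather(config.weather),
        read_phenology(config.phenology),
        read_light(config.light),
        read_observations(config.observations),
        t0=config.t0,
        par_fraction=config.par_fraction,
        rs_initial_ip=config.rs_initial_ip,
    )


#: Responses analysed per season, with report rounding (decimals).
RESPONSES = {
    "eat": 1, "sr_sum": 1, "tue": 1, "pq": 2, "ip": 1,
    "ipar": 1, "rue": 1, "tdw": 1, "yield_t_ha": 2,
}

#: The single season-level interception summary reported in tables is
#: the heading-stage (HD) interception.
SEASON_IP_COLUMN = "ip_hd"


def _response_frame(index: pd.DataFrame, response: str) -> pd.Series:
    if response == "ip":
        return index[SEASON_IP_COLUMN]
    return index[response]


def report_tables(
    index: pd.DataFrame,
    alpha: float = 0.05,
    out_dir: str | pathlib.Path | None = None,
) -> dict[str, object]:
    """Run the statistical layer over an index table.

    Per (year, season, response): split-plot ANOVA (stubble = whole
    plot, variety = sub plot, rep = block), three letter groupings
    (variety means, stubble means, stubble within variety), and the
    HS-vs-LS percentage contrast of treatment means.  Per (year,
    season, stubble): Pearson correlation and OLS fit of yield against
    every index.  Responses with zero variance are skipped with a log
    notice.  Returns the bundle as DataFrames plus a text summary;
    writes ``indices.csv, anova.csv, letters.csv, contrasts.csv,
    correlations.csv, summary.txt`` when ``out_dir`` is given.
    """
    anova_rows, letter_rows, contrast_rows, corr_rows = [], [], [], []
    summary_lines = [
        "ratoon-rice light-temperature resource-use report",
        f"plots: {index.groupby(PLOT_KEY).ngroups}; alpha = {alpha}",
        "",
    ]

    for (year, season), grp in index.groupby(["year", "season"]):
        for response, ndec in RESPONSES.items():
            if season == "TS" and response == "ip":
                continue
            vals = _response_frame(grp, response)
            if vals.isna().any():
                logger.info("skipping %s %s %s: undefined values", year, season, response)
                continue
            data = grp[SEASON_KEY].copy()
            data["y"] = vals.to_numpy()
            if np.ptp(data["y"].to_numpy()) == 0:
                logger.info(
                    "skipping statistics for %s %s %s: zero variance", year, season, response
                )
                continue
            degenerate = grp["variety"].nunique() < 2 or grp["stubble"].nunique() < 2
            if degenerate:
                # too few factor levels for the split-plot strata; letters
                # are omitted but the treatment contrast below still runs
                logger.info(
                    "skipping ANOVA/letters for %s %s %s: degenerate design",
                    year, season, response,
                )
                means = data.groupby("stubble")["y"].mean()
                if {"HS", "LS"} <= set(means.index) and means["LS"] != 0:
                    contrast_rows.append({
                        "year": year, "season": season, "response": response,
                        "mean_ls": means["LS"], "mean_hs": means["HS"],
                        "pct_change": round(
                            splitplot.pct_contrast(means["HS"], means["LS"]), 1
                        ),
                    })
                continue
            model = splitplot.SplitPlotAnova(data, "y")
            res = model.fit()
            for source in ("Whole", "Sub", "Sub_x_Whole", "Error_a", "Error_b"):
                row = res.anova.loc[source]
                anova_rows.append({
                    "year": year, "season": season, "response": response,
                    "source": {"Whole": "T", "Sub": "V", "Sub_x_Whole": "V*T",
                               "Error_a": "Error(a)", "Error_b": "Error(b)"}[source],
                    "ss": row.ss, "df": int(row.df), "ms": row.ms,
                    "F": row.F,
                    "p": splitplot.format_p(row.p) if not math.isnan(row.p) else "",
                    "sig": splitplot.significance_code(row.p)
                    if not math.isnan(row.p) else "",
                })
            for scope, tag in (("sub", "variety"), ("whole", "treatment")):
                for _, lrow in res.letters(scope, alpha).iterrows():
                    letter_rows.append({
                        "year": year, "season": season, "response": response,
                        "scope": tag, "level": lrow["level"],
                        "mean": round(lrow["mean"], ndec), "letters": lrow["letters"],
                    })
            for _, lrow in res.whole_within_sub_letters(alpha).iterrows():
                letter_rows.append({
                    "year": year, "season": season, "response": response,
                    "scope": "treatment-within-variety",
                    "level": f"{lrow['variety']}:{lrow['level']}",
                    "mean": round(lrow["mean"], ndec), "letters": lrow["letters"],
                })
            means = res.means("whole")
            if "HS" in means.index and "LS" in means.index and means["LS"] != 0:
                contrast_rows.append({
                    "year": year, "season": season, "response": response,
                    "mean_ls": means["LS"], "mean_hs": means["HS"],
                    "pct_change": round(
                        splitplot.pct_contrast(means["HS"], means["LS"]), 1
                    ),
                })

        # yield-index correlations per stubble level
        for stubble, sgrp in grp.groupby("stubble"):
            y = sgrp["yield_t_ha"].to_numpy()
            for response in ("eat", "sr_sum", "pq", "ip", "ipar", "rue", "tue", "tdw"):
                if season == "TS" and response == "ip":
                    continue
                x = _response_frame(sgrp, response).to_numpy()
                if len(x) < 3 or np.isnan(x).any():
                    continue
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    logger.info(
                        "skipping correlation %s %s %s %s: zero variance",
                        year, season, stubble, response,
                    )
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    c = splitplot.correlate(x, y)
                corr_rows.append({
                    "year": year, "season": season, "stubble": stubble,
                    "x": response, "y": "yield_t_ha", "n": c.n,
                    "r": round(c.r, 3), "p": splitplot.format_p(c.p),
                    "slope": c.slope, "intercept": c.intercept,
                })

    bundle = {
        "indices": index,
        "anova": pd.DataFrame(anova_rows),
        "letters": pd.DataFrame(letter_rows),
        "contrasts": pd.DataFrame(contrast_rows),
        "correlations": pd.DataFrame(corr_rows),
    }

    if not bundle["contrasts"].empty:
        summary_lines.append("high- vs low-stubble % change of treatment means:")
        for _, r in bundle["contrasts"].iterrows():
            summary_lines.append(
                f"  {r['year']} {r['season']} {r['response']}: {r['pct_change']:+.1f}%"
            )
    bundle["summary"] = "\n".join(summary_lines) + "\n"

    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("indices", "anova", "letters", "contrasts", "correlations"):
            bundle[name].to_csv(out / f"{name}.csv", index=False)
        (out / "summary.txt").write_text(bundle["summary"])
    return bundle


def input_checksums(config: RunConfig) -> dict[str, str]:
    """SHA-256 checksums of the four input files, for provenance metadata."""
    out = {}
    for name in ("weather", "phenology", "light", "observations"):
        path = pathlib.Path(getattr(config, name))
        out[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out
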