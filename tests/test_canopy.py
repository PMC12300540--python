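"""Canopy interception, stage-wise IPAR integration and RUE."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from ratoonlight import canopy
from ratoonlight.errors import (
    InvalidParameterError,
    InvalidReadingError,
    PhenologyError,
    SchemaError,
)
from ratoonlight.thermal import GrowthWindow

from conftest import full_window, make_weather, random_weather


class TestInterception:
    @pytest.mark.parametrize(
        "incoming,below,expected",
        [
            (2000.0, [500.0] * 6, 75.0),
            (2000.0, [2000.0] * 6, 0.0),
            (1800.0, [900, 850, 800, 400, 450, 500], 100 * (1800 - 650) / 1800),
        ],
    )
    def test_examples(self, incoming, below, expected):
        assert canopy.interception_pct(incoming, below) == pytest.approx(expected)

    def test_below_exceeding_incoming_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            ip = canopy.interception_pct(1000.0, [1200.0] * 6)
        assert ip == 0.0

    def test_invalid_incoming(self):
        with pytest.raises(InvalidReadingError):
            canopy.interception_pct(0.0, [1.0] * 6)

    def test_wrong_reading_count(self):
        with pytest.raises(SchemaError):
            canopy.interception_pct(1000.0, [1.0] * 5)


class TestStageIpar:
    @pytest.mark.parametrize(
        "ip0,ip1,sr,expected",
        [
            (40.0, 60.0, 300.0, 67.5),
            (0.0, 0.0, 500.0, 0.0),
            (63.8, 80.4, 412.7, 133.900515),  # hand arithmetic: .5*1.442*.45*412.7
        ],
    )
    def test_examples(self, ip0, ip1, sr, expected):
        assert canopy.stage_ipar(ip0, ip1, sr) == pytest.approx(expected, abs=1e-6)

    def test_negative_radiation_rejected(self):
        with pytest.raises(InvalidParameterError):
            canopy.stage_ipar(10.0, 20.0, -1.0)

    def test_out_of_range_ip_rejected(self):
        with pytest.raises(InvalidParameterError):
            canopy.stage_ipar(-1.0, 20.0, 10.0)


def _profile(window, ips):
    span = window.n_days - 1
    dates = {
        "MT": window.start + dt.timedelta(days=round(0.25 * span)),
        "PI": window.start + dt.timedelta(days=round(0.5 * span)),
        "HD": window.start + dt.timedelta(days=round(0.7 * span)),
        "MA": window.end,
    }
    return dict(zip(canopy.STAGES, ips)), dates


def day_loop_ipar(stage_ip, stage_dates, weather, window, initial_ip=0.0, par_fraction=0.45):
    """Independent day-level oracle: piecewise-constant interval means."""
    bounds = [window.start] + [stage_dates[s] for s in canopy.STAGES]
    ips = [initial_ip] + [stage_ip[s] for s in canopy.STAGES]
    total = 0.0
    for _, row in weather.iterrows():
        d = pd.Timestamp(row["date"]).date()
        if not (window.start <= d <= window.end):
            continue
        for i in range(4):
            in_interval = (
                (bounds[i] <= d < bounds[i + 1]) if i < 3
                else (bounds[i] <= d <= bounds[i + 1])
            )
            if in_interval:
                mean_ip = 0.5 * (ips[i] + ips[i + 1])
                total += par_fraction * row["srad"] * mean_ip / 100.0
                break
    return total


class TestSeasonIpar:
    def test_transparent_canopy_intercepts_nothing(self):
        w = make_weather(21)
        win = full_window(w)
        ips, dates = _profile(win, [0, 0, 0, 0])
        assert canopy.season_ipar(ips, dates, w, win) == 0.0

    def test_full_interception_reaches_par_upper_bound(self):
        w = make_weather(21, srad=17.0)
        win = full_window(w)
        ips, dates = _profile(win, [100, 100, 100, 100])
        got = canopy.season_ipar(ips, dates, w, win, initial_ip=100.0)
        assert got == pytest.approx(0.45 * w["srad"].sum(), abs=1e-9)

    def test_matches_day_level_oracle_on_seeded_plots(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            w = random_weather(rng, 60)
            win = full_window(w)
            ips, dates = _profile(win, sorted(rng.uniform(5, 95, 4)))
            init = float(rng.uniform(0, 30))
            got = canopy.season_ipar(ips, dates, w, win, initial_ip=init)
            want = day_loop_ipar(ips, dates, w, win, initial_ip=init)
            assert got == pytest.approx(want, abs=1e-9)

    def test_never_exceeds_par_fraction_of_window_radiation(self):
        rng = np.random.default_rng(3)
        w = random_weather(rng, 40)
        win = full_window(w)
        ips, dates = _profile(win, rng.uniform(0, 100, 4))
        assert canopy.season_ipar(ips, dates, w, win) <= 0.45 * w["srad"].sum() + 1e-9

    def test_raising_one_stage_ip_never_decreases_ipar(self):
        w = make_weather(30, srad=15.0)
        win = full_window(w)
        base_ips, dates = _profile(win, [30, 50, 70, 60])
        base = canopy.season_ipar(base_ips, dates, w, win)
        for stage in canopy.STAGES:
            bumped = dict(base_ips, **{stage: base_ips[stage] + 10})
            assert canopy.season_ipar(bumped, dates, w, win) >= base

    def test_out_of_order_stages_rejected(self):
        w = make_weather(21)
        win = full_window(w)
        ips, dates = _profile(win, [10, 20, 30, 40])
        dates["PI"], dates["HD"] = dates["HD"], dates["PI"]
        with pytest.raises(PhenologyError):
            canopy.season_ipar(ips, dates, w, win)

    def test_harvest_after_window_end_refused(self):
        w = make_weather(21)
        win = full_window(w)
        ips, dates = _profile(win, [10, 20, 30, 40])
        dates["MA"] = win.end - dt.timedelta(days=2)
        with pytest.raises(PhenologyError, match="MA"):
            canopy.season_ipar(ips, dates, w, win)


class TestRue:
    @pytest.mark.parametrize(
        "tdw,ipar,expected",
        [
            (3147.7, 1223.7, 2.6),  # published LY6326 LS annual cells
            (936.0, 396.2, 2.4),    # published LY6326 LS ratoon cells
            (0.0, 100.0, 0.0),
        ],
    )
    def test_examples(self, tdw, ipar, expected):
        assert round(canopy.rue(tdw, ipar), 1) == pytest.approx(expected)

    def test_nonpositive_ipar_flags_nan(self):
        with pytest.warns(UserWarning, match="RUE undefined"):
            assert math.isnan(canopy.rue(100.0, 0.0))


class TestAnnualTotals:
    def test_published_row_components_add(self):
        ts = canopy.annual_totals(
            {"tdw": 2211.7, "ipar": 827.5}, {"tdw": 936.0, "ipar": 396.2}
        )
        assert ts["tdw"] == pytest.approx(3147.7)
        assert ts["ipar"] == pytest.approx(1223.7)
        assert ts["rue"] == pytest.approx(3147.7 / 1223.7)

    def test_symmetric_seasons_preserve_common_rue(self):
        ts = canopy.annual_totals({"tdw": 500.0, "ipar": 200.0},
                                  {"tdw": 500.0, "ipar": 200.0})
        assert ts["rue"] == pytest.approx(2.5)

    def test_missing_key_rejected(self):
        with pytest.raises(SchemaError):
            canopy.annual_totals({"tdw": 1.0}, {"tdw": 1.0, "ipar": 1.0})
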