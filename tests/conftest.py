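import numpy as np
import pandas as pd
import pytest

from ratoonlight import synthetic
from ratoonlight.thermal import GrowthWindow


def make_weather(n_days, tmax=30.0, tmin=20.0, srad=17.0, start="2022-05-01"):
    dates = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame({
        "date": dates,
        "tmax": np.broadcast_to(tmax, n_days).astype(float),
        "tmin": np.broadcast_to(tmin, n_days).astype(float),
        "srad": np.broadcast_to(srad, n_days).astype(float),
    })


def random_weather(rng, n_days, start="2022-05-01"):
    """Random daily weather spanning the 10 degC effectiveness threshold."""
    tmin = rng.uniform(2.0, 24.0, n_days)
    tmax = tmin + rng.uniform(0.5, 12.0, n_days)
    srad = rng.uniform(0.0, 30.0, n_days)
    dates = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame({"date": dates, "tmax": tmax, "tmin": tmin, "srad": srad})


def full_window(weather, label="MS"):
    d = pd.to_datetime(weather["date"])
    return GrowthWindow(label, d.iloc[0].date(), d.iloc[-1].date())


@pytest.fixture(scope="session")
def trial_weather():
    return synthetic.generate_weather(synthetic.WeatherModelParams(seed=1))


@pytest.fixture(scope="session")
def noise_free_trial(trial_weather):
    design = synthetic.TrialDesignParams(obs_noise_cv=0.0, seed=2)
    phen, light, obs = synthetic.generate_trial(trial_weather, design)
    return design, phen, light, obs
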