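"""Synthetic forcing data: growth-chamber regimes and field weather.

Two kinds of inputs are emulated.  The chamber generator reproduces a
controlled-environment protocol: three day/night temperature regimes
(control 25/15, moderate 30/20, severe 35/25 deg C) with 3-hour ramps
between night minimum and day maximum, 70 % relative humidity, 900 umol
m-2 s-1 of lamp light and 2 m s-1 of fan wind, run as five consecutive
7-day phases (pre-treatment, treatment, recovery, treatment, recovery)
where the elevated temperatures apply only during the treatment weeks.
The field generator produces multi-year temperate daily weather (seasonal
sinusoids with autocorrelated anomalies, Markov-chain rainfall, PET,
radiation, humidity, wind) in a high-rainfall cool-temperate and a
medium-rainfall warm-temperate flavour.  All generators are pure functions
of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .energy_budget import saturation_vapor_pressure


@dataclass(frozen=True)
class ChamberRegime:
    """One growth chamber: day/night set points and ambient conditions."""

    t_day: float  # deg C, daytime plateau (daily maximum)
    t_night: float  # deg C, nighttime plateau (daily minimum)
    ramp_hours: float = 3.0
    day_plateau_hours: float = 9.0
    rh: float = 70.0  # %
    ppfd: float = 900.0  # umol m-2 s-1
    wind: float = 2.0  # m s-1
    phase_days: int = 7

    def __post_init__(self) -> None:
        if self.t_day <= self.t_night:
            raise ValueError("t_day must exceed t_night")
        if 2 * self.ramp_hours + self.day_plateau_hours >= 24:
            raise ValueError("diurnal profile does not fit in 24 h")

    @property
    def t_mean(self) -> float:
        """Time-weighted mean of the trapezoidal diurnal profile."""
        night_plateau = 24.0 - self.day_plateau_hours - 2.0 * self.ramp_hours
        ramp_mean = 0.5 * (self.t_day + self.t_night)
        return (
            self.day_plateau_hours * self.t_day
            + night_plateau * self.t_night
            + 2.0 * self.ramp_hours * ramp_mean
        ) / 24.0


CONTROL = ChamberRegime(t_day=25.0, t_night=15.0)
MODERATE = ChamberRegime(t_day=30.0, t_night=20.0)
SEVERE = ChamberRegime(t_day=35.0, t_night=25.0)
REGIMES = {"control": CONTROL, "moderate": MODERATE, "severe": SEVERE}

PHASES = ("pre", "treatment1", "recovery1", "treatment2", "recovery2")
_TREATMENT_PHASES = frozenset({"treatment1", "treatment2"})


def chamber_weather(
    regime: ChamberRegime, start: str = "2021-01-01"
) -> pd.DataFrame:
    """Deterministic 35-day chamber weather series (5 phases x 7 days).

    During pre-treatment and recovery weeks the chamber runs at the control
    set points; the regime's elevated temperatures apply only during the two
    treatment weeks.  Columns: date, phase, tmax, tmin, tmean (trapezoid
    mean), rh, ppfd, wind, rain, pet (the last two are zero placeholders:
    chamber watering is expressed as a forced GLF_W schedule instead).
    """
    rows = []
    date = pd.Timestamp(start)
    for phase in PHASES:
        active = regime if phase in _TREATMENT_PHASES else CONTROL
        for _ in range(regime.phase_days):
            rows.append(
                {
                    "date": date,
                    "phase": phase,
                    "tmax": active.t_day,
                    "tmin": active.t_night,
                    "tmean": active.t_mean,
                    "rh": regime.rh,
                    "ppfd": regime.ppfd,
                    "wind": regime.wind,
                    "rain": 0.0,
                    "pet": 0.0,
                }
            )
            date += pd.Timedelta(days=1)
    return pd.DataFrame(rows)


def watering_schedule(
    regime: ChamberRegime,
    arm: str,
    dry_down_min: float = 0.05,
    curve: str = "linear",
) -> np.ndarray:
    """Daily GLF_W forcing for the well-watered (WW) or water-stressed (WS) arm.

    WW pots are watered to field capacity daily (GLF_W = 1 throughout).  In
    the WS arm irrigation is withheld during each 7-day treatment week: the
    soil starts wet (GLF_W = 1 on day 1) and dries to ``dry_down_min`` by
    day 7, linearly by default or exponentially; watering resumes in the
    recovery weeks.
    """
    if arm not in ("WW", "WS"):
        raise ValueError(f"unknown watering arm {arm!r}")
    n = regime.phase_days
    glf = []
    for phase in PHASES:
        if arm == "WW" or phase not in _TREATMENT_PHASES:
            glf.extend([1.0] * n)
            continue
        frac = np.arange(n) / (n - 1)  # 0 on day 1, 1 on day 7
        if curve == "linear":
            vals = 1.0 - frac * (1.0 - dry_down_min)
        elif curve == "exponential":
            vals = dry_down_min ** frac
        else:
            raise ValueError(f"unknown dry-down curve {curve!r}")
        glf.extend(vals.tolist())
    return np.asarray(glf)


@dataclass(frozen=True)
class SiteProfile:
    """Climatology knobs for the field weather generator."""

    name: str
    latitude: float
    tmax_mean: float  # annual mean of daily maxima, deg C
    tmax_amplitude: float  # seasonal half-range of daily maxima
    diurnal_range: float  # mean tmax - tmin
    rain_p_wet_given_dry: float
    rain_p_wet_given_wet: float
    rain_mean_mm: float  # mean wet-day amount
    pet_summer: float  # mm day-1 midsummer
    pet_winter: float


# loosely styled on a high-rainfall cool-temperate and a medium-rainfall
# warm-temperate pasture zone of south-eastern Australia
COOL_TEMPERATE = SiteProfile(
    name="cool-temperate",
    latitude=-38.25,
    tmax_mean=18.0,
    tmax_amplitude=7.0,
    diurnal_range=10.0,
    rain_p_wet_given_dry=0.35,
    rain_p_wet_given_wet=0.55,
    rain_mean_mm=6.0,
    pet_summer=5.5,
    pet_winter=1.0,
)
WARM_TEMPERATE = SiteProfile(
    name="warm-temperate",
    latitude=-36.37,
    tmax_mean=21.5,
    tmax_amplitude=9.0,
    diurnal_range=12.0,
    rain_p_wet_given_dry=0.22,
    rain_p_wet_given_wet=0.45,
    rain_mean_mm=5.0,
    pet_summer=7.0,
    pet_winter=1.0,
)
SITES = {"cool-temperate": COOL_TEMPERATE, "warm-temperate": WARM_TEMPERATE}


def field_weather(
    n_years: int,
    seed: int,
    site: SiteProfile | str = "cool-temperate",
    start_year: int = 2000,
) -> pd.DataFrame:
    """Seeded multi-year daily weather for a temperate pasture site.

    Southern-hemisphere seasonality (warmest around mid-January).  Daily
    maxima are a seasonal sinusoid plus AR(1) anomalies; minima follow at a
    noisy diurnal range below; radiation and PET track the season; rainfall
    occurrence is a two-state Markov chain with exponential amounts; vapor
    pressure is near-saturation at the daily minimum (dewpoint ~ tmin).
    Columns: date, tmax, tmin, radiation (MJ m-2), rh (%), vp (kPa),
    wind (m s-1), rain (mm), pet (mm).
    """
    if n_years < 1:
        raise ValueError("n_years must be at least 1")
    profile = SITES[site] if isinstance(site, str) else site
    rng = np.random.default_rng(seed)

    dates = pd.date_range(f"{start_year}-01-01", periods=365 * n_years, freq="D")
    doy = dates.dayofyear.to_numpy()
    n = len(dates)
    # peak near 15 January in the southern hemisphere
    season = np.cos(2.0 * np.pi * (doy - 15) / 365.0)

    anomaly = np.empty(n)
    anomaly[0] = rng.normal(0.0, 3.0)
    eps = rng.normal(0.0, 3.0 * np.sqrt(1 - 0.6**2), size=n)
    for i in range(1, n):
        anomaly[i] = 0.6 * anomaly[i - 1] + eps[i]

    tmax = profile.tmax_mean + profile.tmax_amplitude * season + anomaly
    tmin = tmax - profile.diurnal_range + rng.normal(0.0, 1.5, size=n)
    tmin = np.minimum(tmin, tmax - 1.0)

    radiation = np.clip(
        18.0 + 10.0 * season + rng.normal(0.0, 2.5, size=n), 2.0, 33.0
    )
    pet_mid = 0.5 * (profile.pet_summer + profile.pet_winter)
    pet_amp = 0.5 * (profile.pet_summer - profile.pet_winter)
    pet = np.clip(pet_mid + pet_amp * season + rng.normal(0.0, 0.4, size=n), 0.2, None)

    wet = np.empty(n, dtype=bool)
    wet[0] = rng.random() < 0.3
    u = rng.random(n)
    for i in range(1, n):
        p = profile.rain_p_wet_given_wet if wet[i - 1] else profile.rain_p_wet_given_dry
        wet[i] = u[i] < p
    rain = np.where(wet, rng.exponential(profile.rain_mean_mm, size=n), 0.0)

    vp = np.array([0.95 * saturation_vapor_pressure(t) for t in np.clip(tmin, -19, 59)])
    esat_max = np.array(
        [saturation_vapor_pressure(t) for t in np.clip(tmax, -19, 59)]
    )
    rh = np.clip(100.0 * vp / esat_max, 5.0, 100.0)
    wind = np.clip(rng.lognormal(mean=0.9, sigma=0.4, size=n), 0.3, 15.0)

    return pd.DataFrame(
        {
            "date": dates,
            "tmax": np.round(tmax, 2),
            "tmin": np.round(tmin, 2),
            "radiation": np.round(radiation, 2),
            "rh": np.round(rh, 1),
            "vp": np.round(vp, 3),
            "wind": np.round(wind, 2),
            "rain": np.round(rain, 2),
            "pet": np.round(pet, 2),
        }
    )


def noisy_measurements(t_leaf, sigma: float, seed: int) -> np.ndarray:
    """Simulated infrared leaf-temperature measurements: truth + N(0, sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    truth = np.asarray(t_leaf, dtype=float)
    rng = np.random.default_rng(seed)
    return truth + rng.normal(0.0, sigma, size=truth.shape)
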