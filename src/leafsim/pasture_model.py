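"""Minimal daily pasture photosynthesis simulator with heat-stress recovery.

Daily net positive growth is a four-factor multiplicative model

    growth = max(0, p_max * f(T) * GLF_W * HT * light)

where ``f(T)`` is a trapezoidal temperature response (zero below a minimum,
a plateau between the two optimum temperatures, zero again at the full
heat-stress threshold), ``GLF_W`` the soil-water growth-limiting factor from
a single-bucket water balance, and ``HT`` an empirical high-temperature
stress coefficient on [0, 1] (1 = no stress).  Stress sets in when the
daily maximum exceeds an onset threshold and is complete at a second, full
threshold; recovery afterwards accumulates heat units
``max(0, recovery_base - t_mean)`` per stress-free day until their sum
reaches the T_sum parameter, at which point the coefficient returns to 1.

Management covers a deficit-triggered irrigation rule and end-of-month
cutting to a residual biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class PastureParams:
    """Growth-response, stress and management parameters for a temperate pasture.

    Defaults describe perennial ryegrass: growth between ~5 deg C and a
    15-23 deg C optimum plateau, high-temperature stress onset at 30 deg C
    and full stress at 35 deg C, and a default recovery requirement of
    T_sum = 100 heat units (values of 50 and 20 represent faster-recovering
    parameterizations; ~200 emulates summer dormancy).
    """

    p_max: float = 40.0  # potential net positive photosynthesis, kg C ha-1 day-1
    t_min_growth: float = 5.0  # deg C
    t_opt_lo: float = 15.0
    t_opt_hi: float = 23.0
    ht_onset: float = 30.0
    ht_full: float = 35.0
    t_sum: float = 100.0  # heat units to full recovery
    recovery_base: float = 25.0  # deg C
    residual: float = 1.4  # t DM ha-1 left after each monthly cut
    pawc: float = 80.0  # plant-available water capacity, mm
    dm_per_c: float = 2.5  # kg DM per kg C (~40 % carbon in dry matter)
    initial_biomass: float = 1.4  # t DM ha-1

    def __post_init__(self) -> None:
        if not self.t_min_growth < self.t_opt_lo <= self.t_opt_hi < self.ht_full:
            raise ValueError("temperature response breakpoints must be ordered")
        if not self.ht_onset < self.ht_full:
            raise ValueError("ht_onset must be below ht_full")
        if self.t_sum <= 0:
            raise ValueError("t_sum must be positive")
        if self.residual <= 0:
            raise ValueError("residual must be positive")
        if self.pawc <= 0:
            raise ValueError("pawc must be positive")


IRRIGATION_AMOUNT = 50.0  # mm applied per event
IRRIGATION_DEFICIT_TRIGGER = 25.0  # mm of cumulative PET - rain over 5 days
IRRIGATION_WINDOW = 5  # days


def temperature_growth_factor(t: float, params: PastureParams) -> float:
    """Trapezoidal temperature response on [0, 1].

    Zero at or below ``t_min_growth``, rising linearly to 1 at ``t_opt_lo``,
    flat to ``t_opt_hi``, then falling linearly to zero at ``ht_full``.
    """
    return float(
        np.interp(
            t,
            [params.t_min_growth, params.t_opt_lo, params.t_opt_hi, params.ht_full],
            [0.0, 1.0, 1.0, 0.0],
        )
    )


def ht_stress_coefficient(t_max: float, params: PastureParams) -> float:
    """Instantaneous high-temperature stress coefficient for one day.

    1 up to the onset threshold, falling linearly to 0 at the full-stress
    threshold, 0 beyond.
    """
    if t_max <= params.ht_onset:
        return 1.0
    if t_max >= params.ht_full:
        return 0.0
    return (params.ht_full - t_max) / (params.ht_full - params.ht_onset)


@dataclass
class StressState:
    """Running heat-stress coefficient and its recovery accumulator.

    ``stressed_level`` remembers the lowest coefficient reached in the most
    recent stress episode; the visible ``coefficient`` interpolates linearly
    from that level back to 1 as ``recovery_units`` approaches ``t_sum``.
    """

    coefficient: float = 1.0
    stressed_level: float = 1.0
    recovery_units: float = 0.0
    in_recovery: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.coefficient <= 1.0:
            raise ValueError("coefficient must lie in [0, 1]")
        if self.recovery_units < 0:
            raise ValueError("recovery_units must be non-negative")


def update_stress_state(
    state: StressState, t_max: float, t_mean: float, params: PastureParams
) -> StressState:
    """Advance the stress state by one day.

    A day with ``t_max`` strictly above the onset threshold deepens (or at
    least maintains) the stress level and resets the recovery accumulator.
    On stress-free days, heat units ``max(0, recovery_base - t_mean)``
    accumulate; cool days therefore recover faster and days at or above the
    recovery base contribute nothing.
    """
    if t_max > params.ht_onset:
        level = min(state.coefficient, ht_stress_coefficient(t_max, params))
        return StressState(
            coefficient=level,
            stressed_level=level,
            recovery_units=0.0,
            in_recovery=level < 1.0,
        )

    if state.stressed_level >= 1.0:
        return replace(state, in_recovery=False)

    units = min(
        params.t_sum, state.recovery_units + max(0.0, params.recovery_base - t_mean)
    )
    frac = units / params.t_sum
    if units >= params.t_sum:
        return StressState(
            coefficient=1.0, stressed_level=1.0, recovery_units=0.0, in_recovery=False
        )
    coefficient = state.stressed_level + (1.0 - state.stressed_level) * frac
    return StressState(
        coefficient=coefficient,
        stressed_level=state.stressed_level,
        recovery_units=units,
        in_recovery=True,
    )


def glf_from_water(available_water: float, pawc: float) -> float:
    """Growth-limiting factor for water: linear ramp saturating at half PAWC."""
    return min(1.0, max(0.0, available_water / (0.5 * pawc)))


@dataclass
class SoilWaterState:
    """Single-bucket soil water store with its derived limitation factor."""

    available_water: float  # mm
    pawc: float  # mm
    glf_w: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.available_water <= self.pawc:
            raise ValueError("available_water must lie in [0, pawc]")
        self.glf_w = glf_from_water(self.available_water, self.pawc)


def soil_water_step(
    state: SoilWaterState, rain: float, irrigation: float, pet: float
) -> tuple[SoilWaterState, dict[str, float]]:
    """Advance the bucket one day; returns the new state and the day's fluxes.

    Actual evapotranspiration is demand (``pet``) scaled by the start-of-day
    limitation factor and capped by the water actually present; excess over
    capacity drains.  The returned flux dictionary closes the balance
    exactly: ``delta_storage = rain + irrigation - aet - drainage``.
    """
    if rain < 0 or irrigation < 0 or pet < 0:
        raise ValueError("water fluxes must be non-negative")
    supply = state.available_water + rain + irrigation
    aet = min(pet * state.glf_w, supply)
    water = supply - aet
    drainage = max(0.0, water - state.pawc)
    water -= drainage
    new_state = SoilWaterState(available_water=water, pawc=state.pawc)
    return new_state, {"aet": aet, "drainage": drainage}


def irrigation_rule(pet_window: Sequence[float], rain_window: Sequence[float]) -> float:
    """50 mm event when the 5-day rainfall deficit strictly exceeds 25 mm.

    The deficit is cumulative PET minus cumulative rain (plus any irrigation
    already counted in ``rain_window``) over the trailing 5 days.  Windows
    shorter than 5 days early in a run never trigger.
    """
    if len(pet_window) != len(rain_window):
        raise ValueError("pet and rain windows must have equal length")
    if len(pet_window) < IRRIGATION_WINDOW:
        return 0.0
    deficit = float(np.sum(pet_window[-IRRIGATION_WINDOW:])) - float(
        np.sum(rain_window[-IRRIGATION_WINDOW:])
    )
    return IRRIGATION_AMOUNT if deficit > IRRIGATION_DEFICIT_TRIGGER else 0.0


def daily_growth(
    t_growth: float,
    glf_w: float,
    stress_coefficient: float,
    params: PastureParams,
    light_factor: float = 1.0,
) -> float:
    """Net positive photosynthesis (kg C ha-1 day-1) for one day.

    Negative net photosynthesis (respiration exceeding assimilation) is
    reported as zero, matching a net-positive growth-rate convention.
    """
    growth = (
        params.p_max
        * temperature_growth_factor(t_growth, params)
        * glf_w
        * stress_coefficient
        * light_factor
    )
    return max(0.0, growth)


def monthly_cut(biomass: float, params: PastureParams) -> tuple[float, float]:
    """Harvest down to the residual. Returns ``(harvested, residual_biomass)``."""
    if biomass < 0:
        raise ValueError("biomass must be non-negative")
    residual = min(biomass, params.residual)
    return biomass - residual, residual


def _check_contiguous(dates: pd.Series) -> None:
    dates = pd.to_datetime(dates)
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise ValueError(f"duplicate date in weather series: {dup.date()}")
    gaps = dates.diff().dropna()
    if not (gaps == pd.Timedelta(days=1)).all():
        bad = dates[1:][gaps != pd.Timedelta(days=1)].iloc[0]
        raise ValueError(f"gap in daily weather series before {bad.date()}")


def simulate(
    weather: pd.DataFrame,
    params: PastureParams,
    management: str = "rainfed",
    glf_series: Optional[Sequence[float]] = None,
    initial_water: Optional[float] = None,
) -> pd.DataFrame:
    """Run the daily growth model over a contiguous weather series.

    ``weather`` needs columns ``date``, ``tmax`` and ``tmin``; the water
    modes additionally need ``rain`` and ``pet``.  Management modes:

    - ``"rainfed"``: bucket water balance, no irrigation.
    - ``"irrigated"``: bucket plus the 50 mm deficit-triggered rule.
    - ``"forced-glf"``: GLF_W imposed directly via ``glf_series`` (chamber
      watering schedules), bucket bypassed.

    The growth-driving temperature is the daily mean ``(tmax + tmin)/2``, so
    substituting a leaf temperature for ``tmax`` propagates into both the
    stress bookkeeping and the temperature response.  Deterministic: same
    inputs give identical output.
    """
    if management not in ("rainfed", "irrigated", "forced-glf"):
        raise ValueError(f"unknown management mode {management!r}")
    required = {"date", "tmax", "tmin"}
    missing = required - set(weather.columns)
    if missing:
        raise ValueError(f"weather is missing columns: {sorted(missing)}")
    _check_contiguous(weather["date"])

    forced = management == "forced-glf"
    if forced:
        if glf_series is None:
            raise ValueError("forced-glf management requires glf_series")
        if len(glf_series) != len(weather):
            raise ValueError("glf_series length must match weather")
    else:
        for col in ("rain", "pet"):
            if col not in weather.columns:
                raise ValueError(f"water-balance modes need a {col!r} column")

    dates = pd.to_datetime(weather["date"]).reset_index(drop=True)
    stress = StressState()
    if not forced:
        start_water = params.pawc if initial_water is None else initial_water
        soil = SoilWaterState(available_water=start_water, pawc=params.pawc)
    biomass = params.initial_biomass
    pet_hist: list[float] = []
    wet_hist: list[float] = []  # rain + irrigation, for the deficit window
    deficit_carry = 0.0  # unmet deficit since the last irrigation event

    rows = []
    n = len(weather)
    for i in range(n):
        day = weather.iloc[i]
        t_max = float(day["tmax"])
        t_min = float(day["tmin"])
        t_mean = 0.5 * (t_max + t_min)

        irrigation = 0.0
        if forced:
            glf = float(glf_series[i])
            aet = drainage = 0.0
        else:
            rain = float(day["rain"])
            pet = float(day["pet"])
            pet_hist.append(pet)
            wet_hist.append(rain)
            if management == "irrigated":
                # the rolling-window rule catches sharp dry spells; the
                # carried deficit catches slow drawdown below the window's
                # trigger rate, so irrigated pastures stay unstressed
                deficit_carry = max(0.0, deficit_carry + pet - rain)
                irrigation = irrigation_rule(pet_hist[-5:], wet_hist[-5:])
                if irrigation == 0.0 and deficit_carry > IRRIGATION_DEFICIT_TRIGGER:
                    irrigation = IRRIGATION_AMOUNT
                if irrigation > 0.0:
                    deficit_carry = max(0.0, deficit_carry - irrigation)
                    wet_hist[-1] += irrigation
            soil, fluxes = soil_water_step(soil, rain, irrigation, pet)
            glf = soil.glf_w
            aet, drainage = fluxes["aet"], fluxes["drainage"]

        stress = update_stress_state(stress, t_max, t_mean, params)
        growth_c = daily_growth(t_mean, glf, stress.coefficient, params)
        growth_dm = growth_c * params.dm_per_c  # kg DM ha-1 day-1
        biomass += growth_dm / 1000.0  # t DM ha-1

        harvested = 0.0
        if dates[i].day == dates[i].days_in_month:
            harvested, biomass = monthly_cut(biomass, params)

        rows.append(
            {
                "date": dates[i],
                "tmax": t_max,
                "tmin": t_min,
                "tmean": t_mean,
                "temp_factor": temperature_growth_factor(t_mean, params),
                "glf_w": glf,
                "stress_coefficient": stress.coefficient,
                "growth_c": growth_c,
                "growth_dm": growth_dm,
                "biomass": biomass,
                "irrigation": irrigation,
                "harvested": harvested,
                "aet": aet,
                "drainage": drainage,
            }
        )
    return pd.DataFrame(rows)
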