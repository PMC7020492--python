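"""Leaf temperature from a linearized (Penman-style) leaf energy budget.

The budget balances absorbed radiation against longwave emission, sensible
heat and latent heat at the leaf surface.  Linearizing the emission and the
saturation vapor pressure around air temperature gives the closed form

    Tl = Ta + [gamma*/(s + gamma*)] * [Rni/(gHr*Cp) - D/(Pa*gamma*)]

where ``gamma* = gamma * gHr / gv`` is the apparent psychrometric constant,
``s`` the slope of the saturation mole-fraction curve, ``Rni`` the isothermal
net radiation (evaluated with the leaf at air temperature so the radiation
term is independent of the unknown), ``gHr`` the combined boundary-layer and
radiative conductance and ``gv`` the whole-leaf vapor conductance.

A full nonlinear balance solved by bracketed root finding
(:func:`energy_balance_oracle`) serves as an independent check on the
linearization; the two agree to a few tenths of a degree under the
conditions a pasture canopy experiences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

from scipy.optimize import brentq

# Physical constants (molar convention of micrometeorology texts)
CP = 29.3  # specific heat of air, J mol-1 C-1
SIGMA = 5.67e-8  # Stefan-Boltzmann, W m-2 K-4
GAMMA_SEA_LEVEL = 6.66e-4  # psychrometric constant at 101.3 kPa, C-1
LATENT_HEAT = 44_000.0  # latent heat of vaporization, J mol-1
P_STANDARD = 101.3  # kPa
KELVIN = 273.15

# Tetens-form saturation vapor pressure coefficients (kPa, deg C)
_ESAT_A = 0.611
_ESAT_B = 17.502
_ESAT_C = 240.97

# photosynthetically active radiation: ~4.6 umol photons per J for sunlight/
# broad-spectrum lamps
PAR_UMOL_PER_J = 4.6

#: below this wind speed forced-convection scaling breaks down; treated as
#: a free-convection floor
WIND_FLOOR = 0.1

Environment = Literal["chamber", "field"]


def saturation_vapor_pressure(t: float) -> float:
    """Saturation vapor pressure (kPa) at air temperature ``t`` (deg C).

    Valid between -20 and 60 deg C.
    """
    if not -20.0 <= t <= 60.0:
        raise ValueError(f"temperature {t} degC outside validity range [-20, 60]")
    return _ESAT_A * math.exp(_ESAT_B * t / (t + _ESAT_C))


def slope_s(t: float, pressure: float = P_STANDARD) -> float:
    """Slope of the saturation mole-fraction curve, ``d(esat/Pa)/dT`` (C-1)."""
    if pressure <= 0:
        raise ValueError("pressure must be positive")
    esat = saturation_vapor_pressure(t)
    desat_dt = esat * _ESAT_B * _ESAT_C / (t + _ESAT_C) ** 2
    return desat_dt / pressure


def vapor_pressure_deficit(t: float, rh: float) -> float:
    """Vapor pressure deficit (kPa) from temperature and relative humidity (%)."""
    if not 0.0 <= rh <= 100.0:
        raise ValueError(f"relative humidity {rh}% outside [0, 100]")
    return saturation_vapor_pressure(t) * (1.0 - rh / 100.0)


def boundary_layer_conductances(wind: float, d: float) -> tuple[float, float]:
    """Forced-convection boundary-layer conductances for heat and vapor.

    Returns ``(g_ha, g_va)`` in mol m-2 s-1 for a flat leaf of characteristic
    dimension ``d`` (m) in wind ``wind`` (m s-1).  The 1.4 factor converts
    laminar flat-plate theory to outdoor turbulent conditions, and the
    conductances are expressed per unit one-sided (projected) leaf area with
    exchange from both faces.  Wind speeds below :data:`WIND_FLOOR` are
    clamped to it to avoid the square-root singularity in still air.
    """
    if d <= 0:
        raise ValueError("characteristic dimension must be positive")
    if wind < 0:
        raise ValueError("wind speed must be non-negative")
    wind = max(wind, WIND_FLOOR)
    ratio = math.sqrt(wind / d)
    g_ha = 1.4 * 0.135 * ratio
    g_va = 1.4 * 0.147 * ratio
    return g_ha, g_va


def radiative_conductance(t_air: float, emissivity: float = 0.97) -> float:
    """Radiative conductance (mol m-2 s-1): longwave exchange linearized at Ta."""
    t_k = t_air + KELVIN
    return 4.0 * emissivity * SIGMA * t_k**3 / CP


@dataclass
class LeafTraits:
    """Morphological and physiological traits entering the energy budget.

    ``char_dimension`` defaults to 0.72 x the maximum leaf width measured in
    the direction of wind flow.  Grasses are amphistomatous (stomata on both
    faces); broadleaf dicots such as chicory are hypostomatous (one face), in
    which case only the abaxial term of the vapor-conductance combination is
    used.
    """

    max_leaf_width: float  # m
    arrangement: Literal["amphistomatous", "hypostomatous"] = "amphistomatous"
    char_dimension: Optional[float] = None  # m; 0.72 * width if None
    emissivity: float = 0.97
    sw_absorptivity: float = 0.5
    gs_abaxial: float = 0.4  # mol m-2 s-1
    gs_adaxial: float = 0.4

    def __post_init__(self) -> None:
        if self.max_leaf_width <= 0:
            raise ValueError("max_leaf_width must be positive")
        if self.char_dimension is None:
            self.char_dimension = 0.72 * self.max_leaf_width
        if self.char_dimension <= 0:
            raise ValueError("char_dimension must be positive")
        if not 0 < self.emissivity <= 1:
            raise ValueError("emissivity must lie in (0, 1]")
        if self.gs_abaxial < 0 or self.gs_adaxial < 0:
            raise ValueError("stomatal conductances must be non-negative")
        if self.arrangement not in ("amphistomatous", "hypostomatous"):
            raise ValueError(f"unknown stomatal arrangement {self.arrangement!r}")

    def with_conductance(self, gs: float) -> "LeafTraits":
        """Copy of these traits with both leaf faces set to conductance ``gs``."""
        return LeafTraits(
            max_leaf_width=self.max_leaf_width,
            arrangement=self.arrangement,
            char_dimension=self.char_dimension,
            emissivity=self.emissivity,
            sw_absorptivity=self.sw_absorptivity,
            gs_abaxial=gs,
            gs_adaxial=gs,
        )


@dataclass
class WeatherRecord:
    """One time step of atmospheric forcing for the leaf energy budget.

    Exactly one of ``ppfd`` (umol m-2 s-1, chamber lamps) or ``sw_radiation``
    (incident shortwave, W m-2) must be supplied.  Humidity may be given as
    relative humidity (%) or as vapor pressure (kPa); vapor pressure wins if
    both are present.
    """

    t_air: float  # deg C
    wind: float  # m s-1
    rh: Optional[float] = None  # %
    vapor_pressure: Optional[float] = None  # kPa
    ppfd: Optional[float] = None  # umol m-2 s-1
    sw_radiation: Optional[float] = None  # W m-2 incident
    pressure: float = P_STANDARD  # kPa

    def __post_init__(self) -> None:
        if (self.ppfd is None) == (self.sw_radiation is None):
            raise ValueError("exactly one of ppfd / sw_radiation is required")
        if self.rh is None and self.vapor_pressure is None:
            raise ValueError("one of rh / vapor_pressure is required")
        if self.rh is not None and not 0 <= self.rh <= 100:
            raise ValueError(f"relative humidity {self.rh}% outside [0, 100]")
        if self.wind < 0:
            raise ValueError("wind speed must be non-negative")
        if self.pressure <= 0:
            raise ValueError("pressure must be positive")

    @property
    def vpd(self) -> float:
        """Vapor pressure deficit (kPa), never negative."""
        esat = saturation_vapor_pressure(self.t_air)
        if self.vapor_pressure is not None:
            return max(0.0, esat - self.vapor_pressure)
        return vapor_pressure_deficit(self.t_air, self.rh)

    @property
    def e_air(self) -> float:
        """Ambient vapor pressure (kPa)."""
        return saturation_vapor_pressure(self.t_air) - self.vpd


@dataclass
class EnergyBudgetResult:
    """Leaf temperature together with every intermediate of the budget."""

    t_leaf: float  # deg C
    t_air: float
    s: float  # C-1
    gamma_star: float  # C-1 (inf when gv == 0)
    r_ni: float  # W m-2
    g_ha: float  # mol m-2 s-1
    g_r: float
    g_hr: float
    g_va: float
    g_v: float
    vpd: float  # kPa
    sw_abs: float  # W m-2
    lw_in: float
    lw_out_iso: float


def vapor_conductance(traits: LeafTraits, g_va: float) -> float:
    """Whole-leaf vapor conductance: stomatal and boundary layers in series.

    Each leaf face contributes half of the (one-sided) leaf area, hence the
    0.5 weights; hypostomatous leaves only transpire through the abaxial face.
    """
    if g_va < 0:
        raise ValueError("boundary-layer conductance must be non-negative")

    def series(gs: float) -> float:
        if gs == 0.0 or g_va == 0.0:
            return 0.0
        return 0.5 * gs * g_va / (gs + g_va)

    gv = series(traits.gs_abaxial)
    if traits.arrangement == "amphistomatous":
        gv += series(traits.gs_adaxial)
    return gv


def isothermal_net_radiation(
    sw_abs: float, lw_in: float, t_air: float, emissivity: float = 0.97
) -> float:
    """Net radiation with outgoing longwave evaluated at air temperature."""
    if sw_abs < 0 or lw_in < 0:
        raise ValueError("radiation fluxes must be non-negative")
    lw_out_iso = emissivity * SIGMA * (t_air + KELVIN) ** 4
    return sw_abs + lw_in - lw_out_iso


def incoming_longwave(t_air: float, environment: Environment) -> float:
    """Incoming longwave (W m-2): black chamber walls at Ta, or clear sky.

    The field form uses the clear-sky apparent emissivity
    ``eps_a = 9.2e-6 * (Ta + 273.15)**2``.
    """
    t_k = t_air + KELVIN
    if environment == "chamber":
        return SIGMA * t_k**4
    if environment == "field":
        eps_a = 9.2e-6 * t_k**2
        return eps_a * SIGMA * t_k**4
    raise ValueError(f"unknown environment {environment!r}")


def absorbed_shortwave(
    weather: WeatherRecord, traits: LeafTraits, nir_fraction: float = 0.0
) -> float:
    """Absorbed shortwave per unit one-sided leaf area (W m-2).

    Chamber PPFD is converted at 4.6 umol photons per J; ``nir_fraction``
    adds near-infrared as a multiple of the PAR energy flux (0 for
    low-NIR chamber lamps).
    """
    if weather.ppfd is not None:
        incident = weather.ppfd / PAR_UMOL_PER_J * (1.0 + nir_fraction)
    else:
        incident = weather.sw_radiation
    return traits.sw_absorptivity * incident


def _radiation_terms(
    weather: WeatherRecord,
    traits: LeafTraits,
    environment: Environment,
    nir_fraction: float,
) -> tuple[float, float, float, float]:
    sw_abs = absorbed_shortwave(weather, traits, nir_fraction)
    lw_in = incoming_longwave(weather.t_air, environment)
    lw_out_iso = traits.emissivity * SIGMA * (weather.t_air + KELVIN) ** 4
    r_ni = sw_abs + lw_in - lw_out_iso
    return sw_abs, lw_in, lw_out_iso, r_ni


def leaf_temperature(
    weather: WeatherRecord,
    traits: LeafTraits,
    environment: Environment = "chamber",
    nir_fraction: float = 0.0,
) -> EnergyBudgetResult:
    """Solve the linearized energy budget for leaf temperature.

    When the vapor conductance is zero (closed stomata and no boundary-layer
    path) the apparent psychrometric constant diverges and the budget reduces
    to the non-transpiring limit ``Tl = Ta + Rni/(gHr*Cp)``.
    """
    ta = weather.t_air
    pa = weather.pressure
    d = weather.vpd

    g_ha, g_va = boundary_layer_conductances(weather.wind, traits.char_dimension)
    g_r = radiative_conductance(ta, traits.emissivity)
    g_hr = g_ha + g_r
    g_v = vapor_conductance(traits, g_va)

    sw_abs, lw_in, lw_out_iso, r_ni = _radiation_terms(
        weather, traits, environment, nir_fraction
    )

    s = slope_s(ta, pa)
    gamma = GAMMA_SEA_LEVEL * pa / P_STANDARD

    if g_v == 0.0:
        # gamma* -> inf: no latent heat, weighting factor -> 1
        gamma_star = math.inf
        t_leaf = ta + r_ni / (g_hr * CP)
    else:
        gamma_star = gamma * g_hr / g_v
        t_leaf = ta + (gamma_star / (s + gamma_star)) * (
            r_ni / (g_hr * CP) - d / (pa * gamma_star)
        )

    return EnergyBudgetResult(
        t_leaf=t_leaf,
        t_air=ta,
        s=s,
        gamma_star=gamma_star,
        r_ni=r_ni,
        g_ha=g_ha,
        g_r=g_r,
        g_hr=g_hr,
        g_va=g_va,
        g_v=g_v,
        vpd=d,
        sw_abs=sw_abs,
        lw_in=lw_in,
        lw_out_iso=lw_out_iso,
    )


def daylength_seconds(latitude_deg: float, day_of_year: int) -> float:
    """Astronomical daylength (s) from standard solar geometry.

    Declination follows the cosine approximation with solstice offset; the
    half-day hour angle is ``arccos(-tan(phi) tan(delta))``, clipped for
    polar day/night.
    """
    phi = math.radians(latitude_deg)
    decl = math.radians(-23.45) * math.cos(2.0 * math.pi * (day_of_year + 10) / 365.0)
    x = -math.tan(phi) * math.tan(decl)
    x = min(1.0, max(-1.0, x))
    omega_s = math.acos(x)  # radians
    return (24.0 / math.pi) * omega_s * 3600.0


def midday_shortwave(daily_total_mj: float, daylength_s: float) -> float:
    """Midday irradiance (W m-2) from a daily shortwave total (MJ m-2).

    Assumes a half-sine diurnal course of irradiance over the daylight
    period, whose peak is ``total * pi / (2 * daylength)``.
    """
    if daylength_s <= 0:
        return 0.0
    return daily_total_mj * 1e6 * math.pi / (2.0 * daylength_s)


def daily_max_weather(
    t_max: float,
    radiation_mj: float,
    wind: float,
    day_of_year: int,
    latitude_deg: float,
    rh: Optional[float] = None,
    vapor_pressure: Optional[float] = None,
    pressure: float = P_STANDARD,
) -> WeatherRecord:
    """Weather record at daily-maximum conditions for field simulations.

    The field driver evaluates the energy budget once per day at the daily
    maximum temperature with midday irradiance, because only the daily
    maximum temperature is replaced by leaf temperature downstream.
    """
    sw = midday_shortwave(radiation_mj, daylength_seconds(latitude_deg, day_of_year))
    return WeatherRecord(
        t_air=t_max,
        wind=wind,
        rh=rh,
        vapor_pressure=vapor_pressure,
        sw_radiation=sw,
        pressure=pressure,
    )


def energy_balance_oracle(
    weather: WeatherRecord,
    traits: LeafTraits,
    environment: Environment = "chamber",
    nir_fraction: float = 0.0,
    bracket_halfwidth: float = 20.0,
) -> float:
    """Leaf temperature from the full nonlinear energy balance.

    Finds the root of

        f(Tl) = Rabs - eps*sigma*Tl^4 - Cp*gHa*(Tl - Ta)
                - lambda*gv*(esat(Tl) - e_air)/Pa

    by bracketed root finding on ``[Ta - 20, Ta + 20]``, where ``Rabs`` is
    total absorbed radiation (shortwave + incoming longwave).  Emission is
    kept fully nonlinear here, so no radiative conductance appears.  Raises
    if the bracket does not contain a sign change.  The residual at the
    returned root is below 1e-3 W m-2.
    """
    ta = weather.t_air
    pa = weather.pressure
    g_ha, g_va = boundary_layer_conductances(weather.wind, traits.char_dimension)
    g_v = vapor_conductance(traits, g_va)
    sw_abs, lw_in, _, _ = _radiation_terms(weather, traits, environment, nir_fraction)
    r_abs = sw_abs + lw_in
    e_air = weather.e_air

    def f(tl: float) -> float:
        emission = traits.emissivity * SIGMA * (tl + KELVIN) ** 4
        sensible = CP * g_ha * (tl - ta)
        latent = LATENT_HEAT * g_v * (saturation_vapor_pressure(tl) - e_air) / pa
        return r_abs - emission - sensible - latent

    lo, hi = ta - bracket_halfwidth, ta + bracket_halfwidth
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no sign change in bracket [{lo}, {hi}]: f(lo)={f_lo:.3g}, f(hi)={f_hi:.3g}"
        )
    root = brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16)
    assert abs(f(root)) < 1e-3
    return root
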