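"""Langmuir-method vaporization enthalpy from isothermal TGA mass loss.

Free evaporation from an open crucible follows the Langmuir relation: the
mass flux per unit area is proportional to the vapor pressure, so the
reduced flux

    nu = (1/A) * (dm/dt) * sqrt(T / M)        [(kg K mol)^(1/2) m^-2 s^-1]

is proportional to p. Combining with the Clausius-Clapeyron equation gives
a straight line

    ln nu = B - (dvapH / R) * (1/T)

whose slope yields the vaporization enthalpy at the mean temperature of
the scanned interval. The Langmuir vaporization coefficient and the
proportionality to absolute pressure are absorbed into the intercept B, so
the method is relative: it needs no pressure calibration to deliver an
enthalpy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import GAS_CONSTANT

__all__ = [
    "TgaSeries",
    "VaporizationFit",
    "langmuir_flux",
    "inverse_langmuir_rate",
    "calibrate_area",
    "fit_clausius_clapeyron",
    "fit_vaporization",
]


@dataclass(frozen=True)
class TgaSeries:
    """Isothermal mass-loss rows for one compound.

    ``temperatures`` in K (strictly increasing), ``rates`` in kg s^-1
    (positive), ``molar_mass`` in kg mol^-1. Either the crucible ``area``
    (m^2) or a pre-computed ``nu`` column must be available to obtain
    fluxes; ``masses`` (mg) are bookkeeping only.
    """

    temperatures: np.ndarray
    rates: np.ndarray
    molar_mass: float
    area: float | None = None
    nu: np.ndarray | None = None
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "rates", r)
        if self.nu is not None:
            object.__setattr__(self, "nu", np.asarray(self.nu, dtype=float))
        if t.size != r.size:
            raise ValueError("temperatures and rates must have equal length")
        if t.size < 3:
            raise ValueError("need at least 3 rows to fit")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("mass-loss rates must be positive")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")

    def fluxes(self) -> np.ndarray:
        """Langmuir fluxes nu, preferring a stored nu column over area."""
        if self.nu is not None:
            return self.nu
        if self.area is None:
            raise ValueError("series has neither a nu column nor a crucible area")
        return langmuir_flux(self.rates, self.area, self.temperatures, self.molar_mass)


@dataclass(frozen=True)
class VaporizationFit:
    """ln(nu) = intercept + slope * (1/T) least-squares result."""

    slope: float  # K
    intercept: float
    mean_temperature: float  # K, midpoint of scanned range
    enthalpy_at_Tm: float  # kJ mol^-1
    slope_standard_error: float  # K
    enthalpy_uncertainty: float  # kJ mol^-1 (k=1, slope component)
    n_points: int


def langmuir_flux(rate, area, temperature, molar_mass):
    """Reduced Langmuir flux nu = (rate/area)*sqrt(T/M); vectorized."""
    rate = np.asarray(rate, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if np.any(rate <= 0) or area <= 0 or np.any(temperature <= 0) or molar_mass <= 0:
        raise ValueError("all Langmuir-flux arguments must be positive")
    return (rate / area) * np.sqrt(temperature / molar_mass)


def inverse_langmuir_rate(nu, area, temperature, molar_mass):
    """Mass-loss rate (kg s^-1) producing flux nu at the given conditions."""
    nu = np.asarray(nu, dtype=float)
    temperature = np.asarray(temperature, dtype=float)
    if np.any(nu <= 0) or area <= 0 or np.any(temperature <= 0) or molar_mass <= 0:
        raise ValueError("all arguments must be positive")
    return nu * area / np.sqrt(temperature / molar_mass)


def calibrate_area(rate: float, temperature: float, molar_mass: float, nu: float) -> float:
    """Back out the crucible area from one (rate, T, nu) anchor row."""
    if min(rate, temperature, molar_mass, nu) <= 0:
        raise ValueError("all arguments must be positive")
    return rate * np.sqrt(temperature / molar_mass) / nu


def fit_clausius_clapeyron(inv_temperature, ln_nu) -> tuple[float, float, float]:
    """Closed-form OLS of ln(nu) on 1/T.

    Returns (slope, intercept, slope standard error). The slope standard
    error comes from the residual variance with n-2 degrees of freedom.
    """
    x = np.asarray(inv_temperature, dtype=float)
    y = np.asarray(ln_nu, dtype=float)
    if x.size != y.size:
        raise ValueError("mismatched lengths")
    if x.size < 3:
        raise ValueError("need at least 3 points to fit")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    residuals = y - (intercept + slope * x)
    sse = float(np.sum(residuals**2))
    se = np.sqrt(sse / (x.size - 2) / sxx) if x.size > 2 else 0.0
    return slope, intercept, float(se)


def fit_vaporization(
    series: TgaSeries | None = None,
    *,
    temperatures=None,
    nu=None,
    inv_temperature=None,
    ln_nu=None,
    gas_constant: float = GAS_CONSTANT,
) -> VaporizationFit:
    """Vaporization enthalpy at the mean temperature of the scan.

    Accepts a :class:`TgaSeries`, explicit ``(temperatures, nu)`` arrays,
    or pre-tabulated ``(inv_temperature, ln_nu)`` columns (used for
    bit-stable refits of published tables). The mean temperature is the
    midpoint of the scanned temperature range; the enthalpy is
    ``-slope * R / 1000`` in kJ mol^-1 and its (k=1) uncertainty is the
    slope-standard-error component ``R * se / 1000``.
    """
    if series is not None:
        temperatures = series.temperatures
        nu = series.fluxes()
    if inv_temperature is None or ln_nu is None:
        if temperatures is None or nu is None:
            raise ValueError("provide a series, (temperatures, nu), or (inv_temperature, ln_nu)")
        temperatures = np.asarray(temperatures, dtype=float)
        nu = np.asarray(nu, dtype=float)
        if np.any(nu <= 0):
            raise ValueError("fluxes must be positive to take logarithms")
        inv_temperature = 1.0 / temperatures
        ln_nu = np.log(nu)
        t_mean = float((temperatures.min() + temperatures.max()) / 2.0)
    else:
        inv_temperature = np.asarray(inv_temperature, dtype=float)
        ln_nu = np.asarray(ln_nu, dtype=float)
        t_mean = float((1.0 / inv_temperature.max() + 1.0 / inv_temperature.min()) / 2.0)

    slope, intercept, se = fit_clausius_clapeyron(inv_temperature, ln_nu)
    enthalpy = -slope * gas_constant / 1000.0
    return VaporizationFit(
        slope=slope,
        intercept=intercept,
        mean_temperature=t_mean,
        enthalpy_at_Tm=enthalpy,
        slope_standard_error=se,
        enthalpy_uncertainty=se * gas_constant / 1000.0,
        n_points=int(inv_temperature.size),
    )
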