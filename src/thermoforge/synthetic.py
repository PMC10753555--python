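"""Seeded synthetic inputs with the statistical structure each stage assumes.

The experimental training sets behind the regression results (84 ester/
coumarin values, 78 ester values, 53 aromatics) are not publicly
deposited, and raw instrument traces are not shipped with publications.
These generators stand in for them:

* group tables — integer Benson-group counts with a linear-additive
  target plus Gaussian noise, at the enthalpy magnitudes typical of the
  compound families involved (|dfH| of order 100-600 kJ mol^-1);
* TGA traces — Langmuir fluxes from a Clausius-Clapeyron vapor-pressure
  law with log-normal multiplicative noise, mass-loss rates back-computed
  through the inverse flux for a fixed crucible area;
* combustion runs — bomb records whose temperature rise is consistent
  with a known massic energy plus calorimeter noise;
* crystal sets — coumarin-style descriptors with a known 5-parameter
  linear target.

Every generator draws from its own ``numpy.random.default_rng(seed)``
stream: a fixed seed reproduces the output bit for bit and generators
never share state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .combustion import CombustionExperiment
from .crystal_model import DEFAULT_RADICAL_CODES, CoumarinDescriptor
from .regression import FeatureTable
from .tga import TgaSeries, inverse_langmuir_rate

__all__ = [
    "GroupTableTruth",
    "TgaTruth",
    "CombustionTruth",
    "CrystalTruth",
    "make_group_table",
    "make_tga_trace",
    "make_combustion_runs",
    "make_crystal_set",
]


@dataclass(frozen=True)
class GroupTableTruth:
    intercept: float
    coefficients: np.ndarray
    noise_sd: float


@dataclass(frozen=True)
class TgaTruth:
    enthalpy: float  # kJ mol^-1 at the generating temperatures
    intercept: float
    area: float
    noise_sd_ln: float


@dataclass(frozen=True)
class CombustionTruth:
    massic_energy: float  # kJ g^-1
    noise_sd: float  # kJ g^-1 equivalent scatter


@dataclass(frozen=True)
class CrystalTruth:
    intercept: float
    coefficients: np.ndarray
    noise_sd: float


def make_group_table(
    vocabulary,
    n: int = 84,
    noise_sd: float = 2.0,
    seed: int = 0,
    max_count: int = 6,
    intercept: float | None = None,
    coefficients=None,
) -> tuple[FeatureTable, GroupTableTruth]:
    """Group-count table with linear-additive targets plus Gaussian noise.

    Counts are uniform integers on [0, max_count]; unless supplied, the
    generating intercept is ~35 and coefficients are drawn on a +-100
    kJ mol^-1 scale, so targets land in the few-hundred kJ mol^-1 range
    typical of oxygenated aromatics.
    """
    vocabulary = tuple(vocabulary)
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    if noise_sd < 0 or n < 1:
        raise ValueError("invalid spec: need n >= 1 and noise_sd >= 0")
    rng = np.random.default_rng(seed)
    p = len(vocabulary)
    beta = (
        rng.uniform(-100.0, 100.0, size=p)
        if coefficients is None
        else np.asarray(coefficients, dtype=float)
    )
    b0 = 34.86 if intercept is None else float(intercept)
    X = rng.integers(0, max_count + 1, size=(n, p)).astype(float)
    y = b0 + X @ beta + rng.normal(0.0, noise_sd, size=n)
    table = FeatureTable(
        compound_ids=tuple(f"synth-{i:03d}" for i in range(n)),
        feature_names=vocabulary,
        X=X,
        y=y,
    )
    return table, GroupTableTruth(intercept=b0, coefficients=beta, noise_sd=noise_sd)


def make_tga_trace(
    enthalpy: float = 80.0,
    t_min: float = 438.15,
    t_max: float = 488.15,
    n: int = 11,
    noise_sd_ln: float = 0.01,
    seed: int = 0,
    intercept: float = 17.0,
    area: float = 2.165e-6,
    molar_mass: float = 0.190198,
) -> tuple[TgaSeries, TgaTruth]:
    """Isothermal mass-loss series following ln nu = B - dH/(R T).

    ``enthalpy`` is the generating vaporization enthalpy in kJ mol^-1
    (must be positive); multiplicative log-normal noise of s.d.
    ``noise_sd_ln`` acts on ln nu. Rates are back-computed through the
    inverse Langmuir flux at the fixed crucible area, so refitting the
    series exercises the full flux + regression path.
    """
    if enthalpy <= 0:
        raise ValueError("generating vaporization enthalpy must be positive")
    if n < 3 or t_max <= t_min:
        raise ValueError("need an increasing grid of at least 3 temperatures")
    from .constants import GAS_CONSTANT

    rng = np.random.default_rng(seed)
    T = np.linspace(t_min, t_max, n)
    ln_nu = intercept - enthalpy * 1000.0 / (GAS_CONSTANT * T)
    ln_nu = ln_nu + rng.normal(0.0, noise_sd_ln, size=n)
    nu = np.exp(ln_nu)
    rates = inverse_langmuir_rate(nu, area, T, molar_mass)
    series = TgaSeries(
        temperatures=T, rates=rates, molar_mass=molar_mass, area=area, nu=nu
    )
    return series, TgaTruth(
        enthalpy=enthalpy, intercept=intercept, area=area, noise_sd_ln=noise_sd_ln
    )


def make_combustion_runs(
    n: int = 6,
    massic_energy: float = -27.69,
    noise_sd: float = 0.01,
    seed: int = 0,
    calor_equiv: float = 1281.2,
    fuse_massic_energy: float = -16.9452,
) -> tuple[list[CombustionExperiment], CombustionTruth]:
    """Bomb records whose reduction recovers a known massic energy.

    Sample and fuse masses are drawn from semimicro-bomb ranges; the
    corrected temperature rise is solved from the energy budget so that
    the per-run massic energy equals ``massic_energy`` plus Gaussian
    scatter of s.d. ``noise_sd`` (kJ g^-1).
    """
    if massic_energy >= 0:
        raise ValueError("massic_energy must be negative (exothermic)")
    if n < 1 or noise_sd < 0:
        raise ValueError("invalid spec")
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n):
        m_sample = rng.uniform(0.030, 0.050)
        m_fuse = rng.uniform(4e-4, 8e-4)
        ignition = rng.uniform(0.003, 0.005)
        correction = rng.uniform(0.0005, 0.0012)
        cont = -rng.uniform(0.0008, 0.0014)
        massic_i = massic_energy + rng.normal(0.0, noise_sd)
        # invert the reduction chain: sample energy -> bomb-process energy -> dTc
        u_ibp = massic_i * m_sample - correction - m_fuse * (-fuse_massic_energy)
        delta_tc = -(u_ibp - cont - ignition) * 1000.0 / calor_equiv
        runs.append(
            CombustionExperiment(
                sample_mass=m_sample,
                fuse_mass=m_fuse,
                delta_Tc=delta_tc,
                calor_equiv=calor_equiv,
                cont_term=cont,
                ignition_energy=ignition,
                standard_state_correction=correction,
                fuse_massic_energy=fuse_massic_energy,
            )
        )
    return runs, CombustionTruth(massic_energy=massic_energy, noise_sd=noise_sd)


def make_crystal_set(
    n: int = 9,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 150.0,
    coefficients=(25.0, 60.0, 5.0, 8.0),
) -> tuple[list[CoumarinDescriptor], CrystalTruth]:
    """Coumarin-style descriptor sets from a known 5-parameter model."""
    if n < 5 or noise_sd < 0:
        raise ValueError("need n >= 5 and noise_sd >= 0")
    rng = np.random.default_rng(seed)
    beta = np.asarray(coefficients, dtype=float)
    radicals = list(DEFAULT_RADICAL_CODES)
    out = []
    for i in range(n):
        h = int(rng.integers(6, 13))
        o = int(rng.integers(2, 5))
        r1 = radicals[rng.integers(0, len(radicals))]
        r2 = radicals[rng.integers(0, len(radicals))]
        x = np.array([h, o, DEFAULT_RADICAL_CODES[r1], DEFAULT_RADICAL_CODES[r2]])
        target = intercept + float(x @ beta) + rng.normal(0.0, noise_sd)
        out.append(
            CoumarinDescriptor(
                compound_id=f"synth-coum-{i:02d}",
                h_count=h,
                o_count=o,
                radical_1=r1,
                radical_2=r2,
                target=target,
            )
        )
    return out, CrystalTruth(intercept=intercept, coefficients=beta, noise_sd=noise_sd)
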