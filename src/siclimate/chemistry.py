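"""Seawater carbonate chemistry, air-sea gas exchange, and climate.

The speciation closure follows the standard seawater carbonate
equilibria used throughout the long-term carbon cycle modelling
literature: total-scale dissociation constants as temperature/salinity
fits (Lueker et al. 2000 for K1/K2, Dickson 1990 for borate, Millero
1995 for water, Weiss 1974 for CO2 solubility, Mucci 1983 for calcite),
with the alkalinity balance solved for [H+] by safeguarded
Newton/Brent root finding. Carbon isotope (13C) air-sea exchange uses
the temperature-dependent equilibrium and kinetic fractionation fits of
Zhang et al. (1995).

Units at the interface: concentrations in mol m^-3, pCO2 in ppm
(numerically treated as uatm), fluxes in mol yr^-1. Internally the
constants operate on mol kg^-1 with a pinned seawater density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from scipy.optimize import brentq

#: pinned seawater density used for mol m^-3 <-> mol kg^-1 conversion
SEAWATER_DENSITY = 1025.0  # kg m^-3

#: modern seawater calcium at S=35, mol kg^-1
CALCIUM_MODERN = 0.01028

#: kinetic fractionation factor for CO2 gas transfer (Zhang et al. 1995)
ALPHA_KINETIC = 0.99912


class DegenerateChemistryError(ValueError):
    """Raised when no carbonate-system root exists in pH [2, 12]."""


@dataclass
class EquilibriumConstants:
    """Total-scale equilibrium constants at given T (degC) and S (psu).

    All in mol kg^-1 except k0 (mol kg^-1 atm^-1) and ksp_calcite
    (mol^2 kg^-2).
    """

    k1: float
    k2: float
    kb: float
    kw: float
    k0: float
    ksp_calcite: float
    boron_total: float
    temperature: float
    salinity: float


def equilibrium_constants(temperature: float, salinity: float) -> EquilibriumConstants:
    """Evaluate the pinned constant set at T (degC), S (psu)."""
    tk = temperature + 273.15
    s = salinity
    ln_tk = math.log(tk)
    sqrt_s = math.sqrt(s)

    # Lueker et al. (2000), total scale, mol/kg
    pk1 = 3633.86 / tk - 61.2172 + 9.67770 * ln_tk - 0.011555 * s + 0.0001152 * s * s
    pk2 = 471.78 / tk + 25.9290 - 3.16967 * ln_tk - 0.01781 * s + 0.0001122 * s * s
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    # Dickson (1990), total scale
    ln_kb = (
        (-8966.90 - 2890.53 * sqrt_s - 77.942 * s + 1.728 * s * sqrt_s - 0.0996 * s * s) / tk
        + 148.0248
        + 137.1942 * sqrt_s
        + 1.62142 * s
        + (-24.4344 - 25.085 * sqrt_s - 0.2474 * s) * ln_tk
        + 0.053105 * sqrt_s * tk
    )
    kb = math.exp(ln_kb)

    # Millero (1995) water dissociation
    ln_kw = (
        148.9652
        - 13847.26 / tk
        - 23.6521 * ln_tk
        + (118.67 / tk - 5.977 + 1.0495 * ln_tk) * sqrt_s
        - 0.01615 * s
    )
    kw = math.exp(ln_kw)

    # Weiss (1974) CO2 solubility, mol/kg/atm
    t100 = tk / 100.0
    ln_k0 = (
        -60.2409
        + 93.4517 / t100
        + 23.3585 * math.log(t100)
        + s * (0.023517 - 0.023656 * t100 + 0.0047036 * t100 * t100)
    )
    k0 = math.exp(ln_k0)

    # Mucci (1983) calcite stoichiometric solubility product
    log_ksp = (
        -171.9065
        - 0.077993 * tk
        + 2839.319 / tk
        + 71.595 * math.log10(tk)
        + (-0.77712 + 0.0028426 * tk + 178.34 / tk) * sqrt_s
        - 0.07711 * s
        + 0.0041249 * s * sqrt_s
    )
    ksp = 10.0 ** log_ksp

    # Uppstrom (1974) total boron
    bt = 0.0004157 * s / 35.0

    return EquilibriumConstants(
        k1=k1, k2=k2, kb=kb, kw=kw, k0=k0, ksp_calcite=ksp,
        boron_total=bt, temperature=temperature, salinity=salinity,
    )


@dataclass
class CarbonateSpeciation:
    """Result of a carbonate-system solve.

    ph is on the total scale (-log10 [H+] in mol/L); co2aq, hco3, co3
    in mol m^-3; h_conc in mM (mol m^-3); pco2 is the seawater
    equilibrium CO2 partial pressure in ppm (== uatm).
    """

    ph: float
    co2aq: float
    hco3: float
    co3: float
    omega_calcite: float
    h_conc: float
    pco2: float
    constants: EquilibriumConstants

    @property
    def dic(self) -> float:
        return self.co2aq + self.hco3 + self.co3


def _alkalinity_residual(h, dic, ta, k, include_borate, include_water):
    """TA(h) - ta, all in mol/kg. Returns (residual, d/dh residual)."""
    den = h * h + k.k1 * h + k.k1 * k.k2
    carb = dic * (k.k1 * h + 2.0 * k.k1 * k.k2) / den
    dden = 2.0 * h + k.k1
    dcarb = dic * (k.k1 * den - (k.k1 * h + 2.0 * k.k1 * k.k2) * dden) / (den * den)
    res = carb - ta
    dres = dcarb
    if include_borate:
        res += k.boron_total * k.kb / (k.kb + h)
        dres += -k.boron_total * k.kb / (k.kb + h) ** 2
    if include_water:
        res += k.kw / h - h
        dres += -k.kw / (h * h) - 1.0
    return res, dres


def solve_carbonate_system(
    dic: float,
    ta: float,
    temperature: float = 25.0,
    salinity: float = 35.0,
    calcium: float = CALCIUM_MODERN,
    include_borate: bool = True,
    include_water: bool = True,
    h_init: float | None = None,
) -> CarbonateSpeciation:
    """Solve for pH and carbonate speciation from DIC and TA.

    Parameters
    ----------
    dic, ta : float
        Dissolved inorganic carbon (mol m^-3) and total alkalinity
        (mol-eq m^-3).
    temperature : float
        In-situ temperature, degC, within [0, 60].
    salinity : float
        Practical salinity.
    calcium : float
        Seawater calcium, mol kg^-1 (modern 0.01028 at S=35).
    include_borate, include_water : bool
        Toggle the borate and water contributions to alkalinity.
    h_init : float, optional
        Warm-start [H+] guess (mol/kg) for the Newton iteration, e.g.
        from the previous integrator step.

    Raises
    ------
    DegenerateChemistryError
        If the alkalinity balance has no root within pH [2, 12].
    """
    if dic <= 0 or ta <= 0:
        raise ValueError(f"dic and ta must be positive (got dic={dic}, ta={ta})")
    if not 0.0 <= temperature <= 60.0:
        raise ValueError(f"temperature {temperature} outside [0, 60] degC")

    k = equilibrium_constants(temperature, salinity)
    dic_kg = dic / SEAWATER_DENSITY
    ta_kg = ta / SEAWATER_DENSITY

    h_lo, h_hi = 1e-12, 1e-2  # pH 12 .. 2 on the mol/kg scale
    h = h_init if h_init is not None else 1e-8

    # damped Newton with Brent fallback
    solved = False
    if h_lo < h < h_hi:
        for _ in range(50):
            res, dres = _alkalinity_residual(h, dic_kg, ta_kg, k, include_borate, include_water)
            if abs(res) < 1e-14 * max(ta_kg, 1e-6):
                solved = True
                break
            if dres == 0.0:
                break
            step = res / dres
            h_new = h - step
            if not (h_lo < h_new < h_hi):
                break
            h = h_new
    if not solved:
        r_lo, _ = _alkalinity_residual(h_lo, dic_kg, ta_kg, k, include_borate, include_water)
        r_hi, _ = _alkalinity_residual(h_hi, dic_kg, ta_kg, k, include_borate, include_water)
        if (r_lo > 0) == (r_hi > 0):
            raise DegenerateChemistryError(
                f"no carbonate-system root in pH [2, 12] for dic={dic}, ta={ta}"
            )
        h = brentq(
            lambda x: _alkalinity_residual(x, dic_kg, ta_kg, k, include_borate, include_water)[0],
            h_lo, h_hi, xtol=1e-18, rtol=8.9e-16,
        )

    den = h * h + k.k1 * h + k.k1 * k.k2
    co2_kg = dic_kg * h * h / den
    hco3_kg = dic_kg * k.k1 * h / den
    co3_kg = dic_kg * k.k1 * k.k2 / den
    omega = calcium * co3_kg / k.ksp_calcite
    h_mol_per_l = h * SEAWATER_DENSITY / 1000.0
    return CarbonateSpeciation(
        ph=-math.log10(h_mol_per_l),
        co2aq=co2_kg * SEAWATER_DENSITY,
        hco3=hco3_kg * SEAWATER_DENSITY,
        co3=co3_kg * SEAWATER_DENSITY,
        omega_calcite=omega,
        h_conc=h * SEAWATER_DENSITY,
        pco2=co2_kg / k.k0 * 1e6,
        constants=k,
    )


def gas_exchange_coefficient(
    piston_velocity: float, area: float, k0: float
) -> float:
    """Linear gas-exchange coefficient, mol yr^-1 ppm^-1.

    piston_velocity in m yr^-1, area in m^2, k0 the CO2 solubility in
    mol kg^-1 atm^-1 at surface conditions.
    """
    if piston_velocity <= 0 or area <= 0:
        raise ValueError("piston velocity and area must be positive")
    return piston_velocity * area * k0 * SEAWATER_DENSITY * 1e-6


def air_sea_co2_exchange(
    pco2_atm: float,
    speciation_surface: CarbonateSpeciation,
    piston_velocity: float,
    area: float,
) -> float:
    """Net CO2 flux into the ocean, mol C yr^-1 (positive = invasion).

    Linear in the air-sea pCO2 disequilibrium; zero when the surface
    ocean is at its equilibrium pCO2.
    """
    kg = gas_exchange_coefficient(piston_velocity, area, speciation_surface.constants.k0)
    return kg * (pco2_atm - speciation_surface.pco2)


class IsotopeFluxPair(NamedTuple):
    """Gross 13C invasion (air->sea) and evasion (sea->air) fluxes."""

    invasion: float
    evasion: float

    @property
    def net(self) -> float:
        return self.invasion - self.evasion


def eps_co2aq_gas(temperature: float) -> float:
    """Equilibrium fractionation CO2(aq)-CO2(g), permil (Zhang 1995)."""
    return 0.0049 * temperature - 1.31


def eps_hco3_gas(temperature: float) -> float:
    """Equilibrium fractionation HCO3-CO2(g), permil (Zhang 1995)."""
    return -0.1141 * temperature + 10.78


def eps_co3_gas(temperature: float) -> float:
    """Equilibrium fractionation CO3-CO2(g), permil (Zhang 1995)."""
    return -0.052 * temperature + 7.22


def eps_dic_gas(speciation: CarbonateSpeciation) -> float:
    """Speciation-weighted equilibrium fractionation DIC-CO2(g), permil."""
    t = speciation.constants.temperature
    dic = speciation.dic
    return (
        speciation.co2aq * eps_co2aq_gas(t)
        + speciation.hco3 * eps_hco3_gas(t)
        + speciation.co3 * eps_co3_gas(t)
    ) / dic


def air_sea_13c_exchange(
    atm_d13c: float,
    surface_d13c: float,
    speciation: CarbonateSpeciation,
    pco2_atm: float,
    kg: float,
    alpha_k: float = ALPHA_KINETIC,
    alpha_aq_gas: float | None = None,
    alpha_dic_gas: float | None = None,
) -> IsotopeFluxPair:
    """Gross 13C air-sea fluxes (in delta-ratio mass units, mol yr^-1).

    Uses the two-film formulation of the LOSCAR lineage: invasion is
    driven by atmospheric pCO2 and the atmospheric isotope ratio,
    evasion by the surface equilibrium pCO2 and the DIC isotope ratio
    corrected by the equilibrium DIC-gas fractionation, both scaled by
    the kinetic factor and the aqueous-gas equilibrium factor. At joint
    chemical (pCO2_atm == pCO2_surf) and isotopic
    (R_DIC == alpha_DIC-g * R_atm) equilibrium the net flux vanishes.
    Setting all alphas to 1 reduces the 13C fluxes to the 12C fluxes
    times the respective isotope ratios.
    """
    t = speciation.constants.temperature
    if alpha_aq_gas is None:
        alpha_aq_gas = 1.0 + eps_co2aq_gas(t) / 1000.0
    if alpha_dic_gas is None:
        alpha_dic_gas = 1.0 + eps_dic_gas(speciation) / 1000.0
    r_atm = 1.0 + atm_d13c / 1000.0
    r_dic = 1.0 + surface_d13c / 1000.0
    invasion = kg * alpha_k * alpha_aq_gas * pco2_atm * r_atm
    evasion = kg * alpha_k * alpha_aq_gas * speciation.pco2 * r_dic / alpha_dic_gas
    return IsotopeFluxPair(invasion=invasion, evasion=evasion)


def temperature_anomaly(
    pco2: float, pco2_background: float, climate_sensitivity: float
) -> float:
    """Warming relative to background, degC.

    dT = S * log2(pCO2 / pCO2_background), with S the equilibrium
    climate sensitivity in degC per CO2 doubling. Exactly additive over
    successive doublings.
    """
    if pco2 <= 0 or pco2_background <= 0:
        raise ValueError("pCO2 values must be positive")
    return climate_sensitivity * math.log2(pco2 / pco2_background)
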