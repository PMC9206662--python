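"""Aggregated model configuration.

Collects the two-box geometry, the flux-law constants, the carbon-cycle
bookkeeping constants and the carbonate-chemistry options into a single
ParameterSet. Defaults are the modern calibration; `permian_defaults`
switches the reverse-weathering law and biogenic silica constants to
the pre-extinction configuration.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

from .core import Geometry
from .fluxes import FluxParams


@dataclass
class CarbonParams:
    """Carbon-cycle constants outside the weathering power laws.

    Fluxes in Tmol yr^-1. The organic subcycle has equal burial and
    weathering at steady state; the export/remineralization loop is the
    biological pump that enriches deep DIC (and lowers deep pH, the
    lever on the clay saturation state).
    """

    f_volc: float = 5.0             # background volcanic degassing, Tmol C/yr
    carb_bio_export0: float = 10.0  # biogenic carbonate burial, Tmol C/yr
    k_inorg_carb: float = 0.5       # inorganic carbonate precip. scale, Tmol/yr
    carb_omega_exponent: float = 1.7
    f_org_burial: float = 10.0      # Tmol C/yr
    f_org_weathering: float = 10.0  # Tmol C/yr, equals burial at steady state
    f_org_export: float = 640.0     # Tmol C/yr surface -> deep organic rain
    d13c_volc: float = -5.0         # permil
    d13c_carbw: float = 2.0
    d13c_orgw: float = -22.0
    eps_org: float = -25.0          # photosynthetic fractionation
    piston_velocity: float = 1752.0  # m/yr (~20 cm/hr)
    climate_sensitivity: float = 3.0  # degC per CO2 doubling
    ppm_to_mol: float = 1.77e14     # atmospheric carbon mass per ppm CO2
    d13c_report_offset: float = 0.5  # carbonate-record reporting offset, permil

    def __post_init__(self) -> None:
        if self.f_org_export < self.f_org_burial:
            raise ValueError("organic export must be >= organic burial")
        for name in ("f_volc", "carb_bio_export0", "k_inorg_carb",
                     "f_org_burial", "piston_velocity", "ppm_to_mol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CarbonParams.{name} must be positive")


@dataclass
class ChemOptions:
    """Carbonate-chemistry and climate-coupling options."""

    salinity: float = 35.0
    include_borate: bool = True
    include_water: bool = True
    calcium: float = 0.01028        # mol/kg
    surface_temp_background: float = 20.0  # degC at pCO2 == pco2c
    deep_temp_offset: float = 16.0  # degC below surface
    pco2_ref_chem: float | None = None  # defaults to pco2c


@dataclass
class ParameterSet:
    """Everything needed to spin up and run the coupled model."""

    geometry: Geometry = field(default_factory=Geometry)
    fluxes: FluxParams = field(default_factory=FluxParams)
    carbon: CarbonParams = field(default_factory=CarbonParams)
    chem: ChemOptions = field(default_factory=ChemOptions)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return asdict(self)


def modern_defaults() -> ParameterSet:
    """Modern-day calibration (reproduces the present silica budget)."""
    return ParameterSet()


def permian_defaults() -> ParameterSet:
    """Pre-extinction (Permian) background configuration.

    First-order clay law (r_si = 1), glauconite-like Alk:Si, reduced
    biogenic silica uptake efficiency, and a warmer reference climate.
    """
    p = ParameterSet()
    p.fluxes = p.fluxes.with_overrides(
        r_si=1.0, r_h=1.0, alk_si=1.5, k_bsi=1.0e13, pco2c=300.0,
        n_si=0.3, n_carb=0.2, rw_offset_o=3.5,
    )
    p.chem.surface_temp_background = 22.0
    return p
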