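"""Carbon and silica flux laws.

All the parameterized fluxes of the coupled carbon-silica cycle:
pCO2-driven silicate/carbonate/quartz weathering, Michaelis-Menten
biogenic silica production, opal dissolution, the reverse-weathering
(authigenic clay) saturation law, abiotic silica precipitation, and the
alkalinity consumption that couples clay formation back to the carbon
cycle.

Fluxes are expressed in Tmol yr^-1 at this interface (the unit the
field reports budgets in); the simulator converts to mol yr^-1
internally. Dissolved
silicon concentrations are in mM (== mol m^-3), [H+] in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class FluxParams:
    """All constants of the flux laws.

    Background weathering fluxes are in Tmol yr^-1; f_silw0 equals the
    background volcanic degassing flux so that, absent reverse
    weathering, steady state sits at pCO2 = pco2c. The reverse
    weathering solubility-product constants si_o (mM) and h_o (mM) are
    tuned to reproduce the modern authigenic clay uptake flux.
    """

    # dynamic weathering
    f_silw0: float = 5.0        # Tmol Si/yr, == background volcanic degassing
    f_carbw0: float = 10.0      # Tmol C/yr
    pco2c: float = 140.0        # ppm, weathering reference
    n_si: float = 0.2
    n_carb: float = 0.1
    quartz_fraction: float = 0.19

    # constant silica inputs, Tmol Si/yr
    f_dust: float = 0.5
    f_hyd: float = 1.7
    f_mssw: float = 1.9
    f_gw: float = 0.7

    # biogenic silica (Michaelis-Menten, concentrations in uM)
    vmax: float = 1.74
    km: float = 74.48
    k_bsi: float = 3.2e14       # mol/yr proportionality constant

    # opal dissolution
    sigma_sol: float = 0.9      # mM, opal-A solubility
    rho_surface_deep: float = 5.5
    rho_sediment: float = 0.4

    # reverse weathering saturation law
    rw_offset_o: float = 1.0
    r_x: float = 1.0
    r_si: float = 3.0           # modern calibration; 1 for pre-extinction
    r_h: float = 1.0
    x_conc: float = 1.0
    x_conc_o: float = 1.0
    h_o: float = 1.9e-5         # mM
    si_o: float = 0.123         # mM
    rw_bsi_ratio: float = 0.0521  # modern F_rw / F_bSi_sed (4.7/90.2)
    alk_si: float = 0.3         # alkalinity per Si in authigenic clay
    rw_box: str = "deep"        # box supplying [Si], [H+] to the clay law

    # inorganic (abiotic) silica
    isi_threshold: float = 0.7  # mM, no abiotic silica below this
    isi_exponent: float = 1.1

    # weathering stoichiometry (Urey/Ebelmen bookkeeping)
    nu_ta_per_si: float = 2.0   # TA delivered per mol Si weathered
    nu_co2_per_si: float = 2.0  # atmospheric CO2 consumed per mol Si

    def __post_init__(self) -> None:
        for name in ("f_silw0", "f_carbw0", "f_dust", "f_hyd", "f_mssw", "f_gw",
                     "k_bsi", "vmax", "km", "sigma_sol"):
            if getattr(self, name) < 0:
                raise ValueError(f"FluxParams.{name} must be nonnegative")
        if not 0.0 < self.quartz_fraction < 1.0:
            raise ValueError("quartz_fraction must lie in (0, 1)")
        if self.rw_box not in ("deep", "surface"):
            raise ValueError("rw_box must be 'deep' or 'surface'")

    def with_overrides(self, **kwargs) -> "FluxParams":
        return replace(self, **kwargs)

    @property
    def alpha_const(self) -> float:
        """Constant proportionality term of the clay law, Tmol/yr:
        volcanic + hydrothermal + dust + marine sediment + groundwater."""
        return self.f_silw0 + self.f_hyd + self.f_dust + self.f_mssw + self.f_gw

    @property
    def ksp_rw(self) -> float:
        """Solubility product of the generic authigenic clay."""
        return (self.x_conc_o ** self.r_x) * (self.si_o ** self.r_si) / (self.h_o ** self.r_h)


def silicate_weathering(pco2: float, p: FluxParams) -> float:
    """Silicate weathering DSi flux, Tmol Si yr^-1.

    F = F0_silw * (pCO2 / pCO2c)^n_si.
    """
    if pco2 <= 0:
        raise ValueError("pco2 must be positive")
    return p.f_silw0 * (pco2 / p.pco2c) ** p.n_si


def carbonate_weathering(pco2: float, p: FluxParams) -> float:
    """Carbonate weathering carbon flux, Tmol C yr^-1."""
    if pco2 <= 0:
        raise ValueError("pco2 must be positive")
    return p.f_carbw0 * (pco2 / p.pco2c) ** p.n_carb


def quartz_weathering(f_silw: float, p: FluxParams | None = None) -> float:
    """Terrestrial SiO2 (quartz/sandstone/chert) weathering, Tmol Si yr^-1.

    A fixed fraction (default 19%) of the silicate weathering flux;
    delivers DSi only, no alkalinity.
    """
    if f_silw < 0:
        raise ValueError("f_silw must be nonnegative")
    frac = p.quartz_fraction if p is not None else 0.19
    return frac * f_silw


def bsi_production(si_surface: float, p: FluxParams) -> float:
    """Biogenic silica production, mol Si yr^-1 (note: not Tmol).

    Michaelis-Menten in surface DSi: k_bSi * Vmax*[Si]uM / (Km + [Si]uM),
    with [Si] supplied in mM and converted to uM by the factor 1000.
    """
    if si_surface < 0:
        raise ValueError("si_surface must be nonnegative")
    si_um = si_surface * 1000.0
    return p.k_bsi * p.vmax * si_um / (p.km + si_um)


def bsi_dissolution(f_in: float, si_box: float, rho: float, p: FluxParams) -> float:
    """Opal dissolution of an input bSi flux, same units as f_in.

    F_in * (1 - [Si]/sigma)^rho, clamped to zero at saturation
    ([Si] >= sigma): complete dissolution at [Si]=0, none at solubility.
    """
    if f_in < 0:
        raise ValueError("f_in must be nonnegative")
    under = 1.0 - si_box / p.sigma_sol
    if under <= 0.0:
        return 0.0
    return f_in * under ** rho


def rw_saturation(si: float, h: float, p: FluxParams) -> float:
    """Saturation state Omega of the generic authigenic clay.

    Omega = IAP / Ksp with IAP = [X]^r_x [Si]^r_si / [H+]^r_H and the
    Ksp built from the tuned reference concentrations; equals 1 at
    ([Si]_o, [H+]_o) by construction.
    """
    if si <= 0 or h <= 0:
        raise ValueError("si and h must be positive")
    iap = (p.x_conc ** p.r_x) * (si ** p.r_si) / (h ** p.r_h)
    return iap / p.ksp_rw


def reverse_weathering(si: float, h: float, f_bsi_sed: float, p: FluxParams) -> float:
    """Authigenic clay (reverse weathering) Si uptake, Tmol Si yr^-1.

    F_rw = (beta + alpha) * (Omega_rw - o), clamped at zero below the
    offset o. beta = F_bSi_sed * (modern F_rw / modern F_bSi_sed)
    couples clay formation to biogenic silica delivery to sediments;
    alpha collects the constant silica inputs.
    """
    if f_bsi_sed < 0:
        raise ValueError("f_bsi_sed must be nonnegative")
    omega = rw_saturation(si, h, p)
    beta = f_bsi_sed * p.rw_bsi_ratio
    drive = omega - p.rw_offset_o
    if drive <= 0.0:
        return 0.0
    return (beta + p.alpha_const) * drive


def inorganic_si(si_surface: float, f_bsi_sed: float, p: FluxParams) -> float:
    """Abiotic silica precipitation flux, Tmol Si yr^-1.

    (beta + alpha) * ([Si]_ssw / threshold - 1)^1.1 above the threshold
    concentration, zero below it.
    """
    if si_surface < 0 or f_bsi_sed < 0:
        raise ValueError("inputs must be nonnegative")
    drive = si_surface / p.isi_threshold - 1.0
    if drive <= 0.0:
        return 0.0
    beta = f_bsi_sed * p.rw_bsi_ratio
    return (beta + p.alpha_const) * drive ** p.isi_exponent


def rw_alkalinity_consumption(f_rw: float, p: FluxParams) -> float:
    """Alkalinity removed by clay formation, Tmol-eq yr^-1.

    Alk:Si times the reverse weathering flux; removed from the box
    where clay forms with DIC unchanged, which converts bicarbonate
    back to CO2 -- the carbon-recycling mechanism.
    """
    if f_rw < 0:
        raise ValueError("f_rw must be nonnegative")
    return p.alk_si * f_rw
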