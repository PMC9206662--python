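"""State containers for the two-box ocean + atmosphere model.

The ocean is split into a surface box (top 100 m, in contact with the
atmosphere) and a deep box. Each box carries dissolved inorganic carbon
(DIC), total alkalinity (TA), dissolved silicon (DSi) and the carbon
isotope composition of DIC. Concentrations are in mol m^-3 (numerically
equal to mM for DSi), isotope ratios in permil VPDB.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Geometry:
    """Two-box ocean geometry and exchange.

    Parameters
    ----------
    surface_depth : float
        Surface box depth in metres (default 100 m).
    ocean_area : float
        Ocean area in m^2.
    deep_volume : float
        Deep box volume in m^3.
    mixing_rate : float
        Water exchange between boxes in m^3 yr^-1.
    """

    surface_depth: float = 100.0
    ocean_area: float = 3.6e14
    deep_volume: float = 1.314e18
    mixing_rate: float = 1.9e15

    def __post_init__(self) -> None:
        for name in ("surface_depth", "ocean_area", "deep_volume", "mixing_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Geometry.{name} must be positive")
        if self.surface_volume >= self.deep_volume:
            raise ValueError("surface volume must be smaller than deep volume")

    @property
    def surface_volume(self) -> float:
        return self.surface_depth * self.ocean_area


@dataclass
class BoxState:
    """Tracer concentrations of one ocean box.

    dic, ta in mol m^-3 (mol-eq m^-3 for TA), dsi in mol m^-3 (== mM),
    d13c in permil VPDB.
    """

    dic: float
    ta: float
    dsi: float
    d13c: float = 0.0

    def __post_init__(self) -> None:
        if self.dic <= 0:
            raise ValueError("dic must be positive")
        if self.ta <= 0:
            raise ValueError("ta must be positive")
        if self.dsi < 0:
            raise ValueError("dsi must be nonnegative")
        if abs(self.d13c) >= 60:
            raise ValueError("d13c outside plausible range (|d13c| < 60 permil)")


@dataclass
class ModelState:
    """Full model state at one model time.

    pco2 is the atmospheric CO2 partial pressure in ppm; the prognostic
    variable carried by the integrator is the atmospheric carbon mass
    (1 ppm == 1.77e14 mol C, pinned in the configuration).
    """

    time: float
    pco2: float
    atm_d13c: float
    surface: BoxState
    deep: BoxState = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pco2 <= 0:
            raise ValueError("pco2 must be positive")
        if self.deep is None:
            raise ValueError("deep box state required")
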