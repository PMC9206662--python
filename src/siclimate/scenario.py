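"""Extinction scenario: phased forcing of the coupled model.

The end-Permian perturbation is prescribed in three phases following
the onset of volcanic carbon release: an initiation ramp (1e5 yr,
biological deposition declining linearly from background to the
full-extinction level), a full-extinction interval (2-7 Myr with
suppressed biogenic silica and calcite deposition), and a linear
recovery (1-6 Myr back to background). The volcanic pulse is a boxcar
release of 30,000-55,000 Pg C over 0.8e5-2.4e5 yr on top of the
background degassing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: 1 Pg C in Tmol C (1e15 g / 12.011 g/mol / 1e12)
PG_C_PER_TMOL = 83.33


@dataclass
class RwOverrides:
    """Extinction-interval reverse-weathering parameters.

    Each is phased in linearly with the extinction factor between the
    background value and this value."""

    o: float = 1.0
    r_si: float = 1.0
    r_h: float = 1.0
    alk_si: float = 1.5


@dataclass
class ExtinctionScenario:
    """Timing and intensity of the end-Permian perturbation.

    Times in years of model time; carbon_mass in Pg C. The default
    onset at 5 Myr leaves a visible pre-event baseline.
    """

    t_onset: float = 5.0e6
    initiation_duration: float = 1.0e5
    full_duration: float = 4.0e6
    recovery_duration: float = 3.0e6
    carbon_mass: float = 4.25e4        # Pg C
    release_duration: float = 1.6e5    # yr
    release_d13c: float = -15.0        # permil, coal + mantle mixture
    extinction_k_bsi: float = 0.0      # bSi rate constant at full extinction
    extinction_carb_factor: float = 0.0  # biogenic carbonate export factor
    extinction_rw: RwOverrides = field(default_factory=RwOverrides)

    def __post_init__(self) -> None:
        for name in ("initiation_duration", "full_duration", "recovery_duration",
                     "release_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ExtinctionScenario.{name} must be positive")
        if not 0.0 <= self.extinction_carb_factor <= 1.0:
            raise ValueError("extinction_carb_factor must lie in [0, 1]")
        if self.carbon_mass < 0:
            raise ValueError("carbon_mass must be nonnegative")

    @property
    def t_full_start(self) -> float:
        return self.t_onset + self.initiation_duration

    @property
    def t_recovery_start(self) -> float:
        return self.t_full_start + self.full_duration

    @property
    def t_end(self) -> float:
        return self.t_recovery_start + self.recovery_duration

    def phase_boundaries(self) -> list[float]:
        """Times where the forcing is non-smooth (for the integrator)."""
        return [
            self.t_onset,
            self.t_onset + self.release_duration,
            self.t_full_start,
            self.t_recovery_start,
            self.t_end,
        ]


def phase_factor(t: float, s: ExtinctionScenario) -> float:
    """Biological deposition factor in [0, 1].

    1 = background biology, 0 = full extinction. Linear ramps through
    the initiation and recovery phases.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t <= s.t_onset:
        return 1.0
    if t < s.t_full_start:
        return 1.0 - (t - s.t_onset) / s.initiation_duration
    if t < s.t_recovery_start:
        return 0.0
    if t < s.t_end:
        return (t - s.t_recovery_start) / s.recovery_duration
    return 1.0


def degassing_rate(t: float, s: ExtinctionScenario, f_vc_background: float = 5.0) -> float:
    """Solid-Earth + metamorphic carbon degassing, Tmol C yr^-1.

    Background plus a boxcar pulse of height carbon_mass /
    release_duration during [t_onset, t_onset + release_duration].
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    rate = f_vc_background
    if s.t_onset <= t < s.t_onset + s.release_duration:
        rate += s.carbon_mass * PG_C_PER_TMOL / s.release_duration
    return rate
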