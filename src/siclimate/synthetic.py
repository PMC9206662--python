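"""Synthetic data generators.

The real filtering target (a sea-surface-temperature proxy
compilation) and the measured sediment tables are not distributed with
this package; these generators produce synthetic stand-ins with the same
qualitative structure so that every pipeline stage can be exercised
end to end: a piecewise-linear temperature-anomaly curve (rapid >10
degC rise, multi-Myr plateau, decline), mineral-abundance tables with
a prescribed pre/post step in the clay:quartz ratio, chert-occurrence
records with an Early Triassic gap and latitude-dependent recovery,
and the printed parameter-range fixture. Every generator is a pure
function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import ParameterRanges, TemperatureTarget, default_ranges
from .minerals import AGE_BINS, CATION_BEARING_CLAYS, latitude_band
from .scenario import ExtinctionScenario, RwOverrides


@dataclass
class SyntheticSSTSpec:
    """Shape of the synthetic temperature-anomaly target curve.

    Onset at t_onset; anomaly rises by rise_magnitude over
    rise_duration, holds for plateau_duration, and declines back to the
    baseline over decline_duration. Gaussian noise of sd noise_sd is
    added pointwise when nonzero.
    """

    rise_magnitude: float = 12.0      # degC, > 10 as observed
    rise_duration: float = 1.5e5      # yr
    plateau_duration: float = 5.0e6   # yr
    decline_duration: float = 2.0e6   # yr
    noise_sd: float = 0.0             # degC
    n_points: int = 25
    seed: int = 0
    t_onset: float = 5.0e6            # yr of model time
    t_start: float = 4.0e6            # first target point
    t_end: float | None = None        # last target point

    def __post_init__(self):
        for name in ("rise_duration", "plateau_duration", "decline_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SyntheticSSTSpec.{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


def sst_curve(times: np.ndarray, spec: SyntheticSSTSpec) -> np.ndarray:
    """Noise-free piecewise-linear anomaly at the given model times."""
    t = np.asarray(times, dtype=float)
    t0 = spec.t_onset
    t1 = t0 + spec.rise_duration
    t2 = t1 + spec.plateau_duration
    t3 = t2 + spec.decline_duration
    return np.interp(t, [t0, t1, t2, t3], [0.0, spec.rise_magnitude, spec.rise_magnitude, 0.0])


def make_sst_target(spec: SyntheticSSTSpec) -> TemperatureTarget:
    """Synthetic temperature-anomaly filtering target.

    Samples the piecewise-linear curve at n_points between t_start and
    t_end (default: 1 Myr past the end of the decline), adding Gaussian
    noise when spec.noise_sd > 0; reproducible under spec.seed.
    """
    t_last = spec.t_end
    if t_last is None:
        t_last = spec.t_onset + spec.rise_duration + spec.plateau_duration \
            + spec.decline_duration + 1.0e6
    times = np.linspace(spec.t_start, t_last, spec.n_points)
    anomaly = sst_curve(times, spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        anomaly = anomaly + rng.normal(0.0, spec.noise_sd, spec.n_points)
    return TemperatureTarget(times=times, mean_anomaly=anomaly)


def make_mineral_table(
    pre_frw_range: tuple = (0.0, 0.15),
    post_frw_range: tuple = (0.15, 0.55),
    n_samples: int = 40,
    noise_sd: float = 0.0,
    seed: int = 0,
    section_id: str = "synthetic",
) -> pd.DataFrame:
    """Synthetic XRD-style mineral-abundance table.

    Half the samples sit below the extinction horizon (negative
    heights, interval 'pre') with clay:(clay+quartz) ratios drawn from
    pre_frw_range, half above ('post') from post_frw_range. Kaolinite
    and pyrite fractions are drawn independently so that the exclusion
    rules can be verified; multiplicative noise perturbs every phase
    after construction (the ratio is recovered exactly at noise_sd=0).
    """
    for name, rr in (("pre_frw_range", pre_frw_range), ("post_frw_range", post_frw_range)):
        lo, hi = rr
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"{name} must be an ordered interval in [0, 1]")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    clays = sorted(CATION_BEARING_CLAYS)
    rows = []
    n_pre = n_samples // 2
    for i in range(n_samples):
        pre = i < n_pre
        lo, hi = pre_frw_range if pre else post_frw_range
        frw = rng.uniform(lo, hi)
        height = (i - n_pre + 0.5) * 1.0  # metres relative to the horizon
        signal = rng.uniform(0.5, 0.7)    # clay + quartz mass
        kaolinite = rng.uniform(0.0, 0.15)
        pyrite = rng.uniform(0.0, 0.05)
        clay_total = frw * signal
        quartz = (1.0 - frw) * signal
        shares = rng.dirichlet(np.ones(len(clays)))
        weights = {"quartz": quartz, "kaolinite": kaolinite, "pyrite": pyrite}
        for clay, share in zip(clays, shares):
            weights[clay] = clay_total * share
        other = max(0.0, 1.0 - sum(weights.values()))
        weights["other"] = other
        if noise_sd > 0:
            for k in weights:
                weights[k] = max(0.0, weights[k] * (1.0 + rng.normal(0.0, noise_sd)))
        for mineral, wf in weights.items():
            rows.append({
                "section_id": section_id,
                "height": height,
                "interval": "pre" if pre else "post",
                "mineral": mineral,
                "weight_fraction": wf,
            })
    return pd.DataFrame(rows)


def make_chert_records(
    n_sites: int = 36,
    gap_bins: tuple = ("Griesbachian", "Dienerian", "Smithian"),
    recovery_bin_by_latitude: dict | None = None,
    seed: int = 0,
    p_chert_background: float = 0.9,
    p_chert_gap: float = 0.03,
) -> pd.DataFrame:
    """Synthetic chert-occurrence compilation with an Early Triassic gap.

    Pre-gap bins are chert-rich, gap bins chert-poor, and deposition
    resumes from a latitude-band-dependent recovery bin (high latitudes
    recover first, the tropics last -- the delayed low-latitude
    recovery pattern).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    unknown = set(gap_bins) - set(AGE_BINS)
    if unknown:
        raise ValueError(f"gap bins outside the age vocabulary: {sorted(unknown)}")
    if recovery_bin_by_latitude is None:
        recovery_bin_by_latitude = {"0-30": "Anisian", "30-60": "Spathian", "60-90": "Smithian"}
    rng = np.random.default_rng(seed)
    order = {b: i for i, b in enumerate(AGE_BINS)}
    gap_start = min(order[b] for b in gap_bins)
    rows = []
    lithologies = ("siliciclastic", "carbonate", "mixed")
    for s in range(n_sites):
        lat = float(rng.uniform(0.0, 72.0))
        band = latitude_band(lat)
        recovery = order[recovery_bin_by_latitude[band]]
        lith = lithologies[int(rng.integers(0, len(lithologies)))]
        for b in AGE_BINS:
            i = order[b]
            if i < gap_start:
                p = p_chert_background
                types = ("biogenic",) if rng.uniform() < 0.7 else ("biogenic", "nodule")
            elif i < recovery:
                p = p_chert_gap
                types = ("replacement",)
            else:
                p = p_chert_background
                types = ("biogenic",)
            bears = rng.uniform() < p
            rows.append({
                "site_id": f"site_{s:03d}",
                "age_bin": b,
                "lithology": lith,
                "paleolat_deg": lat,
                "chert_types": ";".join(types) if bears else "none",
            })
    return pd.DataFrame(rows)


def default_fixture() -> tuple[ParameterRanges, ExtinctionScenario]:
    """The shipped Monte Carlo ranges and scenario timing.

    Ranges are the published end-Permian constraints (carbon release
    30,000-55,000 Pg over 0.8e5-2.4e5 yr, climate sensitivity 2-5 degC,
    weathering exponents, clay-law and Alk:Si ranges); the scenario
    places the onset of release and extinction at 5 Myr of model time.
    """
    ranges = ParameterRanges(default_ranges())
    scenario = ExtinctionScenario(
        t_onset=5.0e6,
        initiation_duration=1.0e5,
        full_duration=4.0e6,
        recovery_duration=3.0e6,
        carbon_mass=4.25e4,
        release_duration=1.6e5,
        extinction_rw=RwOverrides(),
    )
    return ranges, scenario
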