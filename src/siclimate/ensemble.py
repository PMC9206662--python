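"""Monte Carlo ensembles: sampling, execution, filtering, summaries.

Parameters are drawn uniformly (linear or log scale) from the ranges
constrained for the end-Permian: volcanic carbon release 30,000-55,000 Pg over
0.8e5-2.4e5 yr, climate sensitivity 2-5 degC per doubling, weathering
exponents n_si 0.2-0.5 / n_carb 0.1-0.3, end-Permian biogenic silica
rate constant 1e10-7e13 (log-uniform), clay-law offset 1-7, extinction
interval clay exponents 1-6, Alk:Si 1-2 pre / 0.17-6 during the
extinction, abiotic silica threshold 0.6-0.9 mM, full-extinction
duration 2-7 Myr and recovery 1-6 Myr.

Each draw is spun up to steady state; draws whose pre-extinction
atmosphere falls outside 300-1000 ppm are redrawn (never entering the
summaries). Accepted runs are filtered against a temperature-anomaly
target curve with a +-4 degC / +-0.4 Myr tolerance box.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .params import ParameterSet, permian_defaults
from .scenario import ExtinctionScenario, RwOverrides
from .simulator import RunResult, SpinupError, run_scenario, spin_up
from . import chemistry


@dataclass(frozen=True)
class ParamRange:
    lo: float
    hi: float
    scale: str = "linear"  # or "log"

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError(f"empty range [{self.lo}, {self.hi}]")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "log" and self.lo <= 0:
            raise ValueError("log-scaled range requires positive bounds")


def default_ranges() -> dict[str, ParamRange]:
    """The sampled ranges of the end-Permian ensembles."""
    return {
        "carbon_mass": ParamRange(3.0e4, 5.5e4),            # Pg C
        "release_duration": ParamRange(0.8e5, 2.4e5),       # yr
        "climate_sensitivity": ParamRange(2.0, 5.0),        # degC/doubling
        "n_si": ParamRange(0.2, 0.5),
        "n_carb": ParamRange(0.1, 0.3),
        "k_bsi": ParamRange(1.0e10, 7.0e13, "log"),
        "rw_bsi_ratio": ParamRange(0.022, 0.099),
        "o": ParamRange(1.0, 7.0),
        "r_h_pre": ParamRange(1.0, 2.0),
        "alk_si_pre": ParamRange(1.0, 2.0),
        "r_si_ext": ParamRange(1.0, 6.0),
        "r_h_ext": ParamRange(1.0, 6.0),
        "alk_si_ext": ParamRange(0.17, 6.0),
        "isi_threshold": ParamRange(0.6, 0.9),              # mol m^-3
        "full_duration": ParamRange(2.0e6, 7.0e6),          # yr
        "recovery_duration": ParamRange(1.0e6, 6.0e6),      # yr
        "pco2c": ParamRange(150.0, 900.0, "log"),           # ppm
    }


@dataclass
class ParameterRanges:
    """Named sampling ranges; defaults are the end-Permian constraints."""

    ranges: dict[str, ParamRange] = field(default_factory=default_ranges)

    def __getitem__(self, key: str) -> ParamRange:
        return self.ranges[key]

    def names(self) -> list[str]:
        return list(self.ranges)


def sample_parameters(
    ranges: ParameterRanges | dict[str, ParamRange], n: int, seed: int
) -> pd.DataFrame:
    """n independent uniform draws of every named parameter.

    Reproducible under the seed; log-scaled ranges are sampled
    uniformly in log space.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(ranges, ParameterRanges):
        ranges = ranges.ranges
    for key, r in ranges.items():
        if not isinstance(r, ParamRange):
            raise ValueError(f"range for {key!r} is not a ParamRange")
    rng = np.random.default_rng(seed)
    cols = {}
    for key, r in ranges.items():
        if r.scale == "log":
            cols[key] = np.exp(rng.uniform(np.log(r.lo), np.log(r.hi), n))
        else:
            cols[key] = rng.uniform(r.lo, r.hi, n)
    return pd.DataFrame(cols)


def apply_draw(
    draw: pd.Series | dict,
    base: ParameterSet | None = None,
    scenario_template: ExtinctionScenario | None = None,
) -> tuple[ParameterSet, ExtinctionScenario]:
    """Materialize one parameter draw into a config + scenario.

    The clay-law offset o is a property of the clay assemblage and is
    shared between the pre-extinction background and the extinction
    interval; r_si is 1 before the extinction.
    """
    p = (base or permian_defaults()).copy()
    s = scenario_template or ExtinctionScenario()
    d = dict(draw)
    p.fluxes = p.fluxes.with_overrides(
        n_si=d.get("n_si", p.fluxes.n_si),
        n_carb=d.get("n_carb", p.fluxes.n_carb),
        k_bsi=d.get("k_bsi", p.fluxes.k_bsi),
        rw_bsi_ratio=d.get("rw_bsi_ratio", p.fluxes.rw_bsi_ratio),
        rw_offset_o=d.get("o", p.fluxes.rw_offset_o),
        r_si=1.0,
        r_h=d.get("r_h_pre", p.fluxes.r_h),
        alk_si=d.get("alk_si_pre", p.fluxes.alk_si),
        isi_threshold=d.get("isi_threshold", p.fluxes.isi_threshold),
        pco2c=d.get("pco2c", p.fluxes.pco2c),
    )
    p.carbon.climate_sensitivity = d.get(
        "climate_sensitivity", p.carbon.climate_sensitivity
    )
    scenario = replace(
        s,
        carbon_mass=d.get("carbon_mass", s.carbon_mass),
        release_duration=d.get("release_duration", s.release_duration),
        full_duration=d.get("full_duration", s.full_duration),
        recovery_duration=d.get("recovery_duration", s.recovery_duration),
        extinction_rw=RwOverrides(
            o=d.get("o", s.extinction_rw.o),
            r_si=d.get("r_si_ext", s.extinction_rw.r_si),
            r_h=d.get("r_h_ext", s.extinction_rw.r_h),
            alk_si=d.get("alk_si_ext", s.extinction_rw.alk_si),
        ),
    )
    return p, scenario


@dataclass
class EnsembleMember:
    index: int
    draw: dict
    result: RunResult
    redraws: int


@dataclass
class EnsembleResult:
    members: list[EnsembleMember]
    n_requested: int
    n_failed: int
    seed: int

    def __len__(self) -> int:
        return len(self.members)

    def draws_frame(self) -> pd.DataFrame:
        return pd.DataFrame([m.draw for m in self.members])


def _run_one(
    index: int,
    draw_row: dict,
    ranges: ParameterRanges | None,
    base: ParameterSet | None,
    scenario_template: ExtinctionScenario | None,
    dynamic_rw: bool,
    seed: int,
    max_redraws: int,
    t_end: float | None,
    n_out: int,
) -> EnsembleMember | None:
    """Spin up one draw, redrawing on a rejected background state.

    Per-member randomness is seeded from (master seed, member index) so
    results are identical however the members are scheduled.
    """
    child = np.random.default_rng(np.random.SeedSequence((seed, index)))
    draw = dict(draw_row)
    for attempt in range(max_redraws + 1):
        p, scenario = apply_draw(draw, base, scenario_template)
        try:
            sp = spin_up(p, mode="permian")
        except (SpinupError, chemistry.DegenerateChemistryError, ValueError):
            sp = None
        if sp is not None and sp.accepted:
            try:
                result = run_scenario(
                    sp, scenario, p, dynamic_rw=dynamic_rw, t_end=t_end, n_out=n_out
                )
                return EnsembleMember(index=index, draw=draw, result=result, redraws=attempt)
            except (RuntimeError, chemistry.DegenerateChemistryError, ValueError):
                pass  # recorded as a redraw; individual failures are not fatal
        if ranges is None:
            return None
        redraw_seed = int(child.integers(0, 2**31 - 1))
        draw = dict(sample_parameters(ranges, 1, redraw_seed).iloc[0])
    return None


def run_ensemble(
    draws: pd.DataFrame,
    base: ParameterSet | None = None,
    scenario_template: ExtinctionScenario | None = None,
    dynamic_rw: bool = True,
    ranges: ParameterRanges | None = None,
    seed: int = 0,
    max_redraws: int = 20,
    workers: int = 1,
    t_end: float | None = None,
    n_out: int = 600,
) -> EnsembleResult:
    """Execute one scenario run per accepted parameter draw.

    Rejected spin-ups (equilibrium pCO2 outside 300-1000 ppm, or no
    steady state) are redrawn from `ranges` up to max_redraws times;
    with ranges=None they are dropped. The result set is independent of
    the worker count.
    """
    args = [
        (i, dict(row), ranges, base, scenario_template, dynamic_rw,
         seed, max_redraws, t_end, n_out)
        for i, row in draws.reset_index(drop=True).iterrows()
    ]
    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(delayed(_run_one)(*a) for a in args)
    else:
        results = [_run_one(*a) for a in args]
    members = [m for m in results if m is not None]
    return EnsembleResult(
        members=members,
        n_requested=len(draws),
        n_failed=len(draws) - len(members),
        seed=seed,
    )


@dataclass
class TemperatureTarget:
    """Temperature-anomaly curve the ensemble is filtered against.

    times in model years (onset of carbon release at 5 Myr),
    mean_anomaly in degC. tol_temp / tol_time are the half-widths of
    the acceptance box around each target point.
    """

    times: np.ndarray
    mean_anomaly: np.ndarray
    tol_temp: float = 4.0
    tol_time: float = 4.0e5

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mean_anomaly = np.asarray(self.mean_anomaly, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.mean_anomaly.shape:
            raise ValueError("times and mean_anomaly must be matching 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("target times must be strictly increasing")
        if self.tol_temp <= 0 or self.tol_time <= 0:
            raise ValueError("tolerances must be positive")

    @classmethod
    def from_csv(cls, path, tol_temp: float = 4.0, tol_time: float = 4.0e5):
        df = pd.read_csv(path, comment="#")
        return cls(
            times=df["time_yr"].to_numpy(),
            mean_anomaly=df["temp_anomaly_C"].to_numpy(),
            tol_temp=tol_temp,
            tol_time=tol_time,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_yr": self.times, "temp_anomaly_C": self.mean_anomaly})


def run_passes_target(
    times: np.ndarray, temp_anomaly: np.ndarray, target: TemperatureTarget
) -> tuple[bool, int]:
    """Check one run against the target.

    A run passes iff for every target point some run sample within
    +-tol_time of the target time has an anomaly within +-tol_temp of
    the target mean. Returns (passed, index of first violated point or
    -1).
    """
    for i, (tt, ta) in enumerate(zip(target.times, target.mean_anomaly)):
        sel = np.abs(times - tt) <= target.tol_time
        if not np.any(sel):
            return False, i
        if not np.any(np.abs(temp_anomaly[sel] - ta) <= target.tol_temp):
            return False, i
    return True, -1


def filter_by_temperature(
    ensemble: EnsembleResult, target: TemperatureTarget
) -> tuple[list[EnsembleMember], pd.DataFrame]:
    """Split an ensemble on the temperature filter.

    Returns the accepted members and a per-run trace recording pass /
    first violated target point.
    """
    accepted = []
    trace_rows = []
    for m in ensemble.members:
        ok, first_bad = run_passes_target(m.result.times, m.result.temp_anomaly, target)
        trace_rows.append({"index": m.index, "passed": ok, "first_violated_point": first_bad})
        if ok:
            accepted.append(m)
    return accepted, pd.DataFrame(trace_rows)


ENVELOPE_QUANTILES = (2.5, 16.0, 50.0, 84.0, 97.5)

SUMMARY_VARIABLES = (
    "temp_anomaly", "pco2", "ph_surface", "si_surface", "f_bsi_export",
    "f_isi", "f_rw", "f_rw_ma", "residence_norm", "d13c_surface",
)


def _member_series(m: EnsembleMember, var: str) -> tuple[np.ndarray, np.ndarray]:
    r = m.result
    if var == "temp_anomaly":
        return r.times, r.temp_anomaly
    if var == "f_rw_ma":
        return r.times, r.f_rw_ma
    if var == "residence_norm":
        return r.times, r.residence_norm
    return r.times, r.diagnostics[var].to_numpy()


def summarize_ensemble(
    members: list[EnsembleMember],
    variables: tuple = SUMMARY_VARIABLES,
    grid: np.ndarray | None = None,
    duration_bins: np.ndarray | None = None,
    accepted_index: set | None = None,
) -> dict:
    """Percentile envelopes per output variable on a common time grid.

    Returns {'envelopes': {var: DataFrame(time, p2.5..p97.5)},
    'success_by_duration': DataFrame} -- the latter only when
    accepted_index is given (success frequency binned by the sampled
    full-extinction duration). Raises on an empty collection; an empty
    *accepted* set yields an explicit empty-summary marker.
    """
    if not members:
        raise ValueError("cannot summarize an empty ensemble")
    if grid is None:
        t_max = min(m.result.times[-1] for m in members)
        grid = np.linspace(0.0, t_max, 500)
    envelopes = {}
    for var in variables:
        mat = np.empty((len(members), len(grid)))
        for i, m in enumerate(members):
            t, v = _member_series(m, var)
            mat[i] = np.interp(grid, t, v)
        qs = np.nanpercentile(mat, ENVELOPE_QUANTILES, axis=0)
        env = pd.DataFrame({"time_yr": grid})
        for q, row in zip(ENVELOPE_QUANTILES, qs):
            env[f"p{q:g}"] = row
        envelopes[var] = env
    out: dict = {"envelopes": envelopes, "n": len(members)}
    if accepted_index is not None:
        durations = np.array([m.draw.get("full_duration", np.nan) for m in members])
        accepted = np.array([m.index in accepted_index for m in members])
        if duration_bins is None:
            duration_bins = np.linspace(2.0e6, 7.0e6, 6)
        rows = []
        for lo, hi in zip(duration_bins[:-1], duration_bins[1:]):
            sel = (durations >= lo) & (durations < hi)
            n_tot = int(sel.sum())
            n_acc = int((sel & accepted).sum())
            rows.append({
                "duration_lo": lo, "duration_hi": hi, "n": n_tot,
                "n_accepted": n_acc,
                "success_frequency": (n_acc / n_tot) if n_tot else float("nan"),
            })
        out["success_by_duration"] = pd.DataFrame(rows)
        out["empty_accepted"] = not bool(accepted.any())
    return out
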