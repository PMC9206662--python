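"""Spin-up, conservation, run diagnostics, and the two-simulation contrast."""

import math

import numpy as np
import pytest

import siclimate as sc
from siclimate.simulator import SPINUP_PCO2_WINDOW, TMOL, _step, SimContext, f_rw_ma, residence_time_norm


class TestSpinUp:
    def test_steady_state_under_further_integration(self, permian_spinup):
        """1 Myr of unforced integration leaves all tracers unchanged."""
        from scipy.integrate import solve_ivp
        from siclimate.simulator import _atol_for

        p = permian_spinup.params
        ctx = SimContext(p=p, scenario=None, dynamic_rw=True)
        y0 = permian_spinup.y
        sol = solve_ivp(
            lambda t, y: _step(t, y, ctx), (0.0, 1.0e6), y0,
            method="LSODA", rtol=1e-10, atol=_atol_for(y0),
        )
        assert sol.success
        rel = np.abs(sol.y[:7, -1] - y0[:7]) / np.abs(y0[:7])
        assert rel.max() < 1e-6

    def test_permian_acceptance_window(self, permian_spinup):
        lo, hi = SPINUP_PCO2_WINDOW
        assert lo <= permian_spinup.pco2 <= hi
        assert permian_spinup.accepted

    def test_modern_calibration_budget(self, modern_spinup):
        """The modern steady state reproduces the present silica budget:
        clay uptake 4.7 +- 2.3 and biogenic sediment export 90.2 +- 19.1
        Tmol/yr, near-preindustrial atmosphere."""
        d = modern_spinup.diag
        assert d["f_rw"] == pytest.approx(4.7, abs=2.3)
        assert d["f_bsi_sed"] == pytest.approx(90.2, abs=19.1)
        assert modern_spinup.pco2 == pytest.approx(280.0, rel=0.15)

    def test_no_rw_alkalinity_steady_state_is_pco2c(self):
        """Without clay alkalinity consumption the balance closes at
        pCO2 = pCO2c exactly."""
        p = sc.permian_defaults()
        p.fluxes = p.fluxes.with_overrides(alk_si=0.0)
        sp = sc.spin_up(p, mode="modern")
        assert sp.pco2 == pytest.approx(p.fluxes.pco2c, rel=1e-6)

    def test_rw_alkalinity_raises_steady_pco2(self, permian_spinup):
        p = permian_spinup.params
        assert permian_spinup.diag["f_rw"] > 0
        assert permian_spinup.pco2 > p.fluxes.pco2c

    def test_alk_si_monotonically_raises_steady_pco2(self):
        """Sweeping the clay Alk:Si ratio upward raises equilibrium pCO2."""
        pco2 = []
        for alk in (0.0, 0.75, 1.5):
            p = sc.permian_defaults()
            p.fluxes = p.fluxes.with_overrides(alk_si=alk)
            pco2.append(sc.spin_up(p, mode="modern").pco2)
        assert pco2[0] < pco2[1] < pco2[2]

    def test_rh_steepens_saturation_ph_dependence(self):
        """d(Omega)/d(pH) grows with the H+ exponent r_H."""
        from siclimate.fluxes import FluxParams, rw_saturation

        h1, h2 = 2.0e-5, 1.8e-5  # a pH increase
        slopes = []
        for r_h in (1.0, 2.0, 4.0):
            p = FluxParams(r_si=1.0, r_h=r_h)
            slopes.append(rw_saturation(0.15, h2, p) - rw_saturation(0.15, h1, p))
        assert slopes[0] < slopes[1] < slopes[2]


class TestDiagnostics:
    def test_f_rw_ma_arithmetic(self):
        assert f_rw_ma(5.0, 10.0, 5.0) == pytest.approx(0.25)
        assert f_rw_ma(0.0, 10.0, 5.0) == 0.0
        assert f_rw_ma(7.0, 0.0, 0.0) == pytest.approx(1.0)
        assert math.isnan(f_rw_ma(0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            f_rw_ma(-1.0, 0.0, 0.0)

    def test_residence_time_normalization(self):
        assert residence_time_norm(3.0e18, 1.5e13, 2.0e5) == pytest.approx(1.0)
        assert residence_time_norm(6.0e18, 1.5e13, 2.0e5) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            residence_time_norm(3.0e18, 0.0, 2.0e5)


class TestRunScenario:
    def test_zero_perturbation_stays_at_steady_state(self, permian_spinup):
        p = permian_spinup.params
        fl = p.fluxes
        scn = sc.ExtinctionScenario(
            carbon_mass=0.0,
            extinction_k_bsi=fl.k_bsi,
            extinction_carb_factor=1.0,
            extinction_rw=sc.RwOverrides(
                o=fl.rw_offset_o, r_si=fl.r_si, r_h=fl.r_h, alk_si=fl.alk_si
            ),
        )
        rr = sc.run_scenario(permian_spinup, scn, dynamic_rw=True, t_end=1.2e7)
        assert np.nanmax(np.abs(rr.temp_anomaly)) < 0.05
        pco2 = rr.diagnostics["pco2"].to_numpy()
        assert np.max(np.abs(pco2 - permian_spinup.pco2)) / permian_spinup.pco2 < 1e-3

    def test_conservation(self, sim1_sim2_runs):
        """Cumulative inputs-outputs match the reservoir change for C,
        Si and 13C over the whole run."""
        for rr in sim1_sim2_runs:
            assert rr.conservation_c < 1e-6
            assert rr.conservation_si < 1e-6
            assert rr.conservation_c13 < 1e-6

    def test_run_arrays_congruent(self, sim1_sim2_runs):
        for rr in sim1_sim2_runs:
            n = len(rr.times)
            assert len(rr.temp_anomaly) == n
            assert len(rr.f_rw_ma) == n
            assert len(rr.residence_norm) == n
            assert len(rr.diagnostics) == n
            assert np.all(np.diff(rr.times) > 0)
            valid = rr.f_rw_ma[~np.isnan(rr.f_rw_ma)]
            assert np.all((valid >= 0.0) & (valid <= 1.0))
            assert np.all(rr.residence_norm > 0)

    def test_sim1_temperature_relaxes_no_plateau(self, sim1_sim2_runs):
        """With frozen carbon recycling the warming decays on the
        silicate-weathering timescale: no >= 4 Myr plateau."""
        r1, _ = sim1_sim2_runs
        assert plateau_duration(r1) < 4.0e6
        late = r1.temp_anomaly[np.searchsorted(r1.times, 1.0e7)]
        assert late < 2.0

    def test_sim2_sustains_plateau_and_fluxes_rise(self, sim1_sim2_runs):
        """Dynamic clay formation holds the warmth through the
        extinction interval; clay and abiotic silica export rise to a
        plateau above background."""
        _, r2 = sim1_sim2_runs
        assert plateau_duration(r2) >= 4.0e6
        d = r2.diagnostics
        i_bg = np.searchsorted(r2.times, 4.0e6)
        i_pl = np.searchsorted(r2.times, 8.5e6)
        assert d["f_rw"][i_pl] > d["f_rw"][i_bg]
        assert d["f_isi"][i_pl] > d["f_isi"][i_bg]

    def test_sim2_exceeds_sim1_plateau_under_identical_forcing(self, sim1_sim2_runs):
        r1, r2 = sim1_sim2_runs
        assert plateau_duration(r2) > plateau_duration(r1)

    def test_surface_dsi_rises_quickly_after_onset(self, sim1_sim2_runs):
        """Dissolved silica accumulates within well under 1e5 yr of the
        extinction onset."""
        _, r2 = sim1_sim2_runs
        onset = r2.scenario.t_onset
        si0 = r2.diagnostics["si_surface"][np.searchsorted(r2.times, onset)]
        i_check = np.searchsorted(r2.times, onset + 1.0e5)
        assert r2.diagnostics["si_surface"][i_check] > si0 * 1.02

    def test_frozen_rw_flux_is_constant_in_sim1(self, sim1_sim2_runs):
        r1, _ = sim1_sim2_runs
        frw = r1.diagnostics["f_rw"].to_numpy()
        assert np.allclose(frw, frw[0])

    def test_carbonate_supersaturation_develops(self, sim1_sim2_runs):
        """Suppressed biogenic carbonate burial drives the surface
        calcite saturation state up during the extinction."""
        _, r2 = sim1_sim2_runs
        om = r2.diagnostics["omega_calcite"].to_numpy()
        i_bg = np.searchsorted(r2.times, 4.0e6)
        sel = (r2.times > 5.2e6) & (r2.times < 9.0e6)
        assert om[sel].max() > om[i_bg] * 1.5


def plateau_duration(rr, threshold_fraction=0.5) -> float:
    """Longest contiguous interval with anomaly above half its peak."""
    ta = rr.temp_anomaly
    peak = np.nanmax(ta)
    if peak <= 0:
        return 0.0
    above = ta >= threshold_fraction * peak
    best = 0.0
    start = None
    for t, flag in zip(rr.times, above):
        if flag and start is None:
            start = t
        elif not flag and start is not None:
            best = max(best, t - start)
            start = None
    if start is not None:
        best = max(best, rr.times[-1] - start)
    return best
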