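"""Carbonate-system solver, air-sea exchange, and climate law."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siclimate.chemistry import (
    CALCIUM_MODERN,
    DegenerateChemistryError,
    air_sea_13c_exchange,
    air_sea_co2_exchange,
    eps_dic_gas,
    gas_exchange_coefficient,
    solve_carbonate_system,
    temperature_anomaly,
)

from conftest import brute_force_ph, ph_molkg_to_mol_per_l


def reconstructed_ta(spec, include_borate=True, include_water=True):
    """Recompute TA (mol m^-3) from the returned speciation."""
    from siclimate.chemistry import SEAWATER_DENSITY

    k = spec.constants
    h = spec.h_conc / SEAWATER_DENSITY
    ta = (spec.hco3 + 2.0 * spec.co3) / SEAWATER_DENSITY
    if include_borate:
        ta += k.boron_total * k.kb / (k.kb + h)
    if include_water:
        ta += k.kw / h - h
    return ta * SEAWATER_DENSITY


class TestCarbonateSolver:
    def test_round_trip_identity(self):
        spec = solve_carbonate_system(2.0, 2.3, 25.0, 35.0)
        assert spec.dic == pytest.approx(2.0, rel=1e-8)
        assert reconstructed_ta(spec) == pytest.approx(2.3, rel=1e-8)

    def test_carbonate_only_alkalinity(self):
        # with borate and water disabled, TA = [HCO3] + 2[CO3] exactly
        spec = solve_carbonate_system(
            2.0, 2.0, 25.0, 35.0, include_borate=False, include_water=False
        )
        assert spec.hco3 + 2.0 * spec.co3 == pytest.approx(2.0, rel=1e-8)
        # frozen value from the 1e7-point grid oracle
        assert spec.ph == pytest.approx(7.39583, abs=2e-5)

    def test_against_bisection_oracle(self):
        # frozen from the independent grid/bisection oracle built first
        spec = solve_carbonate_system(2.0, 2.3, 25.0, 35.0)
        assert spec.ph == pytest.approx(8.03134, abs=2e-5)

    def test_high_ta_limit_is_carbonate_dominated(self):
        # TA >> 2*DIC forces all DIC into CO3; co2aq -> 0 monotonically
        specs = [solve_carbonate_system(2.0, ta, 25.0, 35.0) for ta in (4.5, 6.0, 8.0)]
        co2 = [s.co2aq for s in specs]
        assert co2[0] > co2[1] > co2[2]
        assert specs[-1].co2aq < 1e-6
        assert specs[-1].co3 / specs[-1].dic > 0.95

    def test_degenerate_chemistry_raises(self):
        with pytest.raises(DegenerateChemistryError):
            # TA so negative relative to DIC that no root lies in pH [2,12]
            solve_carbonate_system(0.001, 5e-9, 25.0, 35.0,
                                   include_borate=False, include_water=False)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            solve_carbonate_system(-1.0, 2.3)
        with pytest.raises(ValueError):
            solve_carbonate_system(2.0, 2.3, temperature=80.0)

    @given(
        dic=st.floats(1.0, 4.0),
        ta_excess=st.floats(0.05, 1.2),
        temp=st.floats(1.0, 35.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_round_trip_property(self, dic, ta_excess, temp):
        ta = dic * (1.0 + ta_excess * 0.3)
        spec = solve_carbonate_system(dic, ta, temp, 35.0)
        assert spec.dic == pytest.approx(dic, rel=1e-8)
        assert reconstructed_ta(spec) == pytest.approx(ta, rel=1e-8)
        assert spec.omega_calcite > 0

    def test_monotonicity_in_ta_and_dic(self):
        ph_up = [solve_carbonate_system(2.0, ta, 25.0, 35.0).ph for ta in (2.1, 2.2, 2.3, 2.4)]
        assert all(a < b for a, b in zip(ph_up, ph_up[1:]))
        ph_down = [solve_carbonate_system(d, 2.3, 25.0, 35.0).ph for d in (1.9, 2.0, 2.1, 2.2)]
        assert all(a > b for a, b in zip(ph_down, ph_down[1:]))

    def test_oracle_equivalence_on_random_states(self):
        # 1e6-point grid oracle on 100 random (DIC, TA) states
        rng = np.random.default_rng(12345)
        for _ in range(100):
            dic = rng.uniform(1.2, 3.5)
            ta = dic * rng.uniform(1.01, 1.25)
            temp = rng.uniform(2.0, 32.0)
            spec = solve_carbonate_system(dic, ta, temp, 35.0)
            ph_oracle = ph_molkg_to_mol_per_l(brute_force_ph(dic, ta, temp, 35.0))
            assert spec.ph == pytest.approx(ph_oracle, abs=2e-5)


class TestAirSea:
    def test_zero_at_equilibrium(self):
        spec = solve_carbonate_system(2.0, 2.3, 25.0, 35.0)
        flux = air_sea_co2_exchange(spec.pco2, spec, 3.0e4, 3.6e14)
        assert flux == pytest.approx(0.0, abs=1e-6)

    def test_linearity(self):
        spec = solve_carbonate_system(2.0, 2.3, 25.0, 35.0)
        f1 = air_sea_co2_exchange(spec.pco2 + 10.0, spec, 3.0e4, 3.6e14)
        f2 = air_sea_co2_exchange(spec.pco2 + 20.0, spec, 3.0e4, 3.6e14)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)

    def test_hand_evaluated_linear_law(self):
        spec = solve_carbonate_system(2.0, 2.3, 25.0, 35.0)
        piston, area, dpco2 = 3.0e4, 3.6e14, 50.0
        expected = piston * area * spec.constants.k0 * 1025.0 * 1e-6 * dpco2
        flux = air_sea_co2_exchange(spec.pco2 + dpco2, spec, piston, area)
        assert flux == pytest.approx(expected, rel=1e-12)


class TestAirSea13C:
    def _setup(self):
        spec = solve_carbonate_system(2.0, 2.3, 25.0, 35.0)
        kg = gas_exchange_coefficient(3.0e4, 3.6e14, spec.constants.k0)
        return spec, kg

    def test_net_zero_at_joint_equilibrium(self):
        spec, kg = self._setup()
        eps = eps_dic_gas(spec)
        atm_d13c = -7.0
        surf_d13c = (1.0 + atm_d13c / 1000.0) * (1.0 + eps / 1000.0) * 1000.0 - 1000.0
        pair = air_sea_13c_exchange(atm_d13c, surf_d13c, spec, spec.pco2, kg)
        assert pair.net == pytest.approx(0.0, abs=abs(pair.invasion) * 1e-12)

    def test_no_fractionation_limit(self):
        spec, kg = self._setup()
        pco2_atm = spec.pco2 * 1.3
        pair = air_sea_13c_exchange(
            2.0, 1.0, spec, pco2_atm, kg, alpha_k=1.0, alpha_aq_gas=1.0, alpha_dic_gas=1.0
        )
        # gross 13C fluxes reduce to 12C fluxes times the isotope ratios
        assert pair.invasion == pytest.approx(kg * pco2_atm * 1.002, rel=1e-12)
        assert pair.evasion == pytest.approx(kg * spec.pco2 * 1.001, rel=1e-12)

    def test_two_reservoir_equilibrium_offset(self):
        # steady state of a closed atmosphere+surface pair: the surface
        # DIC ends up heavier than the atmosphere by eps_DIC-gas(T)
        spec, kg = self._setup()
        eps = eps_dic_gas(spec)
        atm = -7.0
        # solve net=0 for the surface delta (closed form of the linear flux)
        a_dic = 1.0 + eps / 1000.0
        r_surf = (1.0 + atm / 1000.0) * a_dic * spec.pco2 / spec.pco2
        d_surf = (r_surf - 1.0) * 1000.0
        pair = air_sea_13c_exchange(atm, d_surf, spec, spec.pco2, kg)
        assert pair.net == pytest.approx(0.0, abs=abs(pair.invasion) * 1e-12)
        assert d_surf - atm == pytest.approx(eps * (1.0 + atm / 1000.0), rel=1e-3)
        assert 6.0 < d_surf - atm < 9.5  # ~8 permil at 25 degC


class TestTemperatureAnomaly:
    @pytest.mark.parametrize(
        "pco2, background, sens, expected",
        [
            (500.0, 500.0, 3.0, 0.0),
            (560.0, 280.0, 3.0, 3.0),
            (1120.0, 280.0, 2.5, 5.0),  # two doublings
        ],
    )
    def test_doubling_law(self, pco2, background, sens, expected):
        assert temperature_anomaly(pco2, background, sens) == pytest.approx(expected)

    @given(
        ratio1=st.floats(0.3, 8.0),
        ratio2=st.floats(0.3, 8.0),
        sens=st.floats(1.0, 6.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_exact_additivity(self, ratio1, ratio2, sens):
        base = 300.0
        total = temperature_anomaly(base * ratio1 * ratio2, base, sens)
        step = temperature_anomaly(base * ratio1, base, sens) + temperature_anomaly(
            base * ratio1 * ratio2, base * ratio1, sens
        )
        assert total == pytest.approx(step, rel=1e-12, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            temperature_anomaly(-1.0, 280.0, 3.0)
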