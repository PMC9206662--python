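"""Flux laws: hand-evaluated examples, clamps, and threshold continuity."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from siclimate.fluxes import (
    FluxParams,
    bsi_dissolution,
    bsi_production,
    carbonate_weathering,
    inorganic_si,
    quartz_weathering,
    reverse_weathering,
    rw_alkalinity_consumption,
    rw_saturation,
    silicate_weathering,
)


@pytest.fixture
def p():
    return FluxParams()


class TestWeathering:
    def test_silicate_reference_point(self, p):
        assert silicate_weathering(p.pco2c, p) == pytest.approx(p.f_silw0)

    def test_silicate_hand_value(self):
        p = FluxParams(f_silw0=5.0, pco2c=140.0, n_si=0.2)
        assert silicate_weathering(280.0, p) == pytest.approx(5.0 * 2**0.2, rel=1e-12)
        assert silicate_weathering(280.0, p) == pytest.approx(5.7435, abs=1e-4)

    def test_silicate_degenerate_exponent(self):
        p = FluxParams(n_si=0.0)
        assert silicate_weathering(100.0, p) == silicate_weathering(5000.0, p) == p.f_silw0

    def test_carbonate_reference_and_hand_value(self):
        p = FluxParams(f_carbw0=10.0, n_carb=0.1, pco2c=140.0)
        assert carbonate_weathering(p.pco2c, p) == pytest.approx(10.0)
        assert carbonate_weathering(280.0, p) == pytest.approx(10.718, abs=1e-3)

    def test_carbonate_monotone(self, p):
        vals = [carbonate_weathering(x, p) for x in (100.0, 300.0, 900.0, 2700.0)]
        assert vals == sorted(vals)

    def test_quartz_riverine_decomposition(self, p):
        # 19% of the 6.8 Tmol/yr silicate-derived flux: 1.3 quartz,
        # 8.1 total riverine, 16% quartz share
        quartz = quartz_weathering(6.8, p)
        assert quartz == pytest.approx(1.292, abs=1e-3)
        assert round(quartz, 1) == 1.3
        total = 6.8 + quartz
        assert round(total, 1) == 8.1
        assert quartz / total == pytest.approx(0.16, abs=0.005)
        assert quartz_weathering(0.0, p) == 0.0


class TestBiogenicSilica:
    def test_production_zero_and_saturation(self, p):
        assert bsi_production(0.0, p) == 0.0
        assert bsi_production(1e6, p) == pytest.approx(p.k_bsi * p.vmax, rel=1e-4)

    def test_half_saturation_identity(self):
        # [Si]*1000 == Km gives exactly half of Vmax
        p = FluxParams(k_bsi=3.0e14)
        flux = bsi_production(p.km / 1000.0, p)
        assert flux == pytest.approx(3.0e14 * 1.74 / 2.0, rel=1e-12)
        assert flux == pytest.approx(2.61e14, rel=1e-3)

    def test_dissolution_limits(self, p):
        assert bsi_dissolution(50.0, p.sigma_sol, 5.5, p) == 0.0
        assert bsi_dissolution(50.0, 0.0, 5.5, p) == pytest.approx(50.0)
        assert bsi_dissolution(50.0, 2.0 * p.sigma_sol, 5.5, p) == 0.0  # clamp

    @pytest.mark.parametrize(
        "rho, expected", [(5.5, 2.2097), (0.4, 75.786)]
    )
    def test_dissolution_hand_values(self, p, rho, expected):
        # [Si] = 0.45 = sigma/2 -> factor 0.5^rho
        assert bsi_dissolution(100.0, 0.45, rho, p) == pytest.approx(expected, abs=1e-3)

    def test_dissolution_continuous_at_saturation(self, p):
        just_below = bsi_dissolution(100.0, p.sigma_sol - 1e-9, 5.5, p)
        assert just_below == pytest.approx(0.0, abs=1e-6)


class TestReverseWeathering:
    def test_saturation_is_one_at_reference(self):
        for r_si, r_h in ((1, 1), (3, 1), (2, 4)):
            p = FluxParams(r_si=r_si, r_h=r_h)
            assert rw_saturation(p.si_o, p.h_o, p) == pytest.approx(1.0, rel=1e-12)

    def test_ksp_quotient_first_order(self):
        p = FluxParams(r_si=1.0, r_h=1.0)
        assert p.ksp_rw == pytest.approx(0.123 / 1.9e-5, rel=1e-12)
        assert p.ksp_rw == pytest.approx(6473.7, abs=0.1)

    def test_power_law_scaling(self):
        p = FluxParams(r_si=2.0, r_h=1.0)
        base = rw_saturation(0.2, 1.9e-5, p)
        assert rw_saturation(0.4, 1.9e-5, p) == pytest.approx(4.0 * base, rel=1e-12)

    def test_flux_zero_at_offset(self):
        p = FluxParams(r_si=1.0, r_h=1.0, rw_offset_o=1.0)
        assert reverse_weathering(p.si_o, p.h_o, 90.0, p) == 0.0

    def test_biogenic_term_modern_value(self):
        # beta = F_bSi_sed * (modern F_rw / modern F_bSi_sed) = 4.7 at
        # the modern biogenic silica sediment export of 90.2 Tmol/yr
        p = FluxParams(rw_bsi_ratio=4.7 / 90.2)
        beta = 90.2 * p.rw_bsi_ratio
        assert beta == pytest.approx(4.7, rel=1e-12)

    def test_hand_value(self):
        # (beta + alpha) = 15, Omega = 1.3, o = 1 -> 4.5
        p = FluxParams(r_si=1.0, r_h=1.0, rw_offset_o=1.0, rw_bsi_ratio=0.05,
                       f_silw0=5.0, f_hyd=1.7, f_dust=0.5, f_mssw=1.9, f_gw=0.7)
        si = 1.3 * p.si_o  # Omega = 1.3 with first-order law at h = h_o
        f_bsi_sed = (15.0 - p.alpha_const) / p.rw_bsi_ratio
        flux = reverse_weathering(si, p.h_o, f_bsi_sed, p)
        assert flux == pytest.approx(15.0 * 0.3, rel=1e-9)

    def test_clamped_below_offset(self):
        p = FluxParams(r_si=1.0, r_h=1.0, rw_offset_o=5.0)
        assert reverse_weathering(p.si_o, p.h_o, 90.0, p) == 0.0

    def test_continuity_at_offset(self):
        p = FluxParams(r_si=1.0, r_h=1.0, rw_offset_o=1.0)
        si = p.si_o * (1.0 + 1e-10)
        assert reverse_weathering(si, p.h_o, 90.0, p) < 1e-6


class TestInorganicSilica:
    def test_zero_at_and_below_threshold(self, p):
        assert inorganic_si(p.isi_threshold, 90.0, p) == 0.0
        assert inorganic_si(0.5 * p.isi_threshold, 90.0, p) == 0.0

    def test_double_threshold_gives_proportionality_term(self, p):
        beta = 90.0 * p.rw_bsi_ratio
        expected = beta + p.alpha_const
        assert inorganic_si(2.0 * p.isi_threshold, 90.0, p) == pytest.approx(expected)

    def test_hand_value(self):
        # beta + alpha = 20, [Si] = 1.5*threshold -> 20 * 0.5^1.1 = 9.33
        p = FluxParams(rw_bsi_ratio=0.05, f_silw0=5.0, f_hyd=1.7, f_dust=0.5,
                       f_mssw=1.9, f_gw=0.7)
        f_bsi_sed = (20.0 - p.alpha_const) / p.rw_bsi_ratio
        flux = inorganic_si(1.5 * p.isi_threshold, f_bsi_sed, p)
        assert flux == pytest.approx(20.0 * 0.5**1.1, rel=1e-9)
        assert flux == pytest.approx(9.33, abs=0.01)

    def test_continuity_at_threshold(self, p):
        assert inorganic_si(p.isi_threshold * (1 + 1e-10), 90.0, p) < 1e-6


class TestAlkalinityCoupling:
    def test_zero_ratio_decouples_carbon_cycle(self):
        p = FluxParams(alk_si=0.0)
        assert rw_alkalinity_consumption(10.0, p) == 0.0

    def test_modern_product(self):
        p = FluxParams(alk_si=0.3)
        assert rw_alkalinity_consumption(4.7, p) == pytest.approx(1.41, rel=1e-12)

    def test_berthierine_like_ratio(self):
        p = FluxParams(alk_si=4.0)
        assert rw_alkalinity_consumption(1.0, p) == pytest.approx(4.0)


@given(
    si=st.floats(0.0, 2.0),
    h=st.floats(1e-6, 1e-3),
    f_sed=st.floats(0.0, 200.0),
)
@settings(max_examples=80, deadline=None)
def test_all_removal_laws_nonnegative(si, h, f_sed):
    """After clamping, every silica removal flux is nonnegative."""
    p = FluxParams(r_si=2.0, r_h=2.0, rw_offset_o=3.0)
    assert reverse_weathering(max(si, 1e-9), h, f_sed, p) >= 0.0
    assert inorganic_si(si, f_sed, p) >= 0.0
    assert bsi_dissolution(f_sed, si, 5.5, p) >= 0.0
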