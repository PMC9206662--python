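import numpy as np
import pytest

import siclimate as sc


@pytest.fixture(scope="session")
def modern_spinup():
    """Modern-calibration steady state, shared across tests."""
    return sc.spin_up(sc.modern_defaults(), mode="modern")


@pytest.fixture(scope="session")
def permian_spinup():
    """Accepted pre-extinction steady state, shared across tests."""
    sp = sc.spin_up(sc.permian_defaults(), mode="permian")
    assert sp.accepted
    return sp


@pytest.fixture(scope="session")
def reference_scenario():
    return sc.ExtinctionScenario(
        extinction_rw=sc.RwOverrides(o=3.5, r_si=1.5, r_h=1.5, alk_si=2.0)
    )


@pytest.fixture(scope="session")
def sim1_sim2_runs(permian_spinup, reference_scenario):
    """One frozen-clay and one dynamic-clay run under identical forcing."""
    r1 = sc.run_scenario(permian_spinup, reference_scenario, dynamic_rw=False)
    r2 = sc.run_scenario(permian_spinup, reference_scenario, dynamic_rw=True)
    return r1, r2


def brute_force_ph(dic, ta, temperature=25.0, salinity=35.0,
                   include_borate=True, include_water=True, n_grid=1_000_000):
    """Independent carbonate-system oracle: pH grid search.

    Scans n_grid pH values on [2, 12] (mol/kg scale) and returns the pH
    minimizing |TA(pH) - ta|. Shares only the constant definitions with
    the solver under test, not the root-finding path.
    """
    from siclimate.chemistry import SEAWATER_DENSITY, equilibrium_constants

    k = equilibrium_constants(temperature, salinity)
    dic_kg = dic / SEAWATER_DENSITY
    ta_kg = ta / SEAWATER_DENSITY
    ph = np.linspace(2.0, 12.0, n_grid)
    h = 10.0 ** (-ph)
    den = h * h + k.k1 * h + k.k1 * k.k2
    ta_calc = dic_kg * (k.k1 * h + 2.0 * k.k1 * k.k2) / den
    if include_borate:
        ta_calc = ta_calc + k.boron_total * k.kb / (k.kb + h)
    if include_water:
        ta_calc = ta_calc + k.kw / h - h
    i = int(np.argmin(np.abs(ta_calc - ta_kg)))
    return ph[i]


def ph_molkg_to_mol_per_l(ph_molkg):
    from siclimate.chemistry import SEAWATER_DENSITY

    h_molkg = 10.0 ** (-np.asarray(ph_molkg))
    return -np.log10(h_molkg * SEAWATER_DENSITY / 1000.0)
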