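import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spo0relay.params import (KineticParameters, StrainConfig, WT,
                              DELTA_KINC, ConfigError)
from spo0relay import relay, growth_law
from spo0relay.relay import IDX, N_SPECIES


def _integrate(system, y0, t_end, rtol=1e-10, atol=1e-13):
    sol = solve_ivp(system.rhs, (0.0, t_end), y0, method="LSODA",
                    rtol=rtol, atol=atol)
    assert sol.success
    return sol


def test_zero_state_zero_production_is_fixed_point(kinetics):
    system = relay.build_reaction_system(kinetics, WT, {}, 0.0)
    rhs = system.rhs(0.0, np.zeros(N_SPECIES))
    assert np.all(rhs == 0.0)


def test_unknown_species_and_negative_rate_rejected(kinetics):
    with pytest.raises(ConfigError):
        relay.build_reaction_system(kinetics, WT, {"NotAProtein": 1.0}, 0.2)
    with pytest.raises(ConfigError):
        relay.build_reaction_system(kinetics, WT, {"KinA": -1.0}, 0.2)


def test_phosphotransfer_conserves_phosphate(rng):
    """With autophosphorylation, Spo0E catalysis, production and decay all
    off, the relay only moves phosphoryl groups around."""
    kp = KineticParameters(k_a1=0, k_a2=0, k_c1=0, k_c2=0, v_e=0)
    system = relay.build_reaction_system(kp, WT, {}, 0.0)
    y0 = rng.uniform(0.0, 2.0, N_SPECIES)
    sol = _integrate(system, y0, 20.0)
    totals = [system.phosphoryl_total(sol.y[:, k]) for k in range(sol.y.shape[1])]
    drift = (max(totals) - min(totals)) / totals[0]
    assert drift < 1e-8


def test_protein_pools_conserved_without_turnover(kinetics, rng):
    system = relay.build_reaction_system(kinetics, WT, {}, 0.0)
    y0 = rng.uniform(0.0, 2.0, N_SPECIES)
    sol = _integrate(system, y0, 10.0)
    for prot in ("KinA", "KinC", "Spo0F", "Spo0B", "Spo0A", "Spo0E"):
        start = system.protein_total(y0, prot)
        end = system.protein_total(sol.y[:, -1], prot)
        assert end == pytest.approx(start, rel=1e-8)


def test_deletion_strain_stays_deleted(kinetics):
    """dkinC: no KinC production, and zero-KinC trajectories keep KinC 0."""
    system = relay.system_at_growth_rate(kinetics, DELTA_KINC, 0.5)
    assert system.production[IDX["KinC"]] == 0.0
    y0 = system.default_initial_state()
    assert y0[IDX["KinC"]] == 0.0
    sol = _integrate(system, y0, 30.0, rtol=1e-8, atol=1e-12)
    for sp in ("KinC", "KinC~P", "KinC.Spo0F~P"):
        assert np.all(np.abs(sol.y[IDX[sp]]) < 1e-9)


def test_no_kinases_no_phosphorylation(kinetics):
    system = relay.system_at_growth_rate(
        kinetics, StrainConfig.deletion("KinA", "KinC"), 0.5)
    ss = relay.steady_state(system)
    assert relay.spo0ap_fraction(ss) == pytest.approx(0.0, abs=1e-9)


def test_monostability_across_random_initial_states(kinetics, rng):
    """Steady state is independent of the initial condition (1e-6 rel)."""
    system = relay.system_at_growth_rate(kinetics, WT, 0.4)
    ref = relay.steady_state(system)
    scale = max(ref.max(), 1.0)
    for _ in range(5):
        y0 = rng.uniform(0.0, 3.0, N_SPECIES)
        ss = relay.steady_state(system, initial=y0)
        assert np.max(np.abs(ss - ref)) / scale < 1e-6


def test_steady_state_is_a_fixed_point(kinetics):
    system = relay.system_at_growth_rate(kinetics, WT, 0.5)
    ss = relay.steady_state(system)
    sol = _integrate(system, ss, 10.0, rtol=1e-10, atol=1e-14)
    assert np.max(np.abs(sol.y[:, -1] - ss)) < 1e-6
    assert system.residual(ss) < 1e-9


def test_nonnegativity_of_trajectories(kinetics, rng):
    system = relay.system_at_growth_rate(kinetics, WT, 0.3)
    for _ in range(3):
        y0 = rng.uniform(0.0, 2.0, N_SPECIES)
        sol = _integrate(system, y0, 50.0, rtol=1e-8, atol=1e-12)
        assert sol.y.min() > -1e-9


@pytest.mark.parametrize("state_spec, expected", [
    ({"Spo0A": 1.0}, 0.0),
    ({"Spo0A~P": 1.0}, 1.0),
    ({"Spo0A": 1.0, "Spo0A~P": 1.0, "Spo0E.Spo0A~P": 1.0,
      "Spo0B.Spo0A~P": 1.0}, 0.25),
])
def test_spo0ap_fraction_arithmetic(state_spec, expected):
    y = np.zeros(N_SPECIES)
    for name, v in state_spec.items():
        y[IDX[name]] = v
    assert relay.spo0ap_fraction(y) == pytest.approx(expected)


def test_spo0ap_fraction_undefined_without_spo0a():
    with pytest.raises(relay.UndefinedFractionError):
        relay.spo0ap_fraction(np.zeros(N_SPECIES))


def test_kinc_flux_zero_without_kinc(kinetics):
    ss = relay.steady_state(relay.system_at_growth_rate(kinetics, DELTA_KINC, 0.5))
    assert relay.kinc_net_flux(ss, kinetics) == pytest.approx(0.0, abs=1e-9)


def test_kinc_flux_source_at_low_kina_sink_at_high(kinetics):
    """The hallmark of the model: KinC feeds phosphate into the relay when
    KinA is scarce and drains it when KinA is abundant."""
    def state_at(kina, kinc):
        ov = {"KinA": growth_law.kinase_production_for_concentration(kina, "KinA", 0.5),
              "KinC": growth_law.kinase_production_for_concentration(kinc, "KinC", 0.5),
              "Spo0A": 1.0, "Sda": 0.0}
        return relay.steady_state(relay.system_at_growth_rate(kinetics, None, 0.5, None, ov))

    assert relay.kinc_net_flux(state_at(0.03, 0.3), kinetics) > 0
    assert relay.kinc_net_flux(state_at(3.0, 0.3), kinetics) < 0


def test_scan_single_zero_point(kinetics):
    frac, errors = relay.scan_kinase_plane(kinetics, [0.0], [0.0])
    assert not errors
    assert frac.shape == (1, 1)
    assert frac[0, 0] == pytest.approx(0.0, abs=1e-9)


def test_scan_empty_grid_rejected(kinetics):
    with pytest.raises(ValueError):
        relay.scan_kinase_plane(kinetics, [], [1.0])


def test_scan_monotone_in_kina_at_zero_kinc(kinetics):
    frac, errors = relay.scan_kinase_plane(kinetics, [0.03, 0.3, 1.0, 3.0], [0.0])
    assert not errors
    col = frac[:, 0]
    assert np.all(np.diff(col) > 0)


def test_kinc_effect_flips_sign_with_kina(scan_rows):
    """Fraction rises with KinC at 0.03 uM KinA, falls at 3 uM KinA."""
    kinc_axis, frac = scan_rows
    low_row, high_row = frac[0], frac[1]
    assert np.all(np.diff(low_row) > 0)
    assert np.all(np.diff(high_row) < 0)


def test_source_sink_switch_in_phosphatase_variant(kinetics):
    kp = kinetics.with_variant("phosphatase")
    frac, errors = relay.scan_kinase_plane(kp, [0.03, 3.0], [0.0, 0.3, 3.0])
    assert not errors
    assert np.all(np.diff(frac[0]) > 0)
    assert np.all(np.diff(frac[1]) < 0)


def test_sda_titration_sets_free_kina():
    """Strong sequestration: active KinA ~ max(0, total KinA - total Sda)."""
    kp = KineticParameters(k_i=2e4, k_b=1e-3)
    system = relay.system_at_growth_rate(kp, WT, 0.3)
    ss = relay.steady_state(system)
    kina_total = system.protein_total(ss, "KinA")
    sda_total = system.protein_total(ss, "Sda")
    active = ss[IDX["KinA"]] + ss[IDX["KinA~P"]]
    expected = growth_law.free_kinase_titration_limit(kina_total, sda_total)
    assert active == pytest.approx(expected, rel=0.1)
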