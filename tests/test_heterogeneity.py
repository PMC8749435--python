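import numpy as np
import pandas as pd
import pytest

from spo0relay.heterogeneity import (HeterogeneityConfig,
                                     expressing_fraction,
                                     population_mean_decomposition,
                                     sample_generation_times,
                                     single_cell_population)
from spo0relay.params import WT


def test_generation_time_sampling_statistics():
    config = HeterogeneityConfig(n_cells=100_000, seed=42)
    taus = sample_generation_times(2.0, config)
    assert taus.size == 100_000
    assert taus.min() >= 0.2
    assert taus.mean() == pytest.approx(2.0, rel=0.01)
    assert taus.std() / taus.mean() == pytest.approx(0.25, rel=0.05)


def test_generation_times_truncated_at_minimum():
    config = HeterogeneityConfig(n_cells=5000, seed=1)
    taus = sample_generation_times(0.25, config)
    assert taus.size == 5000
    assert taus.min() >= 0.2


def test_tiny_cv_degenerates_to_mean():
    config = HeterogeneityConfig(cv=1e-6, n_cells=100, seed=0)
    taus = sample_generation_times(1.5, config)
    assert np.allclose(taus, 1.5, rtol=1e-4)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        sample_generation_times(-1.0, HeterogeneityConfig())
    with pytest.raises(ValueError):
        HeterogeneityConfig(cv=0.0)
    with pytest.raises(ValueError):
        HeterogeneityConfig(n_cells=0)


def test_population_is_deterministic_per_seed(kinetics):
    config = HeterogeneityConfig(n_cells=20, seed=5)
    a = single_cell_population(5.0, WT, config, kinetics)
    b = single_cell_population(5.0, WT, config, kinetics)
    pd.testing.assert_frame_equal(a, b)


def test_population_mu_consistent_with_tau(late_populations):
    for pop in late_populations.values():
        assert np.allclose(pop["mu"], np.log(2) / pop["tau_cyc"])
        assert pop["tau_cyc"].min() >= 0.2


def test_equal_growth_rates_give_equal_spo0ap(late_populations):
    """Growth-rate noise fully determines Spo0A~P: the map mu -> Spo0A~P
    is deterministic, so cells with (numerically) equal mu agree."""
    pop = late_populations["WT"].copy()
    pop["mu_key"] = pop["mu"].round(4)
    spread = pop.groupby("mu_key")["spo0ap"].agg(lambda s: s.max() - s.min())
    assert spread.max() <= 1e-12


def test_degenerate_population_equals_deterministic_prediction(kinetics):
    config = HeterogeneityConfig(cv=1e-6, n_cells=10, seed=3)
    pop = single_cell_population(5.0, WT, config, kinetics)
    assert pop["spo0ap"].std() < 1e-6 * max(pop["spo0ap"].mean(), 1e-12)


def test_kinc_deletion_raises_mean_and_variance_late(late_populations):
    """Late in starvation KinC is a net phosphate sink, so deleting it
    raises both the mean and the variance of single-cell Spo0A~P."""
    wt, dkc = late_populations["WT"], late_populations["dkinC"]
    assert dkc["spo0ap"].mean() > wt["spo0ap"].mean()
    assert dkc["spo0ap"].var() > wt["spo0ap"].var()


def test_mean_activity_paradox(late_populations):
    """Higher mean Spo0A~P in dkinC yet lower mean PtapA activity, while
    mean PspoIIG is higher: the population paradox."""
    wt, dkc = late_populations["WT"], late_populations["dkinC"]
    assert dkc["spo0ap"].mean() > wt["spo0ap"].mean()
    assert dkc["PtapA"].mean() < wt["PtapA"].mean()
    assert dkc["PspoIIG"].mean() > wt["PspoIIG"].mean()


def test_expressing_fraction_limits_and_brute_force(late_populations):
    pop = late_populations["WT"]
    assert expressing_fraction(pop, "PtapA", threshold=0.0) == pytest.approx(
        float((pop["PtapA"] > 0).mean()))
    assert expressing_fraction(pop, "PtapA", threshold=np.inf) == 0.0
    brute = sum(1 for v in pop["PtapA"] if v > 0.5) / len(pop)
    assert expressing_fraction(pop, "PtapA", threshold=0.5) == pytest.approx(brute)


def test_mean_decomposition_identity():
    pop = pd.DataFrame({
        "PtapA": [0.0, 0.0, 2.0, 4.0],
        "PtapA_expressing": [False, False, True, True],
    })
    mean_all, mean_expr, frac = population_mean_decomposition(pop, "PtapA")
    assert mean_all == pytest.approx(frac * mean_expr)
    assert frac == 0.5 and mean_expr == 3.0


def test_mean_decomposition_all_or_none():
    all_on = pd.DataFrame({"PtapA": [1.0, 2.0],
                           "PtapA_expressing": [True, True]})
    m, me, f = population_mean_decomposition(all_on, "PtapA")
    assert m == me and f == 1.0
    none = pd.DataFrame({"PtapA": [0.0, 0.0],
                         "PtapA_expressing": [False, False]})
    m, me, f = population_mean_decomposition(none, "PtapA")
    assert m == 0.0 and f == 0.0
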