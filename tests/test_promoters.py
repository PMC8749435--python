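import numpy as np
import pytest

from spo0relay.params import StrainConfig, WT, DELTA_KINA, DELTA_KINC
from spo0relay.growth import MoserParameters
from spo0relay.promoters import (HillParameters, fit_promoter_params,
                                 hill_activity, predict_activity_dynamics,
                                 repressed_activity, spo0ap_trajectory)

TIMES = np.arange(0.0, 9.01, 1.5)


@pytest.fixture(scope="module")
def hill():
    return HillParameters()


@pytest.fixture(scope="module")
def dynamics(kinetics):
    """Activity time courses for the three study strains."""
    out = {}
    for name, strain in (("WT", WT), ("dkinA", DELTA_KINA), ("dkinC", DELTA_KINC)):
        zp = spo0ap_trajectory(TIMES, strain, kinetics)
        out[name] = {
            "zp": zp,
            "PtapA": np.asarray(hill_activity(zp, HillParameters(), "PtapA")),
            "PspoIIG": np.asarray(hill_activity(zp, HillParameters(), "PspoIIG")),
        }
    return out


def test_hill_activity_zero_half_max_saturation(hill):
    assert hill_activity(0.0, hill, "PtapA") == 0.0
    assert hill_activity(hill.K_t, hill, "PtapA") == pytest.approx(hill.scale_t / 2)
    assert hill_activity(hill.K_g, hill, "PspoIIG") == pytest.approx(hill.scale_g / 2)
    assert hill_activity(1e6, hill, "PtapA") == pytest.approx(hill.scale_t, rel=1e-6)


def test_hill_activity_monotone(hill):
    x = np.linspace(0.0, 5.0, 200)
    y = np.asarray(hill_activity(x, hill, "PtapA"))
    assert np.all(np.diff(y) > 0)


def test_threshold_ordering_enforced():
    with pytest.raises(ValueError):
        HillParameters(K_t=3.0, K_g=2.5)


def test_repressed_activity_rises_then_falls(hill):
    assert repressed_activity(0.0, hill) == 0.0
    x = np.linspace(0.0, 20.0, 4001)
    y = np.asarray(repressed_activity(x, hill))
    peak = x[np.argmax(y)]
    assert hill.K_t1 < peak < hill.K_t2
    assert y[-1] < y.max() * 0.5


def test_repressed_activity_reduces_to_monotone_without_repression(hill):
    weak = HillParameters(K_t2=1e9)
    x = np.linspace(0.0, 5.0, 50)
    assert np.allclose(repressed_activity(x, weak),
                       hill_activity(x, weak, "PtapA"), rtol=1e-6)


def test_fit_recovers_hill_parameters_noise_free():
    truth = HillParameters(n_t=3.0, K_t=0.35, scale_t=2.0)
    zp = {"WT": np.linspace(0, 2.5, 20), "dkinC": np.linspace(0, 0.8, 20)}
    act = {s: np.asarray(hill_activity(z, truth, "PtapA")) for s, z in zp.items()}
    fit = fit_promoter_params(zp, act, "PtapA", seed=3)
    assert fit.params.K_t == pytest.approx(truth.K_t, rel=0.05)
    assert fit.params.scale_t == pytest.approx(truth.scale_t, rel=0.05)
    assert fit.mse < 1e-8


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fit_recovers_threshold_under_noise(seed):
    truth = HillParameters(n_t=3.0, K_t=0.35, scale_t=2.0)
    zp = {"WT": np.linspace(0, 2.5, 20), "dkinC": np.linspace(0, 0.8, 20)}
    rng = np.random.default_rng(100 + seed)
    act = {s: np.asarray(hill_activity(z, truth, "PtapA"))
           + rng.normal(0, 0.1 * truth.scale_t, 20) for s, z in zp.items()}
    fit = fit_promoter_params(zp, act, "PtapA", seed=seed)
    assert fit.params.K_t == pytest.approx(truth.K_t, rel=0.20)


def test_fit_is_deterministic_per_seed():
    truth = HillParameters()
    zp = {"WT": np.linspace(0, 3, 15)}
    act = {"WT": np.asarray(hill_activity(zp["WT"], truth, "PspoIIG"))}
    f1 = fit_promoter_params(zp, act, "PspoIIG", seed=7)
    f2 = fit_promoter_params(zp, act, "PspoIIG", seed=7)
    assert f1.params == f2.params


def test_constant_activity_flagged_unidentifiable():
    zp = {"WT": np.linspace(0, 3, 15)}
    act = {"WT": np.full(15, 0.7)}
    fit = fit_promoter_params(zp, act, "PtapA", seed=0)
    assert fit.unidentifiable


def test_spoiig_requires_kina(dynamics):
    """Sporulation reporter: ~absent in dkinA, higher in dkinC than WT late."""
    assert dynamics["dkinA"]["PspoIIG"].max() < 0.25 * dynamics["WT"]["PspoIIG"].max()
    assert dynamics["dkinC"]["PspoIIG"][-1] > dynamics["WT"]["PspoIIG"][-1]


def test_no_kinases_means_no_activity(kinetics):
    none = StrainConfig.deletion("KinA", "KinC")
    for promoter in ("PtapA", "PspoIIG"):
        act = predict_activity_dynamics(TIMES, none, promoter, kinetics=kinetics)
        assert np.max(np.abs(act)) < 1e-6


def test_monotone_readout_cannot_explain_tapa_pattern(dynamics):
    """Wherever Spo0A~P is higher in dkinC than WT, a monotone Hill map
    forces PtapA(dkinC) >= PtapA(WT): the deterministic model predicts the
    opposite of the measured population-level PtapA ordering."""
    higher = dynamics["dkinC"]["zp"] > dynamics["WT"]["zp"]
    assert higher.any()
    assert np.all(dynamics["dkinC"]["PtapA"][higher]
                  >= dynamics["WT"]["PtapA"][higher])


def test_repression_variant_gives_nonmonotone_dkinc_course(kinetics):
    """With high-Spo0A~P repression of PtapA, the dkinC time course rises
    and then falls again late in starvation."""
    act = predict_activity_dynamics(TIMES, DELTA_KINC, "PtapA",
                                    kinetics=kinetics, repressed=True)
    act = np.asarray(act)
    peak = act.argmax()
    assert 0 < peak < act.size - 1
    assert act[-1] < 0.8 * act[peak]
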