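"""Hill-function promoter read-outs of Spo0A~P and their fitting.

PtapA (biofilm matrix operon) responds to Spo0A~P at a low threshold,
PspoIIG (sporulation) at a high one:

    activity = scale * [0A~P]^n / ([0A~P]^n + K^n)

An alternative read-out adds repression of PtapA at high Spo0A~P
(activation x repression product), which makes the response
nonmonotonic.  Unknown Hill parameters are fitted to promoter-activity
time courses by a seeded particle-swarm search followed by a
derivative-free local polish, minimising the total squared error across
strains and time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .growth import MoserParameters, growth_rate_at
from .params import GrowthLawParameters, KineticParameters, StrainConfig
from . import relay

PROMOTERS = ("PtapA", "PspoIIG")


@dataclass
class HillParameters:
    """Promoter response parameters.

    K values are Spo0A~P concentrations (uM) at half-maximal activity;
    ``scale`` absorbs the proportionality constant left open by the
    activity definition.  The repression-variant fields (``n_t1``/
    ``K_t1`` activation, ``n_t2``/``K_t2`` repression) only affect
    :func:`repressed_activity`.
    """

    n_t: float = 4.0
    K_t: float = 0.2
    n_g: float = 6.0
    K_g: float = 2.5
    scale_t: float = 1.0
    scale_g: float = 1.0
    # repression variant for PtapA
    n_t1: float = 4.0
    K_t1: float = 0.2
    n_t2: float = 2.0
    K_t2: float = 4.0

    def __post_init__(self) -> None:
        for f in ("n_t", "K_t", "n_g", "K_g", "scale_t", "scale_g",
                  "n_t1", "K_t1", "n_t2", "K_t2"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be > 0")
        if not self.K_t < self.K_g:
            raise ValueError("PtapA threshold K_t must lie below PspoIIG's K_g")


def _hill(x, K, n):
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    with np.errstate(over="ignore"):
        xn = x ** n
        return xn / (xn + K ** n)


def hill_activity(spo0ap, params: HillParameters, promoter: str):
    """Monotone Hill activity of a promoter at the given Spo0A~P level."""
    if promoter == "PtapA":
        return params.scale_t * _hill(spo0ap, params.K_t, params.n_t)
    if promoter == "PspoIIG":
        return params.scale_g * _hill(spo0ap, params.K_g, params.n_g)
    raise ValueError(f"unknown promoter {promoter!r}")


def repressed_activity(spo0ap, params: HillParameters):
    """PtapA activity with additional repression at high Spo0A~P.

    activation(K_t1, n_t1) x repression(K_t2, n_t2); rises to a maximum
    between the two thresholds and falls back toward zero beyond K_t2.
    Reduces to the monotone form as K_t2 -> infinity.
    """
    x = np.maximum(np.asarray(spo0ap, dtype=float), 0.0)
    act = _hill(x, params.K_t1, params.n_t1)
    rep = params.K_t2 ** params.n_t2 / (x ** params.n_t2 + params.K_t2 ** params.n_t2)
    return params.scale_t * act * rep


# ---------------------------------------------------------------------------
# prediction through the quasi-steady-state chain


def spo0ap_trajectory(times,
                      strain: StrainConfig,
                      kinetics: KineticParameters | None = None,
                      moser: MoserParameters | None = None,
                      law: GrowthLawParameters | None = None,
                      tol: float = 1e-9) -> np.ndarray:
    """Spo0A~P concentration over time via mu(t) -> relay steady state."""
    kinetics = kinetics or KineticParameters()
    moser = moser or MoserParameters()
    times = np.asarray(times, dtype=float)
    mus = np.atleast_1d(growth_rate_at(moser, times))
    out = np.empty(times.size)
    cache: dict = {}
    for i, mu in enumerate(mus):
        key = round(float(mu), 6)
        if key not in cache:
            system = relay.system_at_growth_rate(kinetics, strain, key, law)
            cache[key] = relay.steady_state(system, tol=tol)[relay.IDX["Spo0A~P"]]
        out[i] = cache[key]
    return out


def predict_activity_dynamics(times,
                              strain: StrainConfig,
                              promoter: str,
                              hill: HillParameters | None = None,
                              kinetics: KineticParameters | None = None,
                              moser: MoserParameters | None = None,
                              law: GrowthLawParameters | None = None,
                              repressed: bool = False) -> np.ndarray:
    """Promoter-activity time course for a strain (QSS chain).

    Chains the fitted growth model (mu at each time), the phosphorelay
    steady state at that growth rate, and the Hill read-out.
    """
    hill = hill or HillParameters()
    zp = spo0ap_trajectory(times, strain, kinetics, moser, law)
    if repressed and promoter == "PtapA":
        return repressed_activity(zp, hill)
    return hill_activity(zp, hill, promoter)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PromoterFit:
    params: HillParameters
    mse: float
    promoter: str
    unidentifiable: bool = False
    seed: int = 0


def _pso(loss, lo, hi, seed, n_particles=24, n_iter=60):
    """Minimal seeded particle-swarm global search over a box."""
    rng = np.random.default_rng(seed)
    dim = lo.size
    x = lo + (hi - lo) * rng.random((n_particles, dim))
    v = 0.1 * (hi - lo) * rng.standard_normal((n_particles, dim))
    pbest = x.copy()
    pval = np.array([loss(xi) for xi in x])
    g = pbest[np.argmin(pval)].copy()
    gval = pval.min()
    for _ in range(n_iter):
        r1 = rng.random((n_particles, dim))
        r2 = rng.random((n_particles, dim))
        v = 0.72 * v + 1.5 * r1 * (pbest - x) + 1.5 * r2 * (g - x)
        x = np.clip(x + v, lo, hi)
        val = np.array([loss(xi) for xi in x])
        better = val < pval
        pbest[better] = x[better]
        pval[better] = val[better]
        if pval.min() < gval:
            gval = pval.min()
            g = pbest[np.argmin(pval)].copy()
    return g, gval


def fit_promoter_params(spo0ap_by_strain: dict,
                        activity_by_strain: dict,
                        promoter: str,
                        seed: int = 0,
                        bounds: dict | None = None) -> PromoterFit:
    """Fit (n, K, scale) of one promoter to activity time courses.

    ``spo0ap_by_strain`` maps strain name -> Spo0A~P trajectory (uM) and
    ``activity_by_strain`` maps the same names -> measured activities on
    the same time points.  All strains enter one unweighted
    sum-of-squares loss.  The search is a particle swarm followed by a
    Nelder-Mead polish; deterministic for a fixed seed.
    """
    if promoter not in PROMOTERS:
        raise ValueError(f"unknown promoter {promoter!r}")
    strains = sorted(spo0ap_by_strain)
    if strains != sorted(activity_by_strain):
        raise ValueError("strain keys of trajectories and measurements differ")
    zp = {s: np.asarray(spo0ap_by_strain[s], float) for s in strains}
    act = {s: np.asarray(activity_by_strain[s], float) for s in strains}
    for s in strains:
        if zp[s].shape != act[s].shape:
            raise ValueError(f"shape mismatch for strain {s}")

    all_act = np.concatenate([act[s] for s in strains])
    unident = np.ptp(all_act) < 1e-12 * max(1.0, np.abs(all_act).max())

    default_bounds = {"n": (0.5, 8.0), "K": (0.01, 20.0),
                      "scale": (1e-6, 10.0 * max(all_act.max(), 1e-9))}
    b = {**default_bounds, **(bounds or {})}
    lo = np.array([b["n"][0], np.log(b["K"][0]), np.log(b["scale"][0])])
    hi = np.array([b["n"][1], np.log(b["K"][1]), np.log(b["scale"][1])])

    def loss(x):
        n, K, scale = x[0], np.exp(x[1]), np.exp(x[2])
        total = 0.0
        for s in strains:
            pred = scale * _hill(zp[s], K, n)
            total += float(np.sum((pred - act[s]) ** 2))
        return total

    g, gval = _pso(loss, lo, hi, seed)
    res = minimize(loss, g, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
    x = res.x if res.fun <= gval else g
    n, K, scale = float(x[0]), float(np.exp(x[1])), float(np.exp(x[2]))

    hp = HillParameters()
    if promoter == "PtapA":
        hp = replace(hp, n_t=n, K_t=min(K, hp.K_g * 0.999), scale_t=scale)
    else:
        hp = replace(hp, n_g=n, K_g=max(K, hp.K_t * 1.001), scale_g=scale)
    npts = sum(a.size for a in act.values())
    mse = min(res.fun, gval) / npts
    return PromoterFit(params=hp, mse=float(mse), promoter=promoter,
                       unidentifiable=bool(unident), seed=seed)
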