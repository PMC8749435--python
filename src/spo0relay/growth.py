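"""Moser-type batch-growth model: simulation, OD-curve fitting, mu(t).

Cell density C (measured as OD600) grows on a normalised nutrient pool N
with a Hill-type specific growth rate and declines through a second
Hill-type death/sporulation term that switches on as nutrient runs out;
a fraction psi of the nutrient bound in dying cells is recycled:

    dC/dt = C [ k_g N^h1/(N^h1 + K1^h1) - k_d K2^h2/(N^h2 + K2^h2) ]
    dN/dt = -gamma C [ k_g N^h1/(N^h1 + K1^h1)
                       - psi k_d K2^h2/(N^h2 + K2^h2) ]

The per-capita gross growth term (the k_g Hill factor) is exported as
the growth rate mu(t) that drives protein dilution in the phosphorelay;
the net term (growth minus death) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

#: floor applied to exported growth rates; the C period diverges at mu=0
MU_FLOOR = 1e-3


@dataclass
class MoserParameters:
    """Parameters of the nutrient-limited growth model.

    Defaults describe a batch starvation culture that grows near its
    maximal rate for the first ~4 h and decelerates between 5 and 8 h
    as the nutrient pool is exhausted, with the inoculum at OD 0.1 and
    the nutrient normalised to 1.
    """

    k_g: float = 0.85      # maximal specific growth rate, h^-1
    k_death: float = 0.15  # maximal death/sporulation rate, h^-1
    K1: float = 0.35       # half-max nutrient level for growth
    K2: float = 0.05       # half-max nutrient level for death onset
    h1: float = 1.0        # Hill coefficient, growth
    h2: float = 4.0        # Hill coefficient, death
    gamma: float = 0.25    # yield: nutrient consumed per unit OD
    psi: float = 0.5       # fraction of nutrient recycled by death
    N0: float = 1.0        # initial nutrient (normalised)
    C0: float = 0.1        # initial cell density (OD600)

    def __post_init__(self) -> None:
        for name in ("k_g", "k_death", "K1", "K2", "h1", "h2", "gamma", "N0", "C0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.psi <= 1.0):
            # psi = 1 is the closed-system limit (full nutrient recycling)
            raise ValueError("psi must lie in (0,1]")

    def as_dict(self) -> dict:
        return asdict(self)


def _hill(x, K, h):
    x = np.maximum(x, 0.0)
    return x ** h / (x ** h + K ** h)


def growth_term(params: MoserParameters, N):
    """Per-capita gross growth rate k_g N^h1/(N^h1+K1^h1)."""
    return params.k_g * _hill(N, params.K1, params.h1)


def death_term(params: MoserParameters, N):
    """Per-capita death/sporulation rate k_d K2^h2/(N^h2+K2^h2)."""
    N = np.maximum(np.asarray(N, float), 0.0)
    return params.k_death * params.K2 ** params.h2 / (N ** params.h2 + params.K2 ** params.h2)


@dataclass
class GrowthTrajectory:
    """Simulated growth: time grid with C(t), N(t) and growth rates."""

    t: np.ndarray
    od: np.ndarray
    nutrient: np.ndarray
    mu_gross: np.ndarray
    mu_net: np.ndarray
    params: MoserParameters = field(repr=False, default=None)

    def mu(self, which: str = "gross") -> np.ndarray:
        return self.mu_gross if which == "gross" else self.mu_net


def simulate_growth(params: MoserParameters, t_grid) -> GrowthTrajectory:
    """Integrate the growth model over an increasing time grid."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("time grid must be 1-D and strictly increasing")

    def rhs(t, y):
        C, N = y
        g = growth_term(params, N)
        d = death_term(params, N)
        return [C * (g - d), -params.gamma * C * (g - params.psi * d)]

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), [params.C0, params.N0],
                    t_eval=t_grid, method="LSODA", rtol=1e-9, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"growth integration failed: {sol.message}")
    C, N = sol.y
    if (C < -1e-9).any() or (N < -1e-6).any():
        raise RuntimeError("growth trajectory went negative")
    N = np.clip(N, 0.0, None)
    mu_gross = growth_term(params, N)
    mu_net = mu_gross - death_term(params, N)
    return GrowthTrajectory(t=t_grid, od=np.clip(C, 0.0, None), nutrient=N,
                            mu_gross=mu_gross, mu_net=np.clip(mu_net, 0.0, None),
                            params=params)


def growth_rate_at(params: MoserParameters, t, horizon: float = 48.0,
                   which: str = "gross") -> np.ndarray | float:
    """Growth rate mu at time(s) t in hours (clamped below at MU_FLOOR).

    Raises if t lies outside [0, horizon]; the model is only meaningful
    over the simulated starvation experiment.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr < 0).any() or (t_arr > horizon).any():
        raise ValueError(f"time outside simulated horizon [0, {horizon}] h")
    grid = np.union1d(np.linspace(0.0, max(horizon, t_arr.max(), 1.0), 481), t_arr)
    traj = simulate_growth(params, grid)
    mu = np.interp(t_arr, traj.t, traj.mu(which))
    mu = np.maximum(mu, MU_FLOOR)
    return float(mu[0]) if np.isscalar(t) or np.ndim(t) == 0 else mu


# ---------------------------------------------------------------------------
# fitting


_FIT_FIELDS = ("k_g", "k_death", "K1", "K2", "h1", "h2", "gamma", "psi")

_DEFAULT_BOUNDS = {
    "k_g": (0.05, 3.0), "k_death": (0.005, 1.0),
    "K1": (0.01, 0.9), "K2": (0.005, 0.5),
    "h1": (0.5, 6.0), "h2": (0.5, 8.0),
    "gamma": (0.05, 2.0), "psi": (0.05, 0.95),
}


@dataclass
class GrowthFit:
    params: MoserParameters
    rmse: float
    converged: bool
    degenerate: bool
    n_points: int


def fit_growth_curve(t, od, bounds: dict | None = None,
                     n_starts: int = 4, seed: int = 0) -> GrowthFit:
    """Fit the growth model to an OD600 time series.

    Bound-constrained nonlinear least squares from several starting
    points (multistart local optimisation); C0 is fixed at 0.1 and N0 at
    1.  Residuals are taken on log OD: OD measurement noise is
    multiplicative, so log-space least squares is the corresponding
    maximum-likelihood fit and keeps the early exponential phase (which
    pins the growth rate) from being swamped by the plateau.  A series
    whose OD never changes by more than 5% is flagged degenerate
    (no-growth data cannot identify the rates).
    """
    t = np.asarray(t, dtype=float)
    od = np.asarray(od, dtype=float)
    if t.size != od.size or t.size < 8:
        raise ValueError("need >= 8 (t, OD) points")
    if (od <= 0).any():
        raise ValueError("OD values must be > 0")
    bounds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    lo = np.array([bounds[f][0] for f in _FIT_FIELDS])
    hi = np.array([bounds[f][1] for f in _FIT_FIELDS])

    degenerate = (od.max() - od.min()) < 0.05 * od.min()

    log_od = np.log(od)

    def residuals(x):
        p = MoserParameters(**dict(zip(_FIT_FIELDS, x)))
        try:
            traj = simulate_growth(p, t)
        except RuntimeError:
            return np.full(t.size, 1e3)
        return np.log(np.maximum(traj.od, 1e-12)) - log_od

    def od_residuals(x):
        p = MoserParameters(**dict(zip(_FIT_FIELDS, x)))
        return simulate_growth(p, t).od - od

    rng = np.random.default_rng(seed)
    default = MoserParameters()
    x0s = [np.array([getattr(default, f) for f in _FIT_FIELDS])]
    # data-driven start: early log-slope estimates k_g, the plateau the yield
    dlog = np.diff(np.log(od)) / np.diff(t)
    kg0 = float(np.clip(np.max(dlog[: max(3, t.size // 4)]), *bounds["k_g"]))
    gamma0 = float(np.clip(1.0 / max(od.max() - od[0], 1e-6), *bounds["gamma"]))
    guess = dict(zip(_FIT_FIELDS, x0s[0]))
    guess.update(k_g=kg0, gamma=gamma0)
    x0s.append(np.array([guess[f] for f in _FIT_FIELDS]))
    for _ in range(max(0, n_starts - 2)):
        x0s.append(lo + (hi - lo) * rng.uniform(0.15, 0.85, lo.size))

    best = None
    converged = False
    for x0 in x0s:
        res = least_squares(residuals, np.clip(x0, lo, hi), bounds=(lo, hi),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or res.cost < best.cost:
            best = res
            converged = res.status > 0
    fitted = MoserParameters(**dict(zip(_FIT_FIELDS, best.x)))
    rmse = float(np.sqrt(np.mean(od_residuals(best.x) ** 2)))
    return GrowthFit(params=fitted, rmse=rmse, converged=converged,
                     degenerate=degenerate, n_points=t.size)
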