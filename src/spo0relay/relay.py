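"""Mass-action model of the KinA/KinC -> Spo0F -> Spo0B -> Spo0A phosphorelay.

Species are tracked in uM.  Every post-translational step is elementary
mass action; the enzyme-substrate complexes Spo0B.Spo0A~P, Spo0E.Spo0A~P
and KinA.Sda are explicit (plus KinC.Spo0F~P in the phosphatase
variant).  Each synthesised protein carries a production term (set by
the growth law) and every species decays at degradation + dilution.

The central quantity is the phosphorylated fraction of the master
regulator,

    [Spo0A~P] / ([Spo0A] + [Spo0A~P] + [Spo0E.Spo0A~P] + [Spo0B.Spo0A~P]),

and the signed phosphoryl flux through KinC, which distinguishes the
kinase acting as a phosphate source (flux toward Spo0F) from a sink
(reverse phosphotransfer draining Spo0F~P).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import growth_law
from .params import (
    PROTEINS,
    VARIANT_PHOSPHATASE,
    ConfigError,
    GrowthLawParameters,
    KineticParameters,
    StrainConfig,
)

#: state-vector layout
SPECIES = (
    "KinA", "KinA~P", "KinC", "KinC~P",
    "Spo0F", "Spo0F~P", "Spo0B", "Spo0B~P",
    "Spo0A", "Spo0A~P", "Sda", "Spo0E",
    "KinA.Sda", "Spo0B.Spo0A~P", "Spo0E.Spo0A~P", "KinC.Spo0F~P",
)
IDX = {name: i for i, name in enumerate(SPECIES)}
N_SPECIES = len(SPECIES)

#: free unphosphorylated form of each synthesised protein
_PRODUCED_INDEX = {p: IDX[p] for p in PROTEINS}

#: species carrying exactly one phosphoryl group
PHOSPHO_SPECIES = ("KinA~P", "KinC~P", "Spo0F~P", "Spo0B~P", "Spo0A~P",
                   "Spo0B.Spo0A~P", "Spo0E.Spo0A~P", "KinC.Spo0F~P")

#: members of each protein's conservation pool
PROTEIN_POOLS = {
    "KinA": ("KinA", "KinA~P", "KinA.Sda"),
    "KinC": ("KinC", "KinC~P", "KinC.Spo0F~P"),
    "Spo0F": ("Spo0F", "Spo0F~P", "KinC.Spo0F~P"),
    "Spo0B": ("Spo0B", "Spo0B~P", "Spo0B.Spo0A~P"),
    "Spo0A": ("Spo0A", "Spo0A~P", "Spo0B.Spo0A~P", "Spo0E.Spo0A~P"),
    "Sda": ("Sda", "KinA.Sda"),
    "Spo0E": ("Spo0E", "Spo0E.Spo0A~P"),
}


class SolverError(RuntimeError):
    """Steady-state search failed to reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None,
                 state: np.ndarray | None = None):
        super().__init__(message)
        self.residual = residual
        self.state = state


class UndefinedFractionError(ZeroDivisionError):
    """Spo0A~P fraction requested for a state with no Spo0A at all."""


@dataclass
class ReactionSystem:
    """Right-hand-side evaluator for the phosphorelay ODEs."""

    params: KineticParameters
    production: np.ndarray  # per-species production rates, uM/h
    decay: np.ndarray       # per-species first-order decay constants, h^-1
    strain: StrainConfig = field(default_factory=StrainConfig.wild_type)
    #: proteolysis of Sda while bound to KinA (h^-1); the kinase is
    #: released intact, so sequestration does not protect Sda from its
    #: fast turnover (otherwise the complex would act as a stable Sda
    #: reservoir and the titration switch could never cross)
    sda_release: float = 0.0

    def __post_init__(self) -> None:
        self.production = np.asarray(self.production, dtype=float)
        self.decay = np.asarray(self.decay, dtype=float)
        if self.production.shape != (N_SPECIES,) or self.decay.shape != (N_SPECIES,):
            raise ConfigError("production/decay vectors must cover every species")
        if (self.production < 0).any():
            raise ConfigError("production rates must be >= 0")
        if (self.decay < 0).any():
            raise ConfigError("decay rates must be >= 0")

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        p = self.params
        (A, Ap, C, Cp, F, Fp, B, Bp, Z, Zp, S, E, AS, BZp, EZp, CFp) = y

        auto_a = p.k_a1 * A - p.k_a2 * Ap
        auto_c = p.k_c1 * C - p.k_c2 * Cp
        # phosphotransfer kinase <-> Spo0F (net forward flux)
        t_a = p.k_a3 * Ap * F - p.k_a4 * A * Fp
        if p.variant == VARIANT_PHOSPHATASE:
            t_c = p.k_c3 * Cp * F
            bind_c = p.k_c4 * C * Fp          # KinC + Spo0F~P -> KinC.Spo0F~P
            hyd_c = p.k_pc * CFp              # -> KinC + Spo0F
        else:
            t_c = p.k_c3 * Cp * F - p.k_c4 * C * Fp
            bind_c = 0.0
            hyd_c = 0.0
        t_fb = p.k1 * Fp * B - p.k2 * F * Bp
        bz_on = p.k3 * Bp * Z - p.k4 * BZp    # net formation via transfer
        bz_off = p.k5 * BZp - p.k6 * B * Zp   # net release of Spo0A~P
        seq = p.k_i * A * S - p.k_b * AS
        e_on = p.v_f * E * Zp - p.v_b * EZp
        e_cat = p.v_e * EZp
        rel = self.sda_release * AS           # KinA.Sda -> KinA

        dy = self.production - self.decay * y
        dy[0] += -auto_a + t_a - seq + rel
        dy[1] += auto_a - t_a
        dy[2] += -auto_c + t_c - bind_c + hyd_c
        dy[3] += auto_c - t_c
        dy[4] += -t_a - t_c + t_fb + hyd_c
        dy[5] += t_a + t_c - t_fb - bind_c
        dy[6] += -t_fb + bz_off
        dy[7] += t_fb - bz_on
        dy[8] += -bz_on + e_cat
        dy[9] += bz_off - e_on
        dy[10] += -seq
        dy[11] += -e_on + e_cat
        dy[12] += seq - rel
        dy[13] += bz_on - bz_off
        dy[14] += e_on - e_cat
        dy[15] += bind_c - hyd_c
        return dy

    def residual(self, y: np.ndarray) -> float:
        return float(np.max(np.abs(self.rhs(0.0, y))))

    def default_initial_state(self) -> np.ndarray:
        """All proteins unphosphorylated at production/decay balance."""
        y0 = np.zeros(N_SPECIES)
        for prot, i in _PRODUCED_INDEX.items():
            if self.decay[i] > 0:
                y0[i] = self.production[i] / self.decay[i]
        return y0

    def phosphoryl_total(self, y: np.ndarray) -> float:
        return float(sum(y[IDX[s]] for s in PHOSPHO_SPECIES))

    def protein_total(self, y: np.ndarray, protein: str) -> float:
        return float(sum(y[IDX[s]] for s in PROTEIN_POOLS[protein]))


def build_reaction_system(params: KineticParameters,
                          strain: StrainConfig | None = None,
                          production_rates: dict | None = None,
                          decay_rate: float | dict = 0.2) -> ReactionSystem:
    """Assemble the ODE system from per-protein production and decay rates.

    ``production_rates`` maps protein name -> uM/h (missing proteins get
    0); strain multipliers scale them (0 for a deletion).  ``decay_rate``
    is either one rate applied to every species or a per-protein mapping
    (complexes then use the ``"complex"`` entry, default 0.2 h^-1).
    """
    strain = strain or StrainConfig.wild_type()
    production_rates = production_rates or {}
    for name in production_rates:
        if name not in PROTEINS:
            raise ConfigError(f"unknown species {name!r} in production map")

    prod = np.zeros(N_SPECIES)
    for prot, v in production_rates.items():
        if v < 0:
            raise ConfigError(f"negative production rate for {prot}")
        prod[_PRODUCED_INDEX[prot]] = strain.multiplier(prot) * v

    decay = np.zeros(N_SPECIES)
    if isinstance(decay_rate, dict):
        cplx = decay_rate.get("complex", 0.2)
        for prot in PROTEINS:
            kd = decay_rate.get(prot, cplx)
            decay[IDX[prot]] = kd
            phospho = prot + "~P"
            if phospho in IDX:
                decay[IDX[phospho]] = kd
        for sp in ("KinA.Sda", "Spo0B.Spo0A~P", "Spo0E.Spo0A~P", "KinC.Spo0F~P"):
            decay[IDX[sp]] = cplx
        # bound Sda is still degraded (excess over the complex's bulk
        # turnover), releasing the kinase
        sda_release = max(0.0, decay_rate.get("Sda", cplx) - cplx)
    else:
        decay[:] = float(decay_rate)
        sda_release = 0.0

    return ReactionSystem(params=params, production=prod, decay=decay,
                          strain=strain, sda_release=sda_release)


def system_at_growth_rate(params: KineticParameters,
                          strain: StrainConfig | None = None,
                          mu: float = 0.5,
                          law: GrowthLawParameters | None = None,
                          production_overrides: dict | None = None) -> ReactionSystem:
    """Build the system with growth-law production/decay at growth rate mu."""
    law = law or GrowthLawParameters()
    strain = strain or StrainConfig.wild_type()
    mu = max(mu, growth_law.MU_FLOOR)
    prod = growth_law.production_rates(mu, law, StrainConfig.wild_type())
    if production_overrides:
        prod.update(production_overrides)
    kd = growth_law.decay_rates(mu, law)
    kd["complex"] = law.k_deg_default + mu
    return build_reaction_system(params, strain, prod, kd)


def steady_state(system: ReactionSystem,
                 initial: np.ndarray | None = None,
                 tol: float = 1e-9,
                 max_horizon: float = 4000.0) -> np.ndarray:
    """Steady state of the relay by stiff integration plus a Newton polish.

    Integrates from ``initial`` (default: unphosphorylated balance) over
    successively longer horizons; once the trajectory is close to the
    fixed point a damped Newton solve drives the RHS max-norm below
    ``tol``.  The system is monostable over the parameter ranges used
    here, so the result is independent of the initial condition.
    """
    y = system.default_initial_state() if initial is None else np.asarray(initial, float)
    if (y < 0).any():
        raise ValueError("initial state must be nonnegative")

    t_end = 60.0
    elapsed = 0.0
    best = y
    best_res = system.residual(y)
    while True:
        sol = solve_ivp(system.rhs, (0.0, t_end), best, method="LSODA",
                        rtol=1e-8, atol=1e-12)
        if not sol.success:
            raise SolverError(f"integration failed: {sol.message}",
                              residual=best_res, state=best)
        best = sol.y[:, -1]
        best_res = system.residual(best)
        if best_res < tol:
            break
        # polish with a root solve from the integrated guess
        polished = _newton_polish(system, best, tol)
        if polished is not None:
            best = polished
            best_res = system.residual(best)
            break
        elapsed += t_end
        if elapsed >= max_horizon:
            raise SolverError(
                f"no steady state within horizon {max_horizon} h "
                f"(residual {best_res:.3e} > tol {tol:.1e})",
                residual=best_res, state=best)
        t_end *= 3.0

    if (best < -1e-9).any():
        raise SolverError("steady state has significantly negative concentrations",
                          residual=best_res, state=best)
    return np.clip(best, 0.0, None)


def _newton_polish(system: ReactionSystem, guess: np.ndarray,
                   tol: float) -> np.ndarray | None:
    sol = root(lambda y: system.rhs(0.0, y), guess, method="hybr",
               options={"xtol": 1e-12})
    y = sol.x
    if (not sol.success) or (y < -1e-9).any() or system.residual(y) > tol:
        return None
    return y


def spo0ap_fraction(state: np.ndarray) -> float:
    """Phosphorylated fraction of the Spo0A pool (complexes included)."""
    zp = state[IDX["Spo0A~P"]]
    denom = (state[IDX["Spo0A"]] + zp + state[IDX["Spo0E.Spo0A~P"]]
             + state[IDX["Spo0B.Spo0A~P"]])
    if denom <= 0:
        raise UndefinedFractionError("total Spo0A is zero; fraction undefined")
    frac = zp / denom
    return float(min(max(frac, 0.0), 1.0))


def kinc_net_flux(state: np.ndarray, params: KineticParameters) -> float:
    """Signed phosphoryl flux from KinC~P toward Spo0F (uM/h).

    Positive: KinC feeds phosphate into the relay (source).  Negative:
    phosphate is drawn from Spo0F~P back into KinC (sink), either by
    reverse phosphotransfer or, in the phosphatase variant, by committed
    binding of Spo0F~P.
    """
    Cp = state[IDX["KinC~P"]]
    C = state[IDX["KinC"]]
    F = state[IDX["Spo0F"]]
    Fp = state[IDX["Spo0F~P"]]
    return float(params.k_c3 * Cp * F - params.k_c4 * C * Fp)


def scan_kinase_plane(params: KineticParameters,
                      kina_concs,
                      kinc_concs,
                      mu: float = 0.5,
                      spo0a_production: float = 1.0,
                      law: GrowthLawParameters | None = None,
                      include_sda: bool = False,
                      tol: float = 1e-9):
    """Steady-state Spo0A~P fraction over a grid of kinase abundances.

    Axes are active-kinase concentrations (uM): each kinase's production
    rate is set to conc * (k_deg + mu) so its steady total matches the
    requested abundance.  Spo0A production is fixed (default 1 uM/h) and
    the growth rate fixed (default 0.5 h^-1).  Sda is left out by
    default so the KinA axis reads as *active* KinA.

    Returns (fractions, errors): an array of shape
    (len(kina_concs), len(kinc_concs)) and a dict mapping failed grid
    indices to exceptions.
    """
    kina_concs = np.atleast_1d(np.asarray(kina_concs, float))
    kinc_concs = np.atleast_1d(np.asarray(kinc_concs, float))
    if kina_concs.size == 0 or kinc_concs.size == 0:
        raise ValueError("scan grid must be nonempty")
    law = law or GrowthLawParameters()
    frac = np.full((kina_concs.size, kinc_concs.size), np.nan)
    errors: dict = {}
    for i, ca in enumerate(kina_concs):
        for j, cc in enumerate(kinc_concs):
            overrides = {
                "KinA": growth_law.kinase_production_for_concentration(ca, "KinA", mu, law),
                "KinC": growth_law.kinase_production_for_concentration(cc, "KinC", mu, law),
                "Spo0A": spo0a_production,
            }
            if not include_sda:
                overrides["Sda"] = 0.0
            system = system_at_growth_rate(params, None, mu, law, overrides)
            try:
                frac[i, j] = spo0ap_fraction(steady_state(system, tol=tol))
            except (SolverError, UndefinedFractionError) as exc:  # pragma: no cover
                errors[(i, j)] = exc
    return frac, errors
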