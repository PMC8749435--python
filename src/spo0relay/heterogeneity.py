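"""Single-cell layer: growth-rate noise propagated through the relay.

Generation times in a snapshot are normally distributed around the
population mean with CV 0.25 (values below 0.2 h are rejected and
redrawn).  Each cell's growth rate mu = ln2/tau_cyc deterministically
sets its steady-state Spo0A~P through the phosphorelay — growth-rate
noise is the only noise source — and promoter activities follow from
the Hill read-outs.  Because slow-growing cells accumulate active KinA
(for which KinC is a phosphate sink) while fast-growing cells rely on
KinC as a source, KinC compresses the Spo0A~P distribution from both
ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import MoserParameters, growth_rate_at
from .params import GrowthLawParameters, KineticParameters, StrainConfig
from .promoters import HillParameters, hill_activity
from . import relay

LN2 = float(np.log(2.0))


@dataclass
class HeterogeneityConfig:
    """Sampling settings for single-cell snapshots."""

    cv: float = 0.25              # coefficient of variation of tau_cyc
    min_generation_time: float = 0.2   # h; smaller draws are rejected
    n_cells: int = 1000
    seed: int = 0
    #: model cells count as expressing when activity exceeds this
    #: fraction of the promoter scale
    expression_threshold_fraction: float = 0.01
    #: growth rates are rounded to this many decimals when reusing
    #: steady states between cells (the map mu -> state is deterministic)
    mu_round: int = 4

    def __post_init__(self) -> None:
        if not self.cv > 0:
            raise ValueError("cv must be > 0")
        if not self.min_generation_time > 0:
            raise ValueError("min generation time must be > 0")
        if self.n_cells < 1:
            raise ValueError("need at least one cell")


def sample_generation_times(mean_tau: float, config: HeterogeneityConfig,
                            rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw generation times ~ Normal(mean, cv*mean), truncated >= 0.2 h.

    Rejected draws are replaced so the requested number of cells is
    always returned.
    """
    if not mean_tau > 0:
        raise ValueError("mean generation time must be > 0")
    rng = rng or np.random.default_rng(config.seed)
    sd = config.cv * mean_tau
    out = np.empty(config.n_cells)
    filled = 0
    while filled < config.n_cells:
        draw = rng.normal(mean_tau, sd, size=config.n_cells - filled)
        keep = draw[draw >= config.min_generation_time]
        out[filled:filled + keep.size] = keep
        filled += keep.size
    return out


def single_cell_population(time_h: float,
                           strain: StrainConfig,
                           config: HeterogeneityConfig | None = None,
                           kinetics: KineticParameters | None = None,
                           moser: MoserParameters | None = None,
                           law: GrowthLawParameters | None = None,
                           hill: HillParameters | None = None,
                           tol: float = 1e-8) -> pd.DataFrame:
    """Snapshot of n cells at a culture time point.

    The population-mean generation time is ln2 / mu(t) from the growth
    model; each cell's Spo0A~P is the relay steady state at its own
    growth rate (cells are independent, so the result does not depend
    on their order).  Returns a DataFrame with per-cell tau_cyc, mu,
    spo0ap, promoter activities and expressing flags.
    """
    config = config or HeterogeneityConfig()
    kinetics = kinetics or KineticParameters()
    moser = moser or MoserParameters()
    hill = hill or HillParameters()

    mu_mean = growth_rate_at(moser, time_h)
    taus = sample_generation_times(LN2 / mu_mean, config)
    mus = LN2 / taus

    cache: dict = {}
    zp = np.empty(config.n_cells)
    for i, mu in enumerate(mus):
        key = round(float(mu), config.mu_round)
        if key not in cache:
            system = relay.system_at_growth_rate(kinetics, strain, key, law)
            cache[key] = relay.steady_state(system, tol=tol)[relay.IDX["Spo0A~P"]]
        zp[i] = cache[key]

    tapa = np.asarray(hill_activity(zp, hill, "PtapA"))
    spoiig = np.asarray(hill_activity(zp, hill, "PspoIIG"))
    thr = config.expression_threshold_fraction
    return pd.DataFrame({
        "cell_id": np.arange(config.n_cells),
        "tau_cyc": taus,
        "mu": mus,
        "spo0ap": zp,
        "PtapA": tapa,
        "PspoIIG": spoiig,
        "PtapA_expressing": tapa > thr * hill.scale_t,
        "PspoIIG_expressing": spoiig > thr * hill.scale_g,
    })


def expressing_fraction(population: pd.DataFrame, promoter: str,
                        threshold: float | None = None) -> float:
    """Fraction of cells whose promoter activity exceeds the threshold.

    With ``threshold=None`` the stored expressing flags are used.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    if threshold is None:
        return float(population[f"{promoter}_expressing"].mean())
    return float((population[promoter].to_numpy() > threshold).mean())


def population_mean_decomposition(population: pd.DataFrame, promoter: str):
    """(mean over all cells, mean over expressing cells, fraction expressing).

    When non-expressing cells contribute zero activity,
    mean_all = fraction * mean_expressing.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    act = population[promoter].to_numpy()
    flags = population[f"{promoter}_expressing"].to_numpy()
    mean_all = float(act.mean())
    frac = float(flags.mean())
    mean_expr = float(act[flags].mean()) if flags.any() else 0.0
    return mean_all, mean_expr, frac
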