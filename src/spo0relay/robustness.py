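"""Monte-Carlo robustness of the KinC source/sink conclusion.

Every kinetic constant of the relay is redrawn uniformly from
[p/3, 3p] around its base value; for each draw the steady-state
Spo0A~P fraction is evaluated at four corner abundances of
(KinA, KinC).  With

    f1 = (low KinA, low KinC)     f2 = (low KinA, high KinC)
    f3 = (high KinA, high KinC)   f4 = (high KinA, low KinC)

f1/f2 < 1 means KinC raises Spo0A~P when KinA is scarce (source) and
f3/f4 < 1 means KinC lowers it when KinA is abundant (sink).  The
summary reports the proportion of draws for which each inequality
holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import GrowthLawParameters, KineticParameters
from . import relay


@dataclass
class RobustnessDesign:
    """Sampling plan for the parameter-perturbation study."""

    fold_range: float = 3.0
    n_samples: int = 1000
    seed: int = 0
    low_kina: float = 0.03   # uM, corner abundances
    high_kina: float = 3.0
    low_kinc: float = 0.03
    high_kinc: float = 3.0
    mu: float = 0.5          # h^-1, fixed growth rate of the scan
    spo0a_production: float = 1.0  # uM/h

    def __post_init__(self) -> None:
        if not self.fold_range >= 1.0:
            raise ValueError("fold_range must be >= 1")
        if self.n_samples < 1:
            raise ValueError("need >= 1 sample")
        corners = {(self.low_kina, self.low_kinc), (self.low_kina, self.high_kinc),
                   (self.high_kina, self.high_kinc), (self.high_kina, self.low_kinc)}
        if len(corners) != 4:
            raise ValueError("corner abundances must be pairwise distinct")


def sample_parameter_sets(base: KineticParameters,
                          design: RobustnessDesign) -> list[KineticParameters]:
    """Draw parameter sets with each listed constant ~ U[p/f, f*p]."""
    rng = np.random.default_rng(design.seed)
    f = design.fold_range
    out = []
    for _ in range(design.n_samples):
        kw = {name: rng.uniform(getattr(base, name) / f, f * getattr(base, name))
              for name in base.SAMPLED}
        out.append(base.replace(**kw))
    return out


def corner_fractions(params: KineticParameters,
                     design: RobustnessDesign | None = None,
                     law: GrowthLawParameters | None = None,
                     tol: float = 1e-8) -> tuple[float, float, float, float]:
    """(f1, f2, f3, f4) Spo0A~P fractions at the four kinase corners."""
    design = design or RobustnessDesign()
    grid, errors = relay.scan_kinase_plane(
        params,
        [design.low_kina, design.high_kina],
        [design.low_kinc, design.high_kinc],
        mu=design.mu, spo0a_production=design.spo0a_production,
        law=law, tol=tol)
    if errors:
        # one retry at a tighter integration tolerance before giving up
        grid, errors = relay.scan_kinase_plane(
            params,
            [design.low_kina, design.high_kina],
            [design.low_kinc, design.high_kinc],
            mu=design.mu, spo0a_production=design.spo0a_production,
            law=law, tol=tol * 0.1)
        if errors:
            raise relay.SolverError(f"corner evaluation failed at {sorted(errors)}")
    f1, f2 = grid[0, 0], grid[0, 1]
    f4, f3 = grid[1, 0], grid[1, 1]
    return float(f1), float(f2), float(f3), float(f4)


@dataclass
class RobustnessSummary:
    prop_f1f2_lt1: float
    prop_f3f4_lt1: float
    se_f1f2: float
    se_f3f4: float
    n_ok: int
    n_failed: int
    table: pd.DataFrame = field(repr=False, default=None)


def robustness_summary(base: KineticParameters | None = None,
                       design: RobustnessDesign | None = None,
                       law: GrowthLawParameters | None = None) -> RobustnessSummary:
    """Run the full Monte-Carlo study; pure function of (base, design).

    Solver failures are counted separately and excluded from the
    denominators of the reported proportions.
    """
    base = base or KineticParameters()
    design = design or RobustnessDesign()
    rows = []
    n_failed = 0
    for sample_id, params in enumerate(sample_parameter_sets(base, design)):
        try:
            f1, f2, f3, f4 = corner_fractions(params, design, law)
        except relay.SolverError:
            n_failed += 1
            continue
        rows.append({"sample_id": sample_id, "f1": f1, "f2": f2, "f3": f3,
                     "f4": f4, "r12": f1 / f2, "r34": f3 / f4})
    table = pd.DataFrame(rows)
    n_ok = len(table)
    p12 = float((table["r12"] < 1).mean()) if n_ok else float("nan")
    p34 = float((table["r34"] < 1).mean()) if n_ok else float("nan")

    def se(p):
        return float(np.sqrt(p * (1 - p) / n_ok)) if n_ok else float("nan")

    return RobustnessSummary(prop_f1f2_lt1=p12, prop_f3f4_lt1=p34,
                             se_f1f2=se(p12), se_f3f4=se(p34),
                             n_ok=n_ok, n_failed=n_failed, table=table)
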