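"""Growth-rate coupling: volume law, gene dosage, production and decay.

A cell's growth rate mu sets protein concentrations through three
channels: (i) slower-growing cells are smaller, so the same synthesis
flux yields a higher concentration (volume factor F); (ii) gene copy
number depends on the replication-origin distance of the gene and on
the ratio of the C period to the cell cycle length; (iii) dilution at
rate mu adds to nonspecific degradation.  Transcription and translation
rates themselves are taken to be growth-rate independent.
"""

from __future__ import annotations

import math

import numpy as np

from .params import GrowthLawParameters, StrainConfig, PROTEINS

#: growth rates below this are clamped; the C period diverges at mu -> 0
MU_FLOOR = 1e-3


def volume_factor(mu: float, law: GrowthLawParameters | None = None) -> float:
    """Cell-volume factor F(mu) = 2^{k (a - mu)}; F = 1 at mu = a."""
    law = law or GrowthLawParameters()
    if not mu > 0:
        raise ValueError(f"growth rate must be > 0, got {mu}")
    return float(2.0 ** (law.k * (law.a - mu)))


def c_period(mu: float, law: GrowthLawParameters | None = None) -> float:
    """C-period duration tau_c = 0.78 + 0.15/mu (h)."""
    law = law or GrowthLawParameters()
    if not mu > 0:
        raise ValueError(f"growth rate must be > 0, got {mu}")
    return law.c_period_const + law.c_period_slope / mu


def gene_copy_number(mu: float, p: float,
                     law: GrowthLawParameters | None = None) -> float:
    """Average copy number n = 2^{1 - tau_c p / tau_cyc}, tau_cyc = ln2/mu.

    Replication is assumed to start at division and multifork replication
    is excluded, so n = 2 at the origin (p = 0) and n = 1 when replication
    takes the whole cycle for a terminus gene (p = 1, tau_c = tau_cyc).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"gene position must lie in [0,1], got {p}")
    tau_c = c_period(mu, law)
    tau_cyc = math.log(2.0) / mu
    return float(2.0 ** (1.0 - tau_c * p / tau_cyc))


def production_rate(v_p: float, n: float, F: float) -> float:
    """Concentration production rate v = n * v_p * F(mu) (uM/h)."""
    if v_p < 0 or n < 0 or F < 0:
        raise ValueError("production-rate inputs must be >= 0")
    return float(n * v_p * F)


def decay_rate(k_deg: float, mu: float) -> float:
    """Effective decay constant k_d = k_deg + mu (degradation + dilution)."""
    if k_deg < 0 or mu < 0:
        raise ValueError("decay-rate inputs must be >= 0")
    return float(k_deg + mu)


def production_rates(mu: float, law: GrowthLawParameters | None = None,
                     strain: StrainConfig | None = None) -> dict:
    """Per-protein production rates (uM/h) at growth rate mu for a strain."""
    law = law or GrowthLawParameters()
    strain = strain or StrainConfig.wild_type()
    mu = max(mu, MU_FLOOR)
    F = volume_factor(mu, law)
    out = {}
    for prot in PROTEINS:
        n = gene_copy_number(mu, law.gene_position[prot], law)
        out[prot] = strain.multiplier(prot) * production_rate(law.v_p[prot], n, F)
    return out


def decay_rates(mu: float, law: GrowthLawParameters | None = None) -> dict:
    """Per-protein effective decay constants (h^-1) at growth rate mu."""
    law = law or GrowthLawParameters()
    mu = max(mu, MU_FLOOR)
    return {p: decay_rate(law.k_deg[p], mu) for p in PROTEINS}


def steady_protein_level(v_p_eff: float, k_deg: float, mu: float) -> float:
    """Steady concentration v/(k_deg + mu) of an isolated protein."""
    return v_p_eff / decay_rate(k_deg, mu)


def free_kinase_titration_limit(total_kinase: float, total_inhibitor: float) -> float:
    """Strong-binding limit of stoichiometric sequestration.

    When an unstable inhibitor binds a stable kinase essentially
    irreversibly, the free kinase is max(0, K_tot - I_tot): the basis of
    the ultrasensitive (molecular-titration) response of KinA to growth
    rate.
    """
    return max(0.0, total_kinase - total_inhibitor)


def kinase_production_for_concentration(conc: float, protein: str, mu: float,
                                        law: GrowthLawParameters | None = None) -> float:
    """Production rate that yields steady total concentration ``conc``.

    Used by the kinase-plane scan, where axes are stated as active-kinase
    concentrations: with Sda absent the total equals the active pool and
    v = conc * (k_deg + mu).
    """
    law = law or GrowthLawParameters()
    return conc * decay_rate(law.k_deg[protein], mu)


def sensitivity_to_growth(k_deg: float, mu_range=(0.2, 1.1)) -> float:
    """Relative change of the steady level v/(k_deg+mu) across mu_range.

    Returns (max - min)/min over the range at fixed production; small for
    actively degraded proteins (Sda), large for stable ones (KinA).
    """
    lo, hi = mu_range
    levels = [1.0 / decay_rate(k_deg, m) for m in np.linspace(lo, hi, 50)]
    return (max(levels) - min(levels)) / min(levels)
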