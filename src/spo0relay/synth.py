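"""Synthetic-data generators standing in for the wet-lab measurements.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes: Moser-type OD600 growth
curves with multiplicative lognormal noise, promoter-activity time
courses (model prediction plus additive normal noise, in triplicate),
and per-cell fluorescence tables whose non-expressing cells are pure
pixel-averaged background noise.  All randomness derives from one root
seed through named substreams, so adding one generator never perturbs
another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import MoserParameters, simulate_growth
from .params import (GrowthLawParameters, KineticParameters, StrainConfig,
                     WT, DELTA_KINA, DELTA_KINC)
from .promoters import HillParameters, predict_activity_dynamics

STRAINS = {"WT": WT, "dkinA": DELTA_KINA, "dkinC": DELTA_KINC}


@dataclass
class SyntheticSpec:
    """Settings for all generators (one root seed, named substreams)."""

    seed: int = 0
    moser: MoserParameters = field(default_factory=MoserParameters)
    kinetics: KineticParameters = field(default_factory=KineticParameters)
    hill: HillParameters = field(default_factory=HillParameters)
    od_noise_cv: float = 0.02          # multiplicative lognormal
    activity_noise_frac: float = 0.10  # additive normal, fraction of signal
    n_replicates: int = 3
    # per-cell table settings
    n_cells: int = 2000
    expressing_fraction: float = 0.5
    expressing_mean: float = 50.0      # intensity shift of expressing cells
    expressing_sd: float = 20.0
    bg_sd: float = 10.0                # pixelwise background SD sigma_p
    pixels_low: int = 50
    pixels_high: int = 400
    # default sampling grid: 0-24 h at 0.5 h steps
    t_start: float = 0.0
    t_end: float = 24.0
    t_step: float = 0.5

    def __post_init__(self) -> None:
        for f in ("od_noise_cv", "activity_noise_frac", "bg_sd",
                  "expressing_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not (0.0 <= self.expressing_fraction <= 1.0):
            raise ValueError("expressing fraction must lie in [0,1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    def time_grid(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_end + 1e-9, self.t_step)


_STREAMS = {"od": 1, "promoter": 2, "cells": 3, "betagal": 4}


def gen_od_curve(spec: SyntheticSpec) -> pd.DataFrame:
    """OD600 time series: Moser trajectory x lognormal noise."""
    t = spec.time_grid()
    traj = simulate_growth(spec.moser, t)
    rng = spec.rng("od")
    if spec.od_noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + spec.od_noise_cv ** 2))
        noise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=t.size)
    else:
        noise = np.ones(t.size)
    return pd.DataFrame({"time_h": t, "od600": traj.od * noise})


def gen_promoter_timeseries(spec: SyntheticSpec,
                            strains=("WT", "dkinA", "dkinC"),
                            promoters=("PtapA", "PspoIIG"),
                            law: GrowthLawParameters | None = None) -> pd.DataFrame:
    """Promoter-activity table: model prediction + noise, in triplicate.

    Columns: time_h, strain, promoter, activity (replicate mean), sd,
    and the noise-free truth for round-trip checks.
    """
    t = spec.time_grid()
    rng = spec.rng("promoter")
    rows = []
    for strain_name in strains:
        strain = STRAINS[strain_name]
        for promoter in promoters:
            truth = predict_activity_dynamics(
                t, strain, promoter, spec.hill, spec.kinetics, spec.moser, law)
            scale = spec.hill.scale_t if promoter == "PtapA" else spec.hill.scale_g
            sd_noise = spec.activity_noise_frac * scale
            reps = truth[None, :] + rng.normal(
                0.0, sd_noise, size=(spec.n_replicates, t.size))
            rows.append(pd.DataFrame({
                "time_h": t, "strain": strain_name, "promoter": promoter,
                "activity": reps.mean(axis=0), "sd": reps.std(axis=0, ddof=1),
                "truth": truth,
            }))
    return pd.concat(rows, ignore_index=True)


def gen_cell_table(spec: SyntheticSpec, channel: str = "GFP") -> pd.DataFrame:
    """Per-cell fluorescence table with ground-truth expressing labels.

    Non-expressing cells: mean intensity ~ Normal(0, sigma_p/sqrt(n))
    (the pixel average of pure background noise).  Expressing cells add
    a positive shift drawn from a truncated normal.  Pixel counts are
    uniform over [pixels_low, pixels_high].
    """
    rng = spec.rng("cells")
    n = spec.n_cells
    npix = rng.integers(spec.pixels_low, spec.pixels_high + 1, size=n)
    is_expr = rng.random(n) < spec.expressing_fraction
    base_noise = rng.normal(0.0, 1.0, size=n) * (spec.bg_sd / np.sqrt(npix))
    shift = np.abs(rng.normal(spec.expressing_mean, spec.expressing_sd, size=n))
    intensity = base_noise + np.where(is_expr, shift, 0.0)
    return pd.DataFrame({
        "cell_id": np.arange(n),
        "image_id": rng.integers(0, max(1, n // 200), size=n),
        "channel": channel,
        "mean_intensity": intensity,
        "n_pixels": npix,
        "bg_mean": 0.0,
        "bg_sd": spec.bg_sd,
        "true_expressing": is_expr,
    })


def gen_beta_gal_readings(spec: SyntheticSpec, activities,
                          t_min: float = 10.0, volume_ml: float = 0.5,
                          od600: float = 1.0) -> pd.DataFrame:
    """Raw OD420/OD550 pairs that decode to the given specific activities.

    Inverts the Miller-type formula with a small scattering component
    on OD550; useful for exercising the decoding arithmetic end to end.
    """
    rng = spec.rng("betagal")
    activities = np.asarray(activities, dtype=float)
    od550 = np.abs(rng.normal(0.05, 0.01, size=activities.size))
    od420 = activities * t_min * volume_ml * od600 / 1000.0 + 1.75 * od550
    return pd.DataFrame({"od420": od420, "od550": od550,
                         "t_min": t_min, "volume_ml": volume_ml,
                         "od600": od600, "true_activity": activities})


def write_fixture_set(spec: SyntheticSpec, outdir) -> dict:
    """Materialise a complete demo dataset as delimited text files."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    od = gen_od_curve(spec)
    paths["od"] = outdir / "od_curve.tsv"
    od.to_csv(paths["od"], sep="\t", index=False)
    prom = gen_promoter_timeseries(spec)
    paths["promoter"] = outdir / "promoter_activity.tsv"
    prom.to_csv(paths["promoter"], sep="\t", index=False)
    cells = gen_cell_table(spec)
    paths["cells"] = outdir / "cell_intensities.tsv"
    cells.to_csv(paths["cells"], sep="\t", index=False)
    return paths
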