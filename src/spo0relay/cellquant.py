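"""Statistics of per-cell fluorescence snapshots.

Works on per-cell tables produced by an upstream segmentation step:
each record carries the background-subtracted mean intensity of a cell,
its pixel count, and the background statistics of its source image.
Under pixelwise-independent normal background noise, a non-expressing
cell's mean intensity has standard error sigma = sigma_p / sqrt(n), so
cells brighter than 3 sigma are called expressing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: required columns of a per-cell intensity table
CELL_TABLE_COLUMNS = ("cell_id", "image_id", "channel", "mean_intensity",
                      "n_pixels", "bg_mean", "bg_sd")


def call_expressing(mean_intensity, n_pixels, bg_sd, k: float = 3.0):
    """3-sigma expressing-cell caller.

    True where the background-subtracted mean intensity exceeds
    k * bg_sd / sqrt(n_pixels).  Accepts scalars or arrays.
    """
    n = np.asarray(n_pixels)
    if (n < 1).any() if n.ndim else n < 1:
        raise ValueError("pixel count must be >= 1")
    sd = np.asarray(bg_sd, dtype=float)
    if (sd < 0).any() if sd.ndim else sd < 0:
        raise ValueError("background SD must be >= 0")
    threshold = k * sd / np.sqrt(n)
    return np.asarray(mean_intensity) > threshold


def call_expressing_table(table: pd.DataFrame, channel: str,
                          k: float = 3.0) -> pd.Series:
    """Apply the caller to one channel of a per-cell table."""
    sub = table[table["channel"] == channel]
    flags = call_expressing(sub["mean_intensity"].to_numpy(),
                            sub["n_pixels"].to_numpy(),
                            sub["bg_sd"].to_numpy(), k=k)
    return pd.Series(flags, index=sub.index)


def bin_by_covariate(records: pd.DataFrame,
                     covariate: str,
                     response: str,
                     expressing: str | np.ndarray | None = None,
                     n_bins: int = 6,
                     equal_count: bool = False) -> pd.DataFrame:
    """Bin cells by a covariate (e.g. KinA-GFP) and summarise a response.

    Returns one row per bin with the mean response, SEM (= SD/sqrt(m))
    and count over all cells, plus the expressing fraction and the
    mean/SEM over expressing cells when an expressing flag is given.
    Bins are equal-width over the observed covariate range by default
    (``equal_count=True`` switches to quantile bins); empty bins are
    kept with count 0 and NaN statistics.
    """
    if len(records) < n_bins:
        raise ValueError("need at least as many records as bins")
    x = records[covariate].to_numpy(dtype=float)
    y = records[response].to_numpy(dtype=float)
    if expressing is None:
        flags = None
    elif isinstance(expressing, str):
        flags = records[expressing].to_numpy(dtype=bool)
    else:
        flags = np.asarray(expressing, dtype=bool)

    if equal_count:
        edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
    else:
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
    if edges.size < 2:
        edges = np.array([x.min(), x.max() + 1e-12])
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, edges.size - 2)

    rows = []
    for b in range(edges.size - 1):
        sel = idx == b
        m = int(sel.sum())
        row = {"bin": b, "lo": edges[b], "hi": edges[b + 1], "count": m,
               "covariate_mean": float(x[sel].mean()) if m else np.nan,
               "mean": float(y[sel].mean()) if m else np.nan,
               "sem": float(y[sel].std(ddof=1) / np.sqrt(m)) if m > 1 else np.nan}
        if flags is not None:
            fe = flags[sel]
            row["fraction_expressing"] = float(fe.mean()) if m else np.nan
            me = y[sel][fe]
            row["mean_expressing"] = float(me.mean()) if me.size else np.nan
            row["sem_expressing"] = (float(me.std(ddof=1) / np.sqrt(me.size))
                                     if me.size > 1 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def beta_gal_activity(od420, od550, t_min, volume_ml, od600):
    """Miller-type specific beta-galactosidase activity.

    1000 * (OD420 - 1.75 * OD550) / (t * V * OD600) with t in minutes
    and V in mL; the 1.75*OD550 term corrects OD420 for light
    scattering by cell debris.  Negative values (noisy blanks) are
    returned as-is.
    """
    t_min = np.asarray(t_min, dtype=float)
    volume_ml = np.asarray(volume_ml, dtype=float)
    od600 = np.asarray(od600, dtype=float)
    for name, v in (("t", t_min), ("V", volume_ml), ("OD600", od600)):
        if (v <= 0).any() if v.ndim else v <= 0:
            raise ValueError(f"{name} must be > 0")
    val = 1000.0 * (np.asarray(od420, float) - 1.75 * np.asarray(od550, float)) \
        / (t_min * volume_ml * od600)
    return val if val.ndim else float(val)


def mean_decomposition(values: np.ndarray, flags: np.ndarray):
    """mean_all = f*mean_expr + (1-f)*mean_nonexpr decomposition terms."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    f = float(flags.mean())
    mean_expr = float(values[flags].mean()) if flags.any() else 0.0
    mean_non = float(values[~flags].mean()) if (~flags).any() else 0.0
    return float(values.mean()), mean_expr, mean_non, f
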