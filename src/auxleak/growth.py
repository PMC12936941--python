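"""Track filtering and single-cell specific growth-rate estimation.

Cell length (major-axis length) is the proxy for cell size; assuming
exponential elongation, the specific growth rate of a track is the ordinary
least-squares slope of ln(length) against time over the track's full
lifetime (birth to division or loss).  Three quality filters are applied in
order: (a) any track with a relative length change above +/-15% between
consecutive frames is excluded (segmentation/tracking artifacts), (b) tracks
shorter than 5 consecutive frames are excluded, and (c) after fitting,
records with R^2 <= 0.8 are excluded.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io import TRACK_KEY

DEFAULT_MAX_REL_LENGTH_CHANGE = 0.15
DEFAULT_MIN_FRAMES = 5
DEFAULT_MIN_R2 = 0.8

GROWTH_COLUMNS = TRACK_KEY + ["cell_type", "mu_h", "r2", "n_frames", "mean_x_um", "mean_y_um"]


def filter_tracks(
    table: pd.DataFrame,
    max_rel_length_change: float = DEFAULT_MAX_REL_LENGTH_CHANGE,
    min_frames: int = DEFAULT_MIN_FRAMES,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop jump-contaminated and short tracks; report exclusion counts.

    A track is excluded entirely (not truncated) if any consecutive-frame
    pair of observed lengths changes by more than ``max_rel_length_change``
    relative to the earlier frame, or if it spans fewer than ``min_frames``
    frames.  The jump rule is evaluated first; a short track that also jumps
    is counted under the jump rule.

    Returns the filtered table and an exclusion log
    ``{"length_jump": ..., "too_few_frames": ..., "retained": ...}`` (track
    counts).
    """
    if table.empty:
        return table.copy(), {"length_jump": 0, "too_few_frames": 0, "retained": 0}
    df = table.sort_values(TRACK_KEY + ["frame"], kind="mergesort")
    g = df.groupby(TRACK_KEY, sort=False)
    rel_change = (df["length_um"] - g["length_um"].shift()).abs() / g["length_um"].shift()
    jumped = rel_change.gt(max_rel_length_change).groupby(
        [df[k] for k in TRACK_KEY], sort=False
    ).any()
    n_frames = g.size()
    short = n_frames < min_frames
    n_jump = int(jumped.sum())
    n_short = int((short & ~jumped).sum())
    keep = ~(jumped | short)
    kept_keys = keep[keep].index
    out = df.set_index(TRACK_KEY).loc[kept_keys].reset_index()
    out = out.sort_values(TRACK_KEY + ["frame"], kind="mergesort").reset_index(drop=True)
    log = {"length_jump": n_jump, "too_few_frames": n_short, "retained": int(keep.sum())}
    return out, log


def fit_track_growth(time_h, length_um) -> tuple[float, float]:
    """Specific growth rate (h^-1) and R^2 of one track by log-linear OLS.

    The slope of the OLS regression of ln(length) on time is the specific
    growth rate per unit biomass.  R^2 conventions: a zero-variance response
    (constant length) gives R^2 = 0 — the fit carries no information — while
    exactly zero residuals on a varying response give R^2 = 1.
    """
    t = np.asarray(time_h, float)
    y = np.asarray(length_um, float)
    if t.size < 2:
        raise ValueError("need at least 2 frames to fit a growth rate")
    if np.any(y <= 0):
        raise ValueError("lengths must be strictly positive")
    ly = np.log(y)
    tc = t - t.mean()
    yc = ly - ly.mean()
    sxx = tc @ tc
    if sxx == 0:
        raise ValueError("time points must not be all identical")
    syy = yc @ yc
    slope = (tc @ yc) / sxx
    if syy == 0:
        return float(slope), 0.0
    resid = yc - slope * tc
    ss_res = resid @ resid
    r2 = 1.0 if ss_res == 0 else 1.0 - ss_res / syy
    return float(slope), float(r2)


def fit_growth(table: pd.DataFrame) -> pd.DataFrame:
    """Fit every track in a (filtered) table; one growth record per track.

    Vectorized per-track OLS on ln(length) vs time via grouped sums —
    numerically identical to :func:`fit_track_growth` applied track by
    track.  Returns columns replicate_id, chamber_id, track_id, cell_type,
    mu_h, r2, n_frames, mean_x_um, mean_y_um.
    """
    if table.empty:
        return pd.DataFrame(columns=GROWTH_COLUMNS)
    if (table["length_um"] <= 0).any():
        raise ValueError("lengths must be strictly positive")
    df = table.copy()
    df["_ly"] = np.log(df["length_um"].to_numpy())
    g = df.groupby(TRACK_KEY, sort=False)
    df["_tc"] = df["time_h"] - g["time_h"].transform("mean")
    df["_yc"] = df["_ly"] - g["_ly"].transform("mean")
    df["_txy"] = df["_tc"] * df["_yc"]
    df["_txx"] = df["_tc"] ** 2
    df["_tyy"] = df["_yc"] ** 2
    agg = g.agg(
        cell_type=("cell_type", "first"),
        n_frames=("frame", "size"),
        mean_x_um=("x_um", "mean"),
        mean_y_um=("y_um", "mean"),
        sxy=("_txy", "sum"),
        sxx=("_txx", "sum"),
        syy=("_tyy", "sum"),
    )
    single = agg["sxx"] == 0
    if single.any():
        raise ValueError(
            f"track(s) with a single frame or constant time: {agg.index[single].tolist()[:5]}"
        )
    agg["mu_h"] = agg["sxy"] / agg["sxx"]
    ss_res = agg["syy"] - agg["sxy"] ** 2 / agg["sxx"]
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / agg["syy"]
    r2 = r2.where(agg["syy"] > 0, 0.0)  # zero-variance response convention
    agg["r2"] = np.clip(r2, 0.0, 1.0)
    return agg.reset_index()[GROWTH_COLUMNS]


def apply_r2_filter(records: pd.DataFrame, min_r2: float = DEFAULT_MIN_R2) -> pd.DataFrame:
    """Keep records with R^2 strictly above ``min_r2``."""
    if records.empty:
        return records.copy()
    return records[records["r2"] > min_r2].reset_index(drop=True)


def doubling_time_min(mu_h: float) -> float:
    """Doubling time in minutes for a specific growth rate in h^-1.

    t_d = ln(2) / mu, converted to minutes.
    """
    if not mu_h > 0:
        raise ValueError("doubling time is defined for strictly positive growth rates")
    return 60.0 * math.log(2.0) / mu_h


def summarize_growth(records: pd.DataFrame) -> pd.DataFrame:
    """Mean, SEM and count of growth rates per (replicate, cell type).

    Pooled rows (over all cells of a type, across replicates) are appended
    with ``replicate_id = "pooled"``.  SEM = sd / sqrt(n) with sd the sample
    standard deviation (ddof=1); for a single-record group the SEM is
    reported as missing.
    """
    if records.empty:
        return pd.DataFrame(columns=["replicate_id", "cell_type", "mean_mu_h", "sem_mu_h", "n"])

    def _summary(g: pd.Series) -> pd.Series:
        n = g.size
        sem = g.std(ddof=1) / math.sqrt(n) if n > 1 else float("nan")
        return pd.Series({"mean_mu_h": g.mean(), "sem_mu_h": sem, "n": n})

    per_rep = (
        records.groupby(["replicate_id", "cell_type"], sort=True)["mu_h"]
        .apply(_summary)
        .unstack()
        .reset_index()
    )
    pooled = records.groupby("cell_type", sort=True)["mu_h"].apply(_summary).unstack().reset_index()
    pooled.insert(0, "replicate_id", "pooled")
    out = pd.concat([per_rep, pooled], ignore_index=True)
    out["n"] = out["n"].astype(int)
    return out
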