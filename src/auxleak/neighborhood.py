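"""Local neighborhood composition and rank-correlation statistics.

Each cell's microenvironment is summarized by the local auxotroph fraction:
the area occupied by auxotroph cells divided by the total cell area within a
circular neighborhood (5 um radius by default) centered on the focal cell's
centroid, excluding the focal cell itself.  The link between this covariate
and single-cell growth is quantified with Spearman rank correlations whose
significance is assessed by permutation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import TRACK_KEY

DEFAULT_RADIUS_UM = 5.0
DEFAULT_RADII_UM = (5.0, 9.0, 13.0)
DEFAULT_N_PERMUTATIONS = 10_000


def frame_aux_fractions(x, y, area, is_aux, radius_um: float, focal_mask=None):
    """Local auxotroph area fraction for every cell in one frame.

    A neighbor contributes its full area iff its centroid lies within
    ``radius_um`` of the focal centroid (centroid-inclusion rule); the focal
    cell is excluded.  Returns an array aligned with the inputs, NaN where a
    cell has no neighbor within the radius.  ``focal_mask`` restricts the
    cells the fraction is evaluated for (others get NaN) without changing
    who counts as a neighbor.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    area = np.asarray(area, float)
    aux = np.asarray(is_aux, bool)
    n = x.size
    out = np.full(n, np.nan)
    if n == 0:
        return out
    foc = np.arange(n) if focal_mask is None else np.flatnonzero(np.asarray(focal_mask, bool))
    if foc.size == 0:
        return out
    inside = (x[foc, None] - x[None, :]) ** 2 + (y[foc, None] - y[None, :]) ** 2 <= radius_um**2
    inside[np.arange(foc.size), foc] = False
    tot = inside @ area
    aux_area = inside @ (area * aux)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[foc] = np.where(tot > 0, aux_area / tot, np.nan)
    return out


def local_aux_fraction(
    table: pd.DataFrame,
    frame: int,
    replicate_id: str,
    chamber_id: str,
    track_id: int,
    radius_um: float = DEFAULT_RADIUS_UM,
) -> float:
    """Local auxotroph fraction of one focal cell at one frame.

    Raises ``ValueError`` if the focal track is absent at the frame or the
    radius is not positive.  Returns NaN when no neighbor centroid falls
    within the radius.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be strictly positive")
    sub = table[
        (table["replicate_id"] == replicate_id)
        & (table["chamber_id"] == chamber_id)
        & (table["frame"] == frame)
    ]
    focal = sub["track_id"] == track_id
    if not focal.any():
        raise ValueError(
            f"focal track {track_id} absent at frame {frame} of {replicate_id}/{chamber_id}"
        )
    frac = frame_aux_fractions(
        sub["x_um"], sub["y_um"], sub["area_um2"], sub["cell_type"] == "AUX", radius_um
    )
    return float(frac[np.flatnonzero(focal.to_numpy())[0]])


def rasterized_aux_fraction(
    shapes: list[dict],
    focal_index: int,
    radius_um: float,
    um_per_pixel: float = 0.065,
) -> float:
    """Pixel-area variant of the local auxotroph fraction.

    ``shapes`` are axis-aligned rectangles (``{"kind": "rect", "x", "y",
    "width", "height", "is_aux"}``) or discs (``{"kind": "disc", "x", "y",
    "radius", "is_aux"}``) in micrometres.  Neighbor pixels whose centers
    fall inside both the shape and the circle of ``radius_um`` around the
    focal centroid are counted; the fraction is AUX pixels over all neighbor
    pixels.  This mirrors how segmented masks would be scored and converges
    to the geometric area fraction as ``um_per_pixel`` shrinks.
    """
    if radius_um <= 0 or um_per_pixel <= 0:
        raise ValueError("radius_um and um_per_pixel must be strictly positive")
    fx, fy = float(shapes[focal_index]["x"]), float(shapes[focal_index]["y"])
    aux_px = 0
    tot_px = 0
    for i, sh in enumerate(shapes):
        if i == focal_index:
            continue
        if sh["kind"] == "rect":
            if sh["width"] <= 0 or sh["height"] <= 0:
                raise ValueError("zero-area shape")
            x0, x1 = sh["x"] - sh["width"] / 2, sh["x"] + sh["width"] / 2
            y0, y1 = sh["y"] - sh["height"] / 2, sh["y"] + sh["height"] / 2
        elif sh["kind"] == "disc":
            if sh["radius"] <= 0:
                raise ValueError("zero-area shape")
            x0, x1 = sh["x"] - sh["radius"], sh["x"] + sh["radius"]
            y0, y1 = sh["y"] - sh["radius"], sh["y"] + sh["radius"]
        else:
            raise ValueError(f"unknown shape kind {sh['kind']!r}")
        # pixel centers at (k + 0.5) * um_per_pixel on a global grid
        ix = np.arange(np.floor(x0 / um_per_pixel), np.ceil(x1 / um_per_pixel) + 1)
        iy = np.arange(np.floor(y0 / um_per_pixel), np.ceil(y1 / um_per_pixel) + 1)
        cx = (ix + 0.5) * um_per_pixel
        cy = (iy + 0.5) * um_per_pixel
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        if sh["kind"] == "rect":
            in_shape = (gx >= x0) & (gx <= x1) & (gy >= y0) & (gy <= y1)
        else:
            in_shape = (gx - sh["x"]) ** 2 + (gy - sh["y"]) ** 2 <= sh["radius"] ** 2
        in_circle = (gx - fx) ** 2 + (gy - fy) ** 2 <= radius_um**2
        count = int(np.count_nonzero(in_shape & in_circle))
        tot_px += count
        if sh["is_aux"]:
            aux_px += count
    return aux_px / tot_px if tot_px else float("nan")


def lifetime_fraction(
    table: pd.DataFrame,
    radius_um: float = DEFAULT_RADIUS_UM,
    focal_types: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Lifetime-mean local auxotroph fraction for every track.

    The per-frame fraction is computed with the centroid rule within each
    (replicate, chamber, frame) and averaged over the track's frames; frames
    without any neighbor are skipped.  Returns one record per track with
    columns replicate_id, chamber_id, track_id, cell_type, radius_um,
    aux_fraction (NaN if never defined), n_frames_defined and
    n_neighbor_cells (mean neighbor count over defined frames).

    ``focal_types`` restricts the focal cells (e.g. ``("AUX",)``) while all
    cells still count as neighbors; None computes records for every track.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be strictly positive")
    if table.empty:
        return pd.DataFrame(
            columns=TRACK_KEY
            + ["cell_type", "radius_um", "aux_fraction", "n_frames_defined", "n_neighbor_cells"]
        )
    x_all = table["x_um"].to_numpy(float)
    y_all = table["y_um"].to_numpy(float)
    area_all = table["area_um2"].to_numpy(float)
    aux_all = (table["cell_type"] == "AUX").to_numpy()
    frac_all = np.full(len(table), np.nan)
    nnb_all = np.zeros(len(table))
    focal_all = (
        table["cell_type"].isin(focal_types).to_numpy()
        if focal_types is not None
        else np.ones(len(table), dtype=bool)
    )
    for rows in table.groupby(["replicate_id", "chamber_id", "frame"], sort=False).indices.values():
        foc = rows[focal_all[rows]]
        if foc.size == 0:
            continue
        x, y = x_all[rows], y_all[rows]
        fx, fy = x_all[foc], y_all[foc]
        inside = (fx[:, None] - x[None, :]) ** 2 + (fy[:, None] - y[None, :]) ** 2 <= radius_um**2
        # the focal cell never counts as its own neighbor
        self_pos = np.searchsorted(rows, foc)
        inside[np.arange(foc.size), self_pos] = False
        area = area_all[rows]
        tot = inside @ area
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_all[foc] = np.where(tot > 0, (inside @ (area * aux_all[rows])) / tot, np.nan)
        nnb_all[foc] = inside.sum(axis=1)
    per_frame = table.loc[focal_all, TRACK_KEY + ["cell_type"]].copy()
    per_frame["aux_fraction"] = frac_all[focal_all]
    per_frame["n_neighbor_cells"] = nnb_all[focal_all]
    rec = (
        per_frame.groupby(TRACK_KEY + ["cell_type"], sort=False)
        .agg(
            aux_fraction=("aux_fraction", "mean"),
            n_frames_defined=("aux_fraction", "count"),
            n_neighbor_cells=("n_neighbor_cells", "mean"),
        )
        .reset_index()
    )
    rec.insert(4, "radius_um", radius_um)
    return rec


def _centered_ranks(v: np.ndarray) -> np.ndarray:
    r = rankdata(v, method="average")
    return r - r.mean()


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Ties receive average (mid) ranks, which is the tie-corrected estimator.
    Raises ``ValueError`` for fewer than 3 pairs or zero rank variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    rx = _centered_ranks(x)
    ry = _centered_ranks(y)
    nx = np.sqrt(rx @ rx)
    ny = np.sqrt(ry @ ry)
    if nx == 0 or ny == 0:
        raise ValueError("zero rank variance: correlation undefined")
    return float((rx @ ry) / (nx * ny))


def permutation_pvalue(
    x,
    y,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | np.random.Generator | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Permutation test of the Spearman correlation.

    ``y`` is shuffled against ``x`` ``n_perm`` times; the p-value is the
    plain fraction of permutations whose correlation is at least as extreme
    as the observed one (|rho| for the two-sided test), so its resolution
    floor is 1/n_perm and p = 0 is attainable.  Deterministic given a seed.

    Returns ``(rho_obs, p)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if seed is None:
        raise ValueError("a seed (or Generator) is required for reproducibility")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rho_obs = spearman_rho(x, y)
    rx = _centered_ranks(x)
    ry = _centered_ranks(y)
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    # all Spearman values via one rank pass: shuffle centered ranks of y
    count = 0
    chunk = max(1, min(n_perm, int(2e7 // max(1, x.size))))
    done = 0
    tol = 1e-12  # absorb round-off so exact re-draws of the observed pattern count
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perm = rng.permuted(np.broadcast_to(ry, (m, ry.size)), axis=1)
        rho_perm = (perm @ rx) / denom
        if alternative == "two-sided":
            count += int(np.count_nonzero(np.abs(rho_perm) >= abs(rho_obs) - tol))
        elif alternative == "less":
            count += int(np.count_nonzero(rho_perm <= rho_obs + tol))
        else:
            count += int(np.count_nonzero(rho_perm >= rho_obs - tol))
        done += m
    return rho_obs, count / n_perm


def radius_sweep(
    growth_records: pd.DataFrame,
    table: pd.DataFrame,
    radii=DEFAULT_RADII_UM,
    n_perm: int = DEFAULT_N_PERMUTATIONS,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Pooled growth-composition correlation per radius and cell type.

    For each neighborhood radius, recomputes lifetime-mean fractions, joins
    them to the growth records and reports (radius_um, cell_type, rho, p, n)
    with cells pooled across replicates.  Groups with undefined correlation
    (fewer than 3 cells or zero rank variance) are reported with NaN.
    """
    radii = list(radii)
    if len(set(radii)) != len(radii):
        raise ValueError("radii must be distinct")
    if any(r <= 0 for r in radii):
        raise ValueError("radii must be strictly positive")
    rng = np.random.default_rng(seed)
    rows = []
    for radius in radii:
        frac = lifetime_fraction(table, radius_um=radius)
        merged = growth_records.merge(
            frac[TRACK_KEY + ["aux_fraction"]], on=TRACK_KEY, how="inner"
        ).dropna(subset=["aux_fraction"])
        for cell_type, sub in merged.groupby("cell_type", sort=True):
            try:
                rho, p = permutation_pvalue(
                    sub["aux_fraction"], sub["mu_h"], n_perm=n_perm, seed=rng
                )
            except ValueError:
                rho, p = float("nan"), float("nan")
            rows.append(
                {"radius_um": radius, "cell_type": cell_type, "rho": rho, "p": p, "n": len(sub)}
            )
    return pd.DataFrame(rows)


def bin_growth_by_fraction(
    records: pd.DataFrame, mode: str = "fixed_width", k: int = 4
) -> pd.DataFrame:
    """Bin growth rates by local auxotroph fraction, for visualization only.

    ``fixed_width`` uses k equal bins on [0, 1]; ``quartile`` (k=4) uses the
    empirical quartiles of the fraction.  Returns per-bin edges, median,
    quartiles and counts.  Inference is always done on the continuous data;
    this summary exists to describe the trend.
    """
    rec = records.dropna(subset=["aux_fraction", "mu_h"])
    if mode == "fixed_width":
        edges = np.linspace(0.0, 1.0, k + 1)
    elif mode == "quartile":
        if len(rec) < k:
            raise ValueError(f"need at least {k} records for quartile binning")
        f = rec["aux_fraction"].to_numpy()
        if np.all(f == f[0]):
            raise ValueError("all fractions identical: quartile bins undefined")
        edges = np.quantile(f, np.linspace(0.0, 1.0, k + 1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    idx = np.clip(np.searchsorted(edges, rec["aux_fraction"].to_numpy(), side="right") - 1, 0, k - 1)
    rows = []
    for b in range(k):
        vals = rec["mu_h"].to_numpy()[idx == b]
        rows.append(
            {
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "n": vals.size,
                "median_mu_h": float(np.median(vals)) if vals.size else float("nan"),
                "q1_mu_h": float(np.quantile(vals, 0.25)) if vals.size else float("nan"),
                "q3_mu_h": float(np.quantile(vals, 0.75)) if vals.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)
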