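"""Synthetic microfluidic-chamber track tables.

Generates per-cell per-frame observations with the statistical structure the
downstream analysis assumes: a monolayer chamber seeded with ~90% wildtype
and ~10% auxotroph cells, exponential cell-length growth with division,
multiplicative length measurement noise, occasional spurious length jumps
(segmentation errors), spatial clustering of mutant lineages, washout at the
open chamber side, and auxotroph growth rates that decline with the local
auxotroph fraction.

Geometry is deliberately simple: cells are 1-um-wide rods stacked in fixed
vertical columns.  Cells in a column touch; as lengths grow, everything
below is pushed toward the open side (y = 0, adjacent to the main feeding
channel) and washed out when the centroid crosses it.  Daughters stay
adjacent to the mother in her column, which produces the clonal clusters
that drive the neighborhood effect.  This shoving rule is an explicit
modeling invention: it reproduces boundary retention and lineage clustering
qualitatively, not cell mechanics.

The growth rule re-uses the analysis' own 5-um centroid neighborhood rule
each frame, so generator and analyzer agree by construction.  Two coupling
modes are available:

- ``linear``: an auxotroph at local auxotroph fraction f grows at
  ``mu_wt * max(0, r0 + beta * f)`` (r0 = 0.23/0.70 by default, echoing the
  observed regime; beta < 0 penalizes clustering);
- ``model``: the auxotroph grows at ``mu_wt * r`` with r from the exchange
  model, the wildtype leakage flux scaled by the local wildtype fraction
  (1 - f).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import COLUMNS, concat_tracks
from .model import fitness_benefit, relative_growth_from_fluxes
from .neighborhood import frame_aux_fractions

__all__ = ["SyntheticConfig", "generate_chamber", "generate_replicates", "ground_truth"]

TRUTH_COLUMNS = [
    "replicate_id",
    "chamber_id",
    "track_id",
    "cell_type",
    "true_mu_h",
    "mean_aux_fraction",
    "n_intervals",
    "parent_id",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic chamber experiment.

    Defaults mirror the experimental setup: 40 x 40 um chambers seeded with
    ~10% auxotrophs, 5-minute frames over 12 h, five biological replicates
    with an average of five chambers each, wildtype rate 0.70 h^-1.
    """

    chamber_side_um: float = 40.0
    aux_seed_fraction: float = 0.10
    n_initial_cells: int = 60
    mu_wt_h: float = 0.70
    coupling_mode: str = "linear"  # "linear" or "model"
    beta: float = -0.5
    r0: float = 0.23 / 0.70
    # model-mode parameters (shared leakage rate, exchange-model constants)
    leakage_rate_h: float = 0.01
    mu_max_aux_h: float = 0.90
    k_m: float = 1.0
    epsilon: float = 1.0
    i_c_factor: float = 20.0
    division_length_um: float = 4.0
    birth_length_um: float = 2.0
    cell_width_um: float = 1.0
    length_noise_cv: float = 0.02
    jump_probability: float = 0.005
    washout: bool = True
    duration_h: float = 12.0
    frame_interval_min: float = 5.0
    n_replicates: int = 5
    n_chambers: int = 5
    replicate_sd_h: float = 0.01
    exclusion_margin_um: float = 8.0
    neighborhood_radius_um: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.aux_seed_fraction <= 1.0:
            raise ValueError("aux_seed_fraction must lie in [0, 1]")
        if not self.division_length_um > self.birth_length_um > 0:
            raise ValueError("need division_length_um > birth_length_um > 0")
        for name in (
            "chamber_side_um",
            "mu_wt_h",
            "cell_width_um",
            "duration_h",
            "frame_interval_min",
            "neighborhood_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("length_noise_cv", "jump_probability", "replicate_sd_h", "leakage_rate_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.coupling_mode not in ("linear", "model"):
            raise ValueError("coupling_mode must be 'linear' or 'model'")
        if self.n_initial_cells < 1 or self.n_replicates < 1 or self.n_chambers < 1:
            raise ValueError("cell, replicate and chamber counts must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h * 60.0 / self.frame_interval_min)) + 1


def _aux_relative_rate(cfg: SyntheticConfig, f: np.ndarray) -> np.ndarray:
    """Auxotroph growth rate relative to wildtype at local aux fraction f."""
    if cfg.coupling_mode == "linear":
        return np.maximum(0.0, cfg.r0 + cfg.beta * f)
    s = fitness_benefit(cfg.mu_max_aux_h, cfg.mu_wt_h)
    big_l = cfg.leakage_rate_h * (1.0 - f) * cfg.i_c_factor / cfg.mu_wt_h
    l_tilde = cfg.leakage_rate_h / cfg.mu_max_aux_h
    return np.asarray(
        relative_growth_from_fluxes(big_l, l_tilde, s, cfg.epsilon, cfg.k_m), dtype=float
    )


class _CellStore:
    """Growable flat arrays of per-cell state; the array index is the track id."""

    def __init__(self, capacity: int = 4096):
        self.n = 0
        self.length = np.empty(capacity)
        self.aux = np.zeros(capacity, dtype=bool)
        self.col = np.zeros(capacity, dtype=np.int32)
        self.parent = np.full(capacity, -1, dtype=np.int64)
        self.n_int = np.zeros(capacity, dtype=np.int32)
        self.sum_mu = np.zeros(capacity)
        self.sum_f = np.zeros(capacity)

    def _ensure(self, extra: int) -> None:
        need = self.n + extra
        cap = self.length.size
        if need <= cap:
            return
        new_cap = max(need, 2 * cap)
        for name in ("length", "aux", "col", "parent", "n_int", "sum_mu", "sum_f"):
            arr = getattr(self, name)
            grown = np.full(new_cap, -1, dtype=arr.dtype) if name == "parent" else np.zeros(
                new_cap, dtype=arr.dtype
            )
            grown[: self.n] = arr[: self.n]
            setattr(self, name, grown)

    def add(self, length: float, aux: bool, col: int, parent: int = -1) -> int:
        self._ensure(1)
        i = self.n
        self.length[i] = length
        self.aux[i] = aux
        self.col[i] = col
        self.parent[i] = parent
        self.n += 1
        return i


def _simulate_chamber(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    replicate_id: str,
    chamber_id: str,
    mu_offset_h: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    dt = cfg.frame_interval_min / 60.0
    side = cfg.chamber_side_um
    n_cols = max(1, int(side // (2.0 * cfg.cell_width_um)))
    col_x = (np.arange(n_cols) + 0.5) * side / n_cols

    # cells stacked per column, ordered from the closed wall (y = side)
    # toward the open side (y = 0)
    store = _CellStore(max(4096, 4 * cfg.n_initial_cells))
    cols: list[list[int]] = [[] for _ in range(n_cols)]
    aux_draw = rng.random(cfg.n_initial_cells) < cfg.aux_seed_fraction
    init_len = rng.uniform(cfg.birth_length_um, cfg.division_length_um, cfg.n_initial_cells)
    for i in range(cfg.n_initial_cells):
        cols[i % n_cols].append(store.add(float(init_len[i]), bool(aux_draw[i]), i % n_cols))

    out_frames: list[int] = []
    out_idx: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    out_obs: list[np.ndarray] = []
    sigma = float(np.sqrt(np.log1p(cfg.length_noise_cv**2)))
    mu_wt = cfg.mu_wt_h + mu_offset_h

    for frame in range(cfg.n_frames):
        # stack each column from the closed wall downward; washed-out cells
        # (centroid past the open boundary) form a suffix of the stack
        idx_parts: list[np.ndarray] = []
        y_parts: list[np.ndarray] = []
        for c in range(n_cols):
            if not cols[c]:
                continue
            ci = np.asarray(cols[c], dtype=np.intp)
            ls = store.length[ci]
            centers = side - np.cumsum(ls) + ls / 2.0
            if cfg.washout and centers[-1] < 0.0:
                keep = int(np.count_nonzero(centers >= 0.0))
                cols[c] = cols[c][:keep]
                ci, centers = ci[:keep], centers[:keep]
            idx_parts.append(ci)
            y_parts.append(centers)
        if not idx_parts:
            break
        idx = np.concatenate(idx_parts)
        y = np.concatenate(y_parts)
        x = col_x[store.col[idx]]
        true_len = store.length[idx]
        aux = store.aux[idx]

        # observation: multiplicative lognormal noise plus rare spurious jumps
        obs = true_len.copy()
        if sigma > 0:
            obs = obs * np.exp(rng.normal(0.0, sigma, obs.size))
        if cfg.jump_probability > 0:
            jump = rng.random(obs.size) < cfg.jump_probability
            if jump.any():
                mag = rng.uniform(1.16, 1.5, int(jump.sum()))
                sign = rng.choice((-1.0, 1.0), int(jump.sum()))
                obs[jump] = obs[jump] * mag**sign
        visible = y >= 0.0  # relevant only when washout is off
        out_frames.append(frame)
        out_idx.append(idx[visible])
        out_y.append(y[visible])
        out_obs.append(obs[visible])

        if frame == cfg.n_frames - 1:
            break

        # growth rates from the current neighborhood composition; only
        # auxotroph rates depend on it, so evaluate at auxotroph focals
        f = frame_aux_fractions(
            x, y, true_len * cfg.cell_width_um, aux, cfg.neighborhood_radius_um, focal_mask=aux
        )
        f = np.nan_to_num(f, nan=0.0)  # an isolated cell sees no auxotrophs
        mu = np.where(aux, mu_wt * _aux_relative_rate(cfg, f), mu_wt)
        store.n_int[idx] += 1
        store.sum_mu[idx] += mu
        store.sum_f[idx] += f
        new_len = true_len * np.exp(mu * dt)
        store.length[idx] = new_len

        # division: mother splits into two adjacent daughters of half length
        dividing = idx[new_len >= cfg.division_length_um]
        if dividing.size:
            div_set = set(dividing.tolist())
            for c in np.unique(store.col[dividing]):
                new_col: list[int] = []
                for i in cols[c]:
                    if i in div_set:
                        half = store.length[i] / 2.0
                        a = bool(store.aux[i])
                        new_col.append(store.add(half, a, c, parent=i))
                        new_col.append(store.add(half, a, c, parent=i))
                    else:
                        new_col.append(i)
                cols[c] = new_col

    if out_idx:
        all_idx = np.concatenate(out_idx)
        all_y = np.concatenate(out_y)
        frame_col = np.repeat(out_frames, [a.size for a in out_idx])
        keep = all_y >= cfg.exclusion_margin_um
        obs_len = np.concatenate(out_obs)[keep]
        tracks = pd.DataFrame(
            {
                "replicate_id": replicate_id,
                "chamber_id": chamber_id,
                "frame": frame_col[keep],
                "time_h": frame_col[keep] * dt,
                "track_id": all_idx[keep].astype(np.int64),
                "cell_type": np.where(store.aux[all_idx[keep]], "AUX", "WT"),
                "x_um": col_x[store.col[all_idx[keep]]],
                "y_um": all_y[keep],
                "length_um": obs_len,
                "area_um2": obs_len * cfg.cell_width_um,
            }
        )
    else:
        tracks = pd.DataFrame(columns=COLUMNS)

    seen = np.flatnonzero(store.n_int[: store.n] > 0)
    n_int = store.n_int[seen]
    truth_df = pd.DataFrame(
        {
            "replicate_id": replicate_id,
            "chamber_id": chamber_id,
            "track_id": seen.astype(np.int64),
            "cell_type": np.where(store.aux[seen], "AUX", "WT"),
            "true_mu_h": store.sum_mu[seen] / n_int,
            "mean_aux_fraction": store.sum_f[seen] / n_int,
            "n_intervals": n_int,
            "parent_id": store.parent[seen],
        }
    )
    return tracks, truth_df


def generate_chamber(
    config: SyntheticConfig,
    seed: int | np.random.SeedSequence,
    replicate_id: str = "R1",
    chamber_id: str = "C1",
    mu_offset_h: float = 0.0,
    return_truth: bool = False,
):
    """Simulate one chamber; deterministic given (config, seed).

    Returns the track table, or ``(tracks, truth)`` when ``return_truth``
    is set.  The truth table holds each track's lifetime-mean true growth
    rate and local auxotroph fraction, joinable on
    (replicate_id, chamber_id, track_id).  ``mean_aux_fraction`` is the
    growth-relevant covariate and is tracked for auxotroph cells; wildtype
    rates do not depend on it and their entry is 0.
    """
    if seed is None:
        raise ValueError("an explicit seed is required (no implicit global randomness)")
    rng = np.random.default_rng(seed)
    tracks, truth = _simulate_chamber(config, rng, replicate_id, chamber_id, mu_offset_h)
    return (tracks, truth) if return_truth else tracks


def ground_truth(config: SyntheticConfig, seed: int | np.random.SeedSequence) -> pd.DataFrame:
    """Per-track true rates for the chamber :func:`generate_chamber` yields."""
    _, truth = generate_chamber(config, seed, return_truth=True)
    return truth


def generate_replicates(
    config: SyntheticConfig,
    seed: int,
    return_truth: bool = False,
):
    """Simulate ``n_replicates`` x ``n_chambers`` chambers.

    Each replicate gets its own wildtype-rate offset drawn from
    Normal(0, replicate_sd_h), emulating between-experiment variation;
    replicate ids are "R1".."Rn", chamber ids "C1".."Cm".
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    ss = np.random.SeedSequence(seed)
    rep_seqs = ss.spawn(config.n_replicates)
    tables = []
    truths = []
    for r, rep_seq in enumerate(rep_seqs, start=1):
        children = rep_seq.spawn(config.n_chambers + 1)
        offset = float(
            np.random.default_rng(children[0]).normal(0.0, config.replicate_sd_h)
        )
        for c in range(1, config.n_chambers + 1):
            tracks, truth = _simulate_chamber(
                config, np.random.default_rng(children[c]), f"R{r}", f"C{c}", offset
            )
            tables.append(tracks)
            truths.append(truth)
    table = concat_tracks(tables)
    if not return_truth:
        return table
    truth_all = pd.concat(truths, ignore_index=True)[TRUTH_COLUMNS]
    return table, truth_all
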