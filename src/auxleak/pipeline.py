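"""End-to-end analysis pipeline over a synthetic chamber experiment.

Chains simulate -> growth fitting -> neighborhood statistics -> replicate
tests -> exchange-model heatmap -> leakage inference, writing every stage's
output as CSV/JSON so any stage can be re-run from its predecessor's file.
Deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import growth, inference, io, neighborhood, simulate, stats
from .config import RunConfig
from .model import critical_leakage, fitness_benefit, growth_heatmap

logger = logging.getLogger("auxleak")

__all__ = ["run_pipeline", "heatmap_long"]


def heatmap_long(
    leakage_grid, benefit_grid, mu_wt: float, epsilon: float, k_m: float, i_c_factor: float
) -> pd.DataFrame:
    """Relative-growth heatmap in long format (leakage, benefit, r)."""
    r = growth_heatmap(leakage_grid, benefit_grid, mu_wt, epsilon, k_m, i_c_factor)
    leak, ben = np.meshgrid(leakage_grid, benefit_grid)
    return pd.DataFrame(
        {"leakage_rate_h": leak.ravel(), "growth_benefit": ben.ravel(), "relative_growth": r.ravel()}
    )


def run_pipeline(config: RunConfig, seed: int | None = None, out_dir: str | Path = "results") -> dict:
    """Run the full analysis; write stage outputs under ``out_dir``.

    Returns a bundle with the in-memory stage results.  Outputs written:
    tracks.csv, truth.csv, growth.csv, exclusions.json, neighborhood.csv,
    radius_sweep.csv, binned_growth.csv, paired_t.json, heatmap.csv,
    contour.csv, inference.json, summary.json, run_config.yaml.
    """
    seed = config.seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    logger.info("pipeline start: seed=%d out=%s", seed, out)

    # --- simulate -----------------------------------------------------------
    cfg = config.synthetic
    tracks, truth = simulate.generate_replicates(cfg, seed, return_truth=True)
    io.write_tracks(tracks, out / "tracks.csv")
    truth.to_csv(out / "truth.csv", index=False)

    # --- growth rates -------------------------------------------------------
    filtered, excl = growth.filter_tracks(
        tracks, config.filters.max_rel_length_change, config.filters.min_frames
    )
    records = growth.apply_r2_filter(growth.fit_growth(filtered), config.filters.min_r2)
    excl["low_r2"] = int(excl["retained"] - len(records))
    excl["retained"] = int(len(records))
    records.to_csv(out / "growth.csv", index=False)
    (out / "exclusions.json").write_text(json.dumps(excl, indent=2))
    summary = growth.summarize_growth(records)
    summary.to_csv(out / "growth_summary.csv", index=False)

    # --- neighborhood composition and correlations --------------------------
    radius0 = config.neighborhood_radii_um[0]
    frac = neighborhood.lifetime_fraction(tracks, radius_um=radius0)
    frac.to_csv(out / "neighborhood.csv", index=False)
    merged = records.merge(
        frac[io.TRACK_KEY + ["aux_fraction"]], on=io.TRACK_KEY, how="left"
    )
    sweep = neighborhood.radius_sweep(
        records,
        tracks,
        radii=config.neighborhood_radii_um,
        n_perm=config.n_permutations,
        seed=seed + 1,
    )
    sweep.to_csv(out / "radius_sweep.csv", index=False)
    aux_merged = merged[merged["cell_type"] == "AUX"].dropna(subset=["aux_fraction"])
    binned = (
        neighborhood.bin_growth_by_fraction(aux_merged, mode="quartile")
        if len(aux_merged) >= 4 and aux_merged["aux_fraction"].nunique() > 1
        else pd.DataFrame()
    )
    binned.to_csv(out / "binned_growth.csv", index=False)

    # --- replicate-level test -----------------------------------------------
    per_rep = summary[summary["replicate_id"] != "pooled"].pivot(
        index="replicate_id", columns="cell_type", values="mean_mu_h"
    )
    paired = None
    if {"WT", "AUX"} <= set(per_rep.columns) and per_rep.dropna().shape[0] >= 2:
        clean = per_rep.dropna()
        paired = stats.paired_t_test(clean["WT"], clean["AUX"])
        (out / "paired_t.json").write_text(json.dumps(paired.to_dict(), indent=2))

    # --- exchange model heatmap + equal-growth contour -----------------------
    m = config.model
    s_default = fitness_benefit(m.mu_max_aux, m.mu_wt)
    leak_grid = np.geomspace(1e-4, 1.0, 60)
    ben_grid = np.linspace(1.02, 1.6, 30)
    hm = heatmap_long(leak_grid, ben_grid, m.mu_wt, m.epsilon, m.k_m, m.i_c_factor)
    hm.to_csv(out / "heatmap.csv", index=False)
    # the equal-growth contour only exists above the shared-leakage benefit
    # floor (r saturates below 1 for smaller benefits)
    u_min = (1.0 + np.sqrt(1.0 + 4.0 / (m.epsilon * m.i_c_factor))) / 2.0
    contour_ben = np.linspace(u_min + 0.01, 1.6, 30)
    contour = pd.DataFrame(
        {
            "growth_benefit": contour_ben,
            "critical_big_l": [
                critical_leakage(b - 1.0, m.epsilon, mu_wt=m.mu_wt, i_c_factor=m.i_c_factor, k_m=m.k_m)
                for b in contour_ben
            ],
        }
    )
    contour["critical_leakage_rate_h"] = contour["critical_big_l"] * m.mu_wt / m.i_c_factor
    contour.to_csv(out / "contour.csv", index=False)

    # --- leakage inference ---------------------------------------------------
    result = None
    if len(aux_merged) >= 3 and aux_merged["aux_fraction"].nunique() > 1:
        result = inference.infer_from_records(
            aux_merged, m.mu_wt, m.mu_max_aux, m.epsilon, m.k_m, m.i_c_factor
        )
        (out / "inference.json").write_text(json.dumps(result.to_dict(), indent=2))

    # --- summary report -------------------------------------------------------
    pooled = summary[summary["replicate_id"] == "pooled"].set_index("cell_type")
    report = {
        "seed": seed,
        "n_tracks_retained": int(len(records)),
        "exclusions": excl,
        "pooled_mean_mu_h": {k: float(v) for k, v in pooled["mean_mu_h"].items()},
        "pooled_sem_mu_h": {k: float(v) for k, v in pooled["sem_mu_h"].items()},
        "doubling_time_min": {
            k: growth.doubling_time_min(v) for k, v in pooled["mean_mu_h"].items() if v > 0
        },
        "radius_sweep": sweep.to_dict(orient="records"),
        "paired_t": paired.to_dict() if paired else None,
        "inference": result.to_dict() if result else None,
        "critical_big_l_at_default_s": critical_leakage(
            s_default, m.epsilon, mu_wt=m.mu_wt, i_c_factor=m.i_c_factor, k_m=m.k_m
        ),
    }
    (out / "summary.json").write_text(json.dumps(report, indent=2))
    logger.info("pipeline done: %d tracks retained", len(records))
    return {
        "tracks": tracks,
        "truth": truth,
        "growth": records,
        "growth_summary": summary,
        "neighborhood": frac,
        "merged": merged,
        "radius_sweep": sweep,
        "binned": binned,
        "paired_t": paired,
        "heatmap": hm,
        "contour": contour,
        "inference": result,
        "summary": report,
    }
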