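#!/usr/bin/env python
"""Exchange-model heatmap and equal-growth contour.

Evaluates the leakage/uptake model over a grid of shared leakage rates and
growth benefits (1+s), writes the relative-growth heatmap and the critical
leakage contour (the break-even line where auxotroph and wildtype grow
equally fast).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from auxleak.config import ModelConfig
from auxleak.model import critical_leakage, fitness_benefit, shared_leakage_growth_limit
from auxleak.pipeline import heatmap_long


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    m = ModelConfig()
    leak = np.geomspace(1e-4, 1.0, 60)
    benefit = np.linspace(1.02, 1.6, 30)
    hm = heatmap_long(leak, benefit, m.mu_wt, m.epsilon, m.k_m, m.i_c_factor)
    hm.to_csv(args.out_dir / "heatmap.csv", index=False)

    # the contour exists only above the shared-leakage benefit floor
    u_min = (1.0 + np.sqrt(1.0 + 4.0 / (m.epsilon * m.i_c_factor))) / 2.0
    ben = np.linspace(u_min + 0.01, 1.6, 30)
    contour = pd.DataFrame(
        {
            "growth_benefit": ben,
            "critical_big_l": [
                critical_leakage(b - 1, m.epsilon, mu_wt=m.mu_wt, i_c_factor=m.i_c_factor)
                for b in ben
            ],
        }
    )
    contour["critical_leakage_rate_h"] = contour["critical_big_l"] * m.mu_wt / m.i_c_factor
    contour.to_csv(args.out_dir / "contour.csv", index=False)

    s = fitness_benefit(m.mu_max_aux, m.mu_wt)
    big_l_star = critical_leakage(s, m.epsilon, mu_wt=m.mu_wt, i_c_factor=m.i_c_factor)
    print(f"fitness benefit s = {s:.4f} (growth benefit {1 + s:.4f})")
    print(f"benefit floor for any threshold under shared leakage: {u_min:.4f}")
    print(f"critical relative leakage flux L* = {big_l_star:.4f} "
          f"(leakage rate {big_l_star * m.mu_wt / m.i_c_factor:.4f} h⁻¹)")
    print(f"saturation limit of r at this benefit: "
          f"{shared_leakage_growth_limit(s, m.epsilon, m.i_c_factor):.4f}")


if __name__ == "__main__":
    main()
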