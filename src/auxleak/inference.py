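"""Leakage-rate inference from observed auxotroph growth.

The maximum growth rate an auxotroph reaches when fully surrounded by
wildtype cells is estimated by extrapolating the regression of auxotroph
growth rate on the local wildtype fraction to a wildtype frequency of 1.
Because the exchange model's predicted relative growth rate is strictly
monotone in the leakage rate, the shared leakage rate l (l_aux = l_wt = l)
that reproduces this observed maximum is found by bracketed root finding.
The result is positioned against the critical leakage flux L* at which
auxotroph and wildtype growth would be equal; the ratio L*/L_fit says how
many-fold higher leakage would have to be for auxotrophs to break even.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model import critical_leakage, fitness_benefit, relative_growth_from_fluxes

__all__ = [
    "InferenceResult",
    "extrapolate_max_growth",
    "infer_leakage_rate",
    "fold_to_threshold",
    "infer_from_records",
]


@dataclass(frozen=True)
class InferenceResult:
    """Leakage inference summary.

    ``mu_max_obs`` (h^-1) is the extrapolated auxotroph rate at wildtype
    fraction 1 with its prediction standard error; ``r_obs`` the same rate
    relative to the wildtype; ``l_fit`` the fitted shared leakage rate
    (h^-1) and ``big_l_fit`` the corresponding relative leakage flux;
    ``big_l_star`` the critical flux; ``fold_to_threshold`` their ratio
    (inf, flagged, when the fitted leakage is zero).
    """

    mu_max_obs: float
    stderr: float
    r_obs: float
    l_fit: float
    big_l_fit: float
    big_l_star: float
    fold_to_threshold: float
    n_cells: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def extrapolate_max_growth(
    aux_records: pd.DataFrame,
    fraction_col: str = "aux_fraction",
    rate_col: str = "mu_h",
) -> tuple[float, float]:
    """Extrapolate auxotroph growth to a fully wildtype neighborhood.

    OLS of growth rate on local wildtype fraction (1 - aux_fraction),
    evaluated at wildtype fraction 1; the returned standard error is that of
    the predicted mean at the extrapolation point.
    """
    rec = aux_records.dropna(subset=[fraction_col, rate_col])
    if len(rec) < 3:
        raise ValueError("need at least 3 auxotroph records")
    f_wt = 1.0 - rec[fraction_col].to_numpy(float)
    if np.all(f_wt == f_wt[0]):
        raise ValueError("constant wildtype-fraction covariate: extrapolation undefined")
    design = sm.add_constant(f_wt)
    fit = sm.OLS(rec[rate_col].to_numpy(float), design).fit()
    pred = fit.get_prediction(np.array([[1.0, 1.0]]))
    return float(pred.predicted_mean[0]), float(pred.se_mean[0])


def infer_leakage_rate(
    mu_max_obs: float,
    mu_wt: float = 0.70,
    mu_max_aux: float = 0.90,
    epsilon: float = 1.0,
    k_m: float = 1.0,
    i_c_factor: float = 20.0,
    rtol: float = 1e-12,
) -> tuple[float, float]:
    """Shared leakage rate explaining an observed auxotroph maximum rate.

    Solves r(l) = mu_max_obs / mu_wt for the shared rate l (l_aux = l_wt),
    with L = l * i_c_factor / mu_wt and l_tilde = l / mu_max_aux, by
    bisection on the monotone map.  Returns ``(l_fit, big_l_fit)``.

    Raises ``ValueError`` if the target is outside (0, 1+s): no finite
    leakage can explain a relative rate at or above the supremum 1 + s.
    """
    s = fitness_benefit(mu_max_aux, mu_wt)
    r_target = mu_max_obs / mu_wt
    if r_target <= 0:
        raise ValueError("observed maximum growth rate must be strictly positive")
    if r_target >= 1.0 + s:
        raise ValueError(
            f"relative rate {r_target:.4f} >= 1 + s = {1 + s:.4f}: unattainable for finite leakage"
        )

    def g(l: float) -> float:
        return (
            relative_growth_from_fluxes(
                l * i_c_factor / mu_wt, l / mu_max_aux, s, epsilon, k_m
            )
            - r_target
        )

    lo, hi = 0.0, max(mu_wt, 1.0)
    for _ in range(200):
        if g(hi) > 0:
            break
        lo, hi = hi, 2.0 * hi
    else:
        raise RuntimeError("failed to bracket the leakage rate")
    from scipy.optimize import brentq

    l_fit = float(brentq(g, lo, hi, xtol=1e-300, rtol=rtol))
    return l_fit, l_fit * i_c_factor / mu_wt


def fold_to_threshold(
    l_fit: float,
    mu_wt: float = 0.70,
    mu_max_aux: float = 0.90,
    epsilon: float = 1.0,
    k_m: float = 1.0,
    i_c_factor: float = 20.0,
) -> float:
    """How many-fold the fitted leakage falls short of the break-even flux.

    L* / L_fit with L* the critical relative leakage flux under the same
    shared-leakage coupling; > 1 whenever the observed relative rate is
    below 1.  A zero fitted leakage yields inf.
    """
    if l_fit < 0:
        raise ValueError("l_fit must be non-negative")
    s = fitness_benefit(mu_max_aux, mu_wt)
    big_l_star = critical_leakage(
        s, epsilon, mu_wt=mu_wt, i_c_factor=i_c_factor, k_m=k_m
    )
    if l_fit == 0:
        return math.inf
    return big_l_star / (l_fit * i_c_factor / mu_wt)


def infer_from_records(
    aux_records: pd.DataFrame,
    mu_wt: float = 0.70,
    mu_max_aux: float = 0.90,
    epsilon: float = 1.0,
    k_m: float = 1.0,
    i_c_factor: float = 20.0,
) -> InferenceResult:
    """Full inference chain from auxotroph growth/neighborhood records.

    Extrapolates the maximum auxotroph rate, inverts the exchange model for
    the shared leakage rate and reports the fold-change to threshold.
    """
    mu_max_obs, stderr = extrapolate_max_growth(aux_records)
    s = fitness_benefit(mu_max_aux, mu_wt)
    r_obs = mu_max_obs / mu_wt
    degenerate = False
    if mu_max_obs <= 0:
        # extrapolation can undershoot zero on pathological inputs
        l_fit, big_l_fit, fold = 0.0, 0.0, math.inf
        degenerate = True
    else:
        mu_capped = min(mu_max_obs, mu_wt * (1.0 + s) * (1.0 - 1e-12))
        if mu_capped < mu_max_obs:
            degenerate = True
        l_fit, big_l_fit = infer_leakage_rate(
            mu_capped, mu_wt, mu_max_aux, epsilon, k_m, i_c_factor
        )
        fold = fold_to_threshold(l_fit, mu_wt, mu_max_aux, epsilon, k_m, i_c_factor)
    big_l_star = critical_leakage(s, epsilon, mu_wt=mu_wt, i_c_factor=i_c_factor, k_m=k_m)
    return InferenceResult(
        mu_max_obs=mu_max_obs,
        stderr=stderr,
        r_obs=r_obs,
        l_fit=l_fit,
        big_l_fit=big_l_fit,
        big_l_star=big_l_star,
        fold_to_threshold=fold,
        n_cells=int(len(aux_records.dropna(subset=["aux_fraction", "mu_h"]))),
        degenerate=degenerate,
    )
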