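"""Leakage/uptake growth model for an auxotroph in a producer population.

The model gives the highest growth rate an amino-acid auxotroph can reach,
relative to the wildtype, when it is surrounded entirely by producing
(wildtype) cells.  Growth of the auxotroph is Monod-limited by its internal
concentration of the missing amino acid, which in turn is set by the balance
of leakage from producers and uptake/leakage by the auxotroph itself:

    r      = (1 + s) * i_hat / (K_M + i_hat)
    s      = (mu_max_aux - mu_wt) / mu_wt            (fitness benefit)
    i_hat  = K_M * [eps*L - lt + sqrt((eps*L + lt)^2 + 4*eps*L*(1+s))]
                 / (2 * ((1+s) + lt))
    lt     = l_aux / mu_max_aux                      (relative leakage rate)
    L      = l_wt * I_C / (mu_wt * K_M)              (relative leakage flux)

with ``eps`` the auxotroph/wildtype ratio of combined uptake+leakage rates
(1 for identical transporters) and ``I_C`` the internal amino-acid pool of
the producers (20 * K_M by default: producers grow near their maximum rate).
All concentrations are expressed in units of K_M, so only ``I_C / K_M``
(``i_c_factor``) enters the result.

``i_hat`` is the non-negative root of the steady-state balance

    ((1+s) + lt) * x^2 - (eps*L - lt) * x - eps*L = 0,   x = i_hat / K_M,

which the closed form above solves; tests verify the equivalence with an
independent bracketed root-finder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "fitness_benefit",
    "derived_ratios",
    "internal_concentration",
    "relative_growth_rate",
    "relative_growth_from_fluxes",
    "growth_heatmap",
    "critical_leakage",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the leakage/uptake exchange model.

    Rates are in h^-1; ``k_m`` sets the concentration unit; ``i_c_factor``
    is the producer-internal amino-acid concentration in units of ``k_m``.
    """

    mu_wt: float = 0.70
    mu_max_aux: float = 0.90
    l_wt: float = 0.01
    l_aux: float = 0.01
    epsilon: float = 1.0
    k_m: float = 1.0
    i_c_factor: float = 20.0

    def __post_init__(self) -> None:
        if self.mu_wt <= 0 or self.mu_max_aux <= 0:
            raise ValueError("growth rates must be strictly positive")
        if self.epsilon <= 0 or self.k_m <= 0:
            raise ValueError("epsilon and k_m must be strictly positive")
        if self.l_wt < 0 or self.l_aux < 0:
            raise ValueError("leakage rates must be non-negative")

    @property
    def s(self) -> float:
        return fitness_benefit(self.mu_max_aux, self.mu_wt)


def fitness_benefit(mu_max_aux: float, mu_wt: float) -> float:
    """Proportional growth advantage s of the auxotroph over the wildtype.

    ``mu_max_aux`` is the auxotroph's rate with the amino acid non-limiting
    (supplemented conditions); ``mu_wt`` the wildtype rate on minimal medium.
    """
    if mu_max_aux <= 0 or mu_wt <= 0:
        raise ValueError("growth rates must be strictly positive")
    return (mu_max_aux - mu_wt) / mu_wt


def derived_ratios(params: ModelParams) -> tuple[float, float]:
    """Dimensionless leakage quantities (L, l_tilde) from absolute rates.

    L = l_wt * i_c_factor / mu_wt is the wildtype relative leakage flux
    (leaked vs. growth-invested amino acid); l_tilde = l_aux / mu_max_aux is
    the auxotroph leakage rate relative to its maximum growth rate.
    """
    big_l = params.l_wt * params.i_c_factor / params.mu_wt
    l_tilde = params.l_aux / params.mu_max_aux
    return big_l, l_tilde


def internal_concentration(big_l, l_tilde, s, epsilon: float = 1.0, k_m: float = 1.0):
    """Steady-state internal amino-acid concentration i_hat of the auxotroph.

    Closed-form non-negative root of the uptake/leakage balance; accepts
    scalars or numpy arrays (broadcasting).
    """
    big_l = np.asarray(big_l, dtype=float)
    if np.any(big_l < 0) or np.any(np.asarray(l_tilde) < 0):
        raise ValueError("leakage terms must be non-negative")
    if k_m <= 0 or epsilon <= 0:
        raise ValueError("k_m and epsilon must be strictly positive")
    el = epsilon * big_l
    disc = (el + l_tilde) ** 2 + 4.0 * el * (1.0 + s)
    if np.any(disc < 0):  # cannot happen for valid inputs; guard regardless
        raise FloatingPointError("negative discriminant in internal_concentration")
    i_hat = k_m * (el - l_tilde + np.sqrt(disc)) / (2.0 * ((1.0 + s) + l_tilde))
    out = np.maximum(i_hat, 0.0)
    return out.item() if out.ndim == 0 else out


def relative_growth_from_fluxes(big_l, l_tilde, s, epsilon: float = 1.0, k_m: float = 1.0):
    """Auxotroph growth rate relative to wildtype from dimensionless fluxes."""
    i_hat = internal_concentration(big_l, l_tilde, s, epsilon, k_m)
    return (1.0 + s) * i_hat / (k_m + i_hat)


def relative_growth_rate(params: ModelParams) -> float:
    """Relative growth rate r of the auxotroph for absolute-rate parameters.

    r is bounded by the Monod term: 0 <= r <= 1 + s, with r -> 1 + s as the
    producer leakage flux grows without bound and r = 0 without any leakage.
    """
    big_l, l_tilde = derived_ratios(params)
    return float(relative_growth_from_fluxes(big_l, l_tilde, params.s, params.epsilon, params.k_m))


def growth_heatmap(
    leakage_grid,
    benefit_grid,
    mu_wt: float = 0.70,
    epsilon: float = 1.0,
    k_m: float = 1.0,
    i_c_factor: float = 20.0,
) -> np.ndarray:
    """Relative growth rate over a (growth benefit) x (leakage rate) grid.

    ``leakage_grid`` holds shared absolute leakage rates l (h^-1, applied to
    both cell types: l_aux = l_wt = l); ``benefit_grid`` holds growth
    benefits 1 + s.  For each pair, mu_max_aux = (1+s) * mu_wt, so the
    auxotroph relative leakage rate varies consistently with the benefit
    axis.  Returns a matrix with rows indexed by benefit and columns by
    leakage.
    """
    leak = np.asarray(leakage_grid, dtype=float)
    ben = np.asarray(benefit_grid, dtype=float)
    if leak.size == 0 or ben.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(leak <= 0) or np.any(ben <= 0):
        raise ValueError("grid values must be strictly positive")
    s = ben[:, None] - 1.0
    mu_max_aux = ben[:, None] * mu_wt
    l_tilde = leak[None, :] / mu_max_aux
    big_l = leak[None, :] * i_c_factor / mu_wt
    return relative_growth_from_fluxes(big_l, l_tilde, s, epsilon, k_m)


def _expanding_brentq(f, hi0: float, rtol: float = 1e-14) -> float:
    """Root of monotone-increasing f with f(0) < 0, bracketing upward."""
    lo, hi = 0.0, hi0
    for _ in range(200):
        if f(hi) > 0:
            break
        lo, hi = hi, hi * 2.0
    else:
        raise RuntimeError("failed to bracket root")
    return float(brentq(f, lo, hi, xtol=1e-300, rtol=rtol))


def shared_leakage_growth_limit(s: float, epsilon: float = 1.0, i_c_factor: float = 20.0) -> float:
    """Supremum of r as the shared leakage rate grows without bound.

    With l_aux = l_wt = l, the auxotroph's own leakage grows alongside the
    supply, so the internal concentration saturates at
    i_hat_inf = eps * i_c_factor * (1+s) * K_M and r approaches a finite
    limit below 1 + s.  A break-even threshold only exists when this limit
    exceeds 1, i.e. for benefits above
    1 + s_min = (1 + sqrt(1 + 4/(eps * i_c_factor))) / 2.
    """
    i_inf = epsilon * i_c_factor * (1.0 + s)  # in units of K_M
    return (1.0 + s) * i_inf / (1.0 + i_inf)


def critical_leakage(
    s: float,
    epsilon: float = 1.0,
    l_tilde: float | None = None,
    *,
    mu_wt: float | None = None,
    i_c_factor: float = 20.0,
    k_m: float = 1.0,
) -> float:
    """Critical relative leakage flux L* at which r(L*) = 1.

    Above L* the auxotroph outgrows the wildtype (the equal-growth contour
    of the heatmap).  At the root, i_hat = K_M / s.

    Two coupling conventions are supported:

    - fixed ``l_tilde``: the auxotroph relative leakage rate is held at the
      given value while L varies;
    - shared leakage (``l_tilde=None``, requires ``mu_wt``): a single
      absolute rate l feeds both L = l * i_c_factor / mu_wt and
      l_tilde = l / ((1+s) * mu_wt), and L* is reported at the critical l.

    Raises ``ValueError`` for s <= 0: the Monod term keeps r < 1 for every
    finite leakage, so no threshold exists.
    """
    if s <= 0:
        raise ValueError("no critical leakage exists for s <= 0 (r < 1 for all finite L)")
    if l_tilde is not None:
        f = lambda big_l: relative_growth_from_fluxes(big_l, l_tilde, s, epsilon, k_m) - 1.0
        return _expanding_brentq(f, hi0=10.0 * max(1.0, i_c_factor * k_m / s))
    if mu_wt is None:
        raise ValueError("provide either a fixed l_tilde or mu_wt for shared-leakage coupling")
    if shared_leakage_growth_limit(s, epsilon, i_c_factor) <= 1.0:
        raise ValueError(
            "benefit too small: under shared leakage the relative growth rate "
            f"saturates below 1 for s = {s:g} (see shared_leakage_growth_limit)"
        )
    mu_max_aux = (1.0 + s) * mu_wt

    def g(l: float) -> float:
        return (
            relative_growth_from_fluxes(
                l * i_c_factor / mu_wt, l / mu_max_aux, s, epsilon, k_m
            )
            - 1.0
        )

    l_star = _expanding_brentq(g, hi0=max(mu_wt, 1.0))
    return l_star * i_c_factor / mu_wt
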