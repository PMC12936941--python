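"""Replicate-level hypothesis tests.

Strain comparisons are made at the replicate level: the unit of analysis is
the arithmetic mean growth rate of each biological replicate, never the
individual cell, so the paired t-test runs on n = number of replicates.
Kruskal-Wallis tests compare growth-rate distributions across arbitrary
user-defined groups.  Raw p-values are reported; no multiple-testing
correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = ["PairedTestResult", "paired_t_test", "kruskal_wallis", "significance_stars"]


@dataclass(frozen=True)
class PairedTestResult:
    t_stat: float
    p_value: float
    n_pairs: int
    mean_diff: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def paired_t_test(a, b) -> PairedTestResult:
    """Classical paired t-test on per-replicate means.

    Two-sided p from the t distribution with n-1 degrees of freedom.
    Degenerate cases are flagged rather than erroring: identical vectors
    give t = 0, p = 1; zero-variance differences with nonzero mean give an
    infinite t with p = 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean_diff == 0.0:
            return PairedTestResult(0.0, 1.0, n, 0.0, degenerate=True)
        t = math.copysign(math.inf, mean_diff)
        return PairedTestResult(t, 0.0, n, mean_diff, degenerate=True)
    t = mean_diff / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return PairedTestResult(float(t), float(p), n, mean_diff)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-squared p on k-1 df.

    All-identical data across groups yield H = 0, p = 1 (no distributional
    difference) instead of scipy's error.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("groups must be non-empty")
    if sum(g.size for g in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def significance_stars(p: float) -> str:
    """Conventional significance annotation: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
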