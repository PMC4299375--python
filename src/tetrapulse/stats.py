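"""Nonparametric statistics for pulse-feature comparisons.

Group comparisons use the Mann-Whitney U test throughout, with midranks for
ties, an exact null distribution by full enumeration for small samples and
a tie-corrected normal approximation with continuity correction otherwise.
Medians are reported with a bootstrap standard error (the standard error of
a median has no finite-sample closed form).  The slope-conservation test
asks whether the per-cell slope distribution differs between the lowest and
highest UV dose; "conserved" means the test fails to reject at alpha=0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "RankSumResult",
    "SlopeConservationReport",
    "mann_whitney_u",
    "median_sem",
    "slope_conservation_test",
]

#: largest pooled sample size for which the exact enumeration is used
EXACT_LIMIT = 14


@dataclass(frozen=True)
class RankSumResult:
    U: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact" | "normal_approx"


@dataclass
class SlopeConservationReport:
    """Dose-resolved slope medians and the lowest-vs-highest dose contrast."""

    channel: str
    doses: tuple[float, ...]
    median_slopes: tuple[float, ...]
    sems: tuple[float, ...]
    n_per_dose: tuple[int, ...]
    test: RankSumResult
    alpha: float = 0.05

    @property
    def p_value(self) -> float:
        return self.test.p_two_sided

    @property
    def conserved(self) -> bool:
        return self.p_value >= self.alpha


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x, from pooled midranks."""
    n1 = len(x)
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   exact_limit: int = EXACT_LIMIT) -> RankSumResult:
    """Two-sided Mann-Whitney U test.

    Ties receive midranks.  When ``n1 + n2 <= exact_limit`` the two-sided
    p-value is exact: every assignment of the pooled (mid)ranks to the two
    groups is enumerated and the doubled smaller tail (including the
    observed value) is reported, capped at 1.  Larger samples use the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    U = float(ranks[:n1].sum() - offset)

    if n <= exact_limit:
        total = 0
        lo = 0
        hi = 0
        for idx in combinations(range(n), n1):
            u = sum(ranks[i] for i in idx) - offset
            total += 1
            if u <= U + 1e-9:
                lo += 1
            if u >= U - 1e-9:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / total)
        return RankSumResult(U=U, n1=n1, n2=n2, p_two_sided=p, method="exact")

    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum())) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # every observation tied
        return RankSumResult(U=U, n1=n1, n2=n2, p_two_sided=1.0,
                             method="normal_approx")
    diff = U - mu
    cc = 0.5 * math.copysign(1.0, diff) if diff != 0 else 0.0
    z = (diff - cc) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return RankSumResult(U=U, n1=n1, n2=n2, p_two_sided=max(p, 1e-300),
                         method="normal_approx")


def median_sem(x: Sequence[float], n_boot: int = 1000,
               seed: int = 0) -> tuple[float, float]:
    """Median and its bootstrap standard error.

    The SEM is the standard deviation of the median over ``n_boot`` seeded
    resamples with replacement.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    medians = np.median(x[idx], axis=1)
    return float(np.median(x)), float(medians.std(ddof=1))


def slope_conservation_test(features: pd.DataFrame, channel: str,
                            doses: Sequence[float] | None = None,
                            alpha: float = 0.05, n_boot: int = 1000,
                            seed: int = 0) -> SlopeConservationReport:
    """Test whether per-cell slopes are conserved across UV doses.

    ``features`` is the table produced by
    :func:`tetrapulse.trace_analysis.features_table`.  Invalid cells are
    dropped; the contrast is the Mann-Whitney comparison of the
    lowest-dose against the highest-dose slope distribution.
    """
    sub = features[(features["channel"] == channel) & features["valid"]]
    if doses is None:
        doses = sorted(sub["uv_dose"].unique())
    doses = tuple(sorted(float(d) for d in doses))
    if len(doses) < 2:
        raise ValueError("need at least 2 doses")
    groups = []
    for d in doses:
        g = sub.loc[sub["uv_dose"] == d, "slope_per_h"].to_numpy()
        if len(g) < 5:
            raise ValueError(f"dose {d} has fewer than 5 valid cells")
        groups.append(g)

    medians, sems = [], []
    for i, g in enumerate(groups):
        m, s = median_sem(g, n_boot=n_boot, seed=seed + i)
        medians.append(m)
        sems.append(s)
    test = mann_whitney_u(groups[0], groups[-1])
    return SlopeConservationReport(
        channel=channel, doses=doses, median_slopes=tuple(medians),
        sems=tuple(sems), n_per_dose=tuple(len(g) for g in groups),
        test=test, alpha=alpha)
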