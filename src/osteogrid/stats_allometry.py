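"""Comparative and allometric statistics for whole-bone morphometry.

The comparative battery is fully nonparametric: a Kruskal–Wallis omnibus
test across groups per parameter, Holm-adjusted pairwise Wilcoxon rank-sum
tests, and a Wilcoxon signed-rank test of whether distal:proximal ratios
depart from 1 within a group.

Allometry is assessed by reduced major axis (RMA, model II) regression of
each logged parameter on the logged cube root of bone volume:
``slope = sign(r) * sd(y)/sd(x)``, 95% CI by the standard model-II factor
``B * (sqrt(F+1) ∓ sqrt(F))`` with ``F = t²(1-r²)/(n-2)``, and a p-value
from the two-sided test of zero correlation.  Shape-like parameters
(BV/TV, DA, Tb.N) have isometric slope 0; size-like parameters (Tb.Th,
Tb.Sp, Ct.Th) have isometric slope 1.  A fit is classified Uncorrelated
when p exceeds alpha, Isometry when the CI contains the isometric slope,
and Positive/Negative allometry when the CI lies entirely above/below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .volume_io import VoxelVolume

__all__ = [
    "GroupedValues",
    "AllometryResult",
    "ISOMETRIC_SLOPES",
    "kruskal_wallis",
    "pairwise_wilcoxon_holm",
    "signed_rank_ratio",
    "rma_fit",
    "classify_allometry",
    "capitate_size",
]

#: isometric expectations by parameter (shape-like 0, size-like 1)
ISOMETRIC_SLOPES = {
    "trab_bvtv": 0, "total_bvtv": 0, "da": 0, "tbn_per_mm": 0,
    "tbth_mm": 1, "tbsp_mm": 1, "ctth_mm": 1,
}

#: largest sample size at which exact rank-test null distributions are used
EXACT_N_MAX = 25


@dataclass
class GroupedValues:
    """Values of one parameter grouped by taxon / behavioural group."""

    parameter: str
    groups: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        self.groups = [(g, np.asarray(v, float)) for g, v in self.groups]
        for g, v in self.groups:
            if v.size == 0:
                raise ValidationError(f"group {g!r} has no observations")
            if not np.isfinite(v).all():
                raise ValidationError(f"group {g!r} contains non-finite values")


@dataclass
class AllometryResult:
    parameter: str
    scope: str
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r2: float
    p: float
    n: int
    isometric_slope: int | None = None
    category: str | None = None


# ---------------------------------------------------------------------------
# nonparametric group comparisons
# ---------------------------------------------------------------------------

def kruskal_wallis(g: GroupedValues) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H, degrees of freedom, chi-square p."""
    if len(g.groups) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups")
    arrays = [v for _, v in g.groups]
    df = len(arrays) - 1
    allv = np.concatenate(arrays)
    if allv.size < 3:
        raise ValidationError("Kruskal-Wallis needs total n >= 3")
    if np.all(allv == allv[0]):  # all observations tied: H = 0 by convention
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for small tie-free samples,
    otherwise normal approximation with continuity and tie correction."""
    exact = (
        len(a) <= EXACT_N_MAX
        and len(b) <= EXACT_N_MAX
        and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def pairwise_wilcoxon_holm(g: GroupedValues) -> pd.DataFrame:
    """Holm-adjusted two-sided rank-sum p-values for every group pair.

    Returns a symmetric matrix (NaN diagonal); pairs involving a group
    with fewer than 2 observations are left NaN (untestable), the rest are
    adjusted over the testable family.
    """
    names = [n for n, _ in g.groups]
    k = len(names)
    if k < 2:
        raise ValidationError("pairwise tests need >= 2 groups")
    raw, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = g.groups[i][1], g.groups[j][1]
            if len(a) < 2 or len(b) < 2:
                continue
            raw.append(_rank_sum_p(a, b))
            pairs.append((i, j))
    out = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    if raw:
        adj = multipletests(raw, method="holm")[1]
        for (i, j), p in zip(pairs, adj):
            out.iloc[i, j] = out.iloc[j, i] = min(float(p), 1.0)
    return out


def signed_rank_ratio(
    ratios: Sequence[float], null_value: float = 1.0
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of ratios against a null value.

    Equivalent to the paired distal-vs-proximal test on the differences
    ``ratio - 1``.  Zero differences are dropped (classical convention);
    the exact null distribution is used for small tie-free samples, the
    normal approximation with continuity correction otherwise.  All ratios
    equal to the null give the degenerate (V=0, p=1).
    """
    d = np.asarray(ratios, float) - null_value
    d = d[np.isfinite(d)]
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    if d.size < 2:
        raise ValidationError("signed-rank test needs >= 2 nonzero differences")
    exact = d.size <= EXACT_N_MAX and len(np.unique(np.abs(d))) == d.size
    res = stats.wilcoxon(
        d,
        alternative="two-sided",
        zero_method="wilcox",
        correction=not exact,
        method="exact" if exact else "approx",
    )
    # report V = sum of positive ranks (the R convention); scipy's
    # two-sided statistic is min(T+, T-)
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    return v, float(res.pvalue)


# ---------------------------------------------------------------------------
# reduced major axis allometry
# ---------------------------------------------------------------------------

def rma_fit(
    x: Sequence[float],
    y: Sequence[float],
    parameter: str = "",
    scope: str = "whole sample",
    alpha_ci: float = 0.05,
) -> AllometryResult:
    """Reduced major axis fit of logged parameter ``y`` on logged size ``x``."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValidationError("RMA needs >= 3 paired observations")
    sx, sy = float(np.std(x, ddof=1)), float(np.std(y, ddof=1))
    if sx == 0 or sy == 0:
        raise ValidationError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0  # r = 0: positive by convention
    slope = sign * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    r2 = r * r
    if r2 >= 1.0:
        p = 0.0
        ci_low = ci_high = slope
    else:
        t = abs(r) * math.sqrt((n - 2) / (1.0 - r2))
        p = 2.0 * stats.t.sf(t, n - 2)
        tcrit = stats.t.ppf(1.0 - alpha_ci / 2.0, n - 2)
        F = tcrit**2 * (1.0 - r2) / (n - 2)
        lo = slope * (math.sqrt(F + 1.0) - math.sqrt(F))
        hi = slope * (math.sqrt(F + 1.0) + math.sqrt(F))
        ci_low, ci_high = (lo, hi) if lo <= hi else (hi, lo)
    return AllometryResult(
        parameter=parameter, scope=scope, slope=float(slope),
        intercept=intercept, ci_low=float(ci_low), ci_high=float(ci_high),
        r2=float(r2), p=float(p), n=int(n),
    )


def classify_allometry(
    fit: AllometryResult, isometric_slope: int, alpha: float = 0.05
) -> str:
    """Assign {Positive, Negative, Isometry, Uncorrelated} to an RMA fit.

    Significance uses p <= alpha; among significant fits the category is
    decided by where the 95% CI lies relative to the isometric slope, the
    straddling case being Isometry.
    """
    if fit.p > alpha:
        category = "Uncorrelated"
    elif fit.ci_low > isometric_slope:
        category = "Positive"
    elif fit.ci_high < isometric_slope:
        category = "Negative"
    else:
        category = "Isometry"
    fit.isometric_slope = isometric_slope
    fit.category = category
    return category


def capitate_size(tv: VoxelVolume | np.ndarray, spacing: float | None = None) -> tuple[float, float]:
    """Bone size proxy from the enclosed volume: (cube root mm, log10 cube root).

    Accepts a binary TV volume or a label volume (any nonzero voxel counts
    toward TV).
    """
    if isinstance(tv, VoxelVolume):
        data, spacing = np.asarray(tv.data), tv.spacing
    else:
        data = np.asarray(tv)
        if spacing is None:
            raise ValidationError("spacing required with a bare array")
    n = int((data > 0).sum())
    if n == 0:
        raise ValidationError("empty enclosed volume")
    volume_mm3 = n * spacing**3
    croot = volume_mm3 ** (1.0 / 3.0)
    return float(croot), float(math.log10(croot))
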