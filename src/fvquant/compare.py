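"""Omnibus and many-to-one group tests on per-animal mean G-values.

The analysis unit here is the per-animal mean, not the pixel: pixels
within one animal are pseudo-replicates, so group sizes match the cohort
sizes.  One-way ANOVA provides the omnibus test; Dunnett-style many-to-one
comparisons test each stage against a reference (usually Control) with
family-wise error control.

Dunnett's adjusted p-values are computed by Monte-Carlo sampling of the
joint null distribution of the comparison t statistics (shared pooled
variance, balanced-correlation structure): for each draw, simulate group
means ~ N(0, 1/n_i) and a pooled variance ~ chi2(nu)/nu, form all
comparison statistics, and record max |T|.  The adjusted p of an observed
t is the fraction of draws whose max |T| exceeds |t|.  This is seedable,
reproducible, and reduces to the two-sample t-test when only one
comparison exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "anova_oneway",
    "dunnett_many_to_one",
    "dunnett_critical_value",
]

MIN_MC = 10_000


@dataclass
class ComparisonResult:
    label: str
    statistic: float
    p_adjusted: float
    p_unadjusted: float
    significant: bool


def _validate_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = []
    for i, g in enumerate(groups):
        a = np.asarray(g, dtype=np.float64).ravel()
        a = a[np.isfinite(a)]
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
        arrs.append(a)
    return arrs


def anova_oneway(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """One-way (non-repeated-measures) ANOVA F statistic and p-value."""
    arrs = _validate_groups(groups)
    pooled = np.concatenate(arrs)
    if np.ptp(pooled) == 0:  # all values identical: F = 0 by convention
        return 0.0, 1.0
    f, p = sps.f_oneway(*arrs)
    return float(f), float(p)


def _null_max_abs_t(
    sizes: np.ndarray, reference_index: int, n_mc: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo draws of max_i |T_i| under the joint Dunnett null."""
    k = sizes.size
    nu = int(sizes.sum() - k)
    others = [i for i in range(k) if i != reference_index]
    z = rng.standard_normal((n_mc, k)) / np.sqrt(sizes)[None, :]
    s2 = rng.chisquare(nu, size=n_mc) / nu
    t_all = np.empty((n_mc, len(others)))
    for j, i in enumerate(others):
        se = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[reference_index]))
        t_all[:, j] = (z[:, i] - z[:, reference_index]) / se
    return np.abs(t_all).max(axis=1)


def dunnett_many_to_one(
    groups: Sequence[Sequence[float]],
    reference_index: int = 0,
    *,
    n_mc: int = 100_000,
    seed: int | None = None,
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> list[ComparisonResult]:
    """Dunnett-style comparisons of every group against the reference.

    Returns one :class:`ComparisonResult` per non-reference group, in input
    order, with two-sided Monte-Carlo adjusted p-values (``n_mc`` >= 10^4
    draws) alongside the unadjusted two-sample-t p-values.
    """
    arrs = _validate_groups(groups)
    k = len(arrs)
    if not (0 <= reference_index < k):
        raise ValueError(f"reference index {reference_index} out of range")
    if n_mc < MIN_MC:
        raise ValueError(f"n_mc must be >= {MIN_MC}")
    sizes = np.array([a.size for a in arrs], dtype=np.float64)
    nu = int(sizes.sum() - k)
    s2p = sum(((a - a.mean()) ** 2).sum() for a in arrs) / nu
    ref = arrs[reference_index]

    rng = np.random.default_rng(seed)
    max_abs = _null_max_abs_t(sizes, reference_index, n_mc, rng)

    if labels is None:
        labels = [f"group{i} vs group{reference_index}" for i in range(k)]
    out = []
    for i, a in enumerate(arrs):
        if i == reference_index:
            continue
        se = np.sqrt(s2p * (1.0 / a.size + 1.0 / ref.size))
        t = float((a.mean() - ref.mean()) / se) if se > 0 else 0.0
        p_adj = float(np.mean(max_abs >= abs(t))) if se > 0 else 1.0
        p_un = float(2.0 * sps.t.sf(abs(t), nu))
        out.append(
            ComparisonResult(
                label=labels[i],
                statistic=t,
                p_adjusted=p_adj,
                p_unadjusted=p_un,
                significant=p_adj < alpha,
            )
        )
    return out


def dunnett_critical_value(
    sizes: Sequence[int],
    reference_index: int = 0,
    *,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> float:
    """Two-sided Dunnett critical value |T| for the given design, by Monte Carlo."""
    sizes = np.asarray(sizes, dtype=np.float64)
    if sizes.size < 2 or np.any(sizes < 2):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if not (0 <= reference_index < sizes.size):
        raise ValueError("reference index out of range")
    if n_mc < MIN_MC:
        raise ValueError(f"n_mc must be >= {MIN_MC}")
    rng = np.random.default_rng(seed)
    max_abs = _null_max_abs_t(sizes, reference_index, n_mc, rng)
    return float(np.quantile(max_abs, 1.0 - alpha))
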