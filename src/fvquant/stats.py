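"""Per-sample and per-group fluorescence-intensity statistics.

Covers the descriptive statistics of the stage summary table (n, mean, SD,
median, min, max, range, mean pairwise Pearson correlation), the
within-sample variation measure (sample standard deviation with the N-1
denominator), and the pooled pixel-distribution histograms whose widening
("scattering") tracks tumor progression.

Group statistics pool pixels across the group's profiles rather than
averaging per-animal summaries: the published group min/max clearly span
pixel-level extremes.  Per-animal aggregation is available via
``per_sample=True`` on :func:`summarize_group`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .measure import MeasurementProfile

__all__ = [
    "SampleSummary",
    "GroupSummary",
    "DistributionTable",
    "ConcordanceResult",
    "sample_sd",
    "detrended_sample_sd",
    "summarize_sample",
    "summarize_group",
    "scatter_distribution",
    "group_concordance",
]


@dataclass
class SampleSummary:
    sample_id: str | None
    stage_label: str | None
    n_pixels: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    range: float


@dataclass
class GroupSummary:
    stage_label: str | None
    n_samples: int
    n_pixels: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    range: float
    mean_pcc: float
    pcc_low: float
    pcc_high: float


@dataclass
class DistributionTable:
    """Pooled pixel histogram per stage over right-open G-value bins."""

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]

    def total(self, stage: str) -> int:
        return int(self.counts[stage].sum())


@dataclass
class ConcordanceResult:
    mean_r: float
    min_r: float
    max_r: float
    #: (index_i, index_j, r, p) for every unordered profile pair
    pairs: list[tuple[int, int, float, float]]


def sample_sd(values: Sequence[float] | np.ndarray) -> float:
    """Sample standard deviation S = sqrt( sum (x_i - mean)^2 / (N - 1) )."""
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("sample_sd requires at least 2 values")
    return float(np.sqrt(np.sum((v - v.mean()) ** 2) / (v.size - 1)))


def detrended_sample_sd(profile: MeasurementProfile) -> float:
    """Within-sample noise SD about the axial trend.

    A raw profile SD mixes pixel noise with the apex→root gradient; this
    estimator removes the fitted inclination line first and returns the
    residual SD (N-2 denominator), the generator's ``within_sd`` analogue.
    """
    x = profile.finite_positions()
    y = profile.finite_values()
    if y.size < 3:
        raise ValueError("detrended_sample_sd requires at least 3 values")
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    return float(np.sqrt(np.sum(resid**2) / (y.size - 2)))


def summarize_sample(profile: MeasurementProfile) -> SampleSummary:
    """Descriptive statistics of one measurement profile.

    Median for even n is the midpoint of the two central order statistics.
    """
    v = profile.finite_values()
    if v.size < 2:
        raise ValueError("summarize_sample requires at least 2 unmasked values")
    vmin, vmax = float(v.min()), float(v.max())
    return SampleSummary(
        sample_id=profile.sample_id,
        stage_label=profile.stage_label,
        n_pixels=int(v.size),
        mean=float(v.mean()),
        sd=sample_sd(v),
        median=float(np.median(v)),
        min=vmin,
        max=vmax,
        range=vmax - vmin,
    )


def summarize_group(
    profiles: Sequence[MeasurementProfile],
    stage_label: str | None = None,
    *,
    per_sample: bool = False,
) -> GroupSummary:
    """Group statistics over pooled pixels plus pairwise profile concordance.

    With ``per_sample=True`` the mean/SD/median are computed over per-sample
    means instead of pooled pixels (min/max/range stay pixel-level).
    """
    if not profiles:
        raise ValueError("summarize_group requires at least 1 profile")
    pooled = np.concatenate([p.finite_values() for p in profiles])
    if stage_label is None:
        stage_label = profiles[0].stage_label
    if per_sample:
        unit = np.array([p.finite_values().mean() for p in profiles])
    else:
        unit = pooled
    if len(profiles) >= 2:
        conc = group_concordance(profiles)
        mean_pcc, lo, hi = conc.mean_r, conc.min_r, conc.max_r
    else:
        mean_pcc = lo = hi = float("nan")
    vmin, vmax = float(pooled.min()), float(pooled.max())
    return GroupSummary(
        stage_label=stage_label,
        n_samples=len(profiles),
        n_pixels=int(pooled.size),
        mean=float(unit.mean()),
        sd=sample_sd(unit) if unit.size >= 2 else float("nan"),
        median=float(np.median(unit)),
        min=vmin,
        max=vmax,
        range=vmax - vmin,
        mean_pcc=mean_pcc,
        pcc_low=lo,
        pcc_high=hi,
    )


def scatter_distribution(
    profiles_by_stage: Mapping[str, Sequence[MeasurementProfile]],
    bin_width: float = 1.0,
) -> DistributionTable:
    """Pooled pixel histograms per stage over [0, 255], right-open bins.

    The default bin width of 1 G-value is the native 8-bit quantization.
    Counts are conserved: each stage's histogram sums to its pixel total.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    edges = np.arange(0.0, 256.0 + bin_width, bin_width)
    counts: dict[str, np.ndarray] = {}
    for stage, profiles in profiles_by_stage.items():
        pooled = np.concatenate([p.finite_values() for p in profiles])
        hist, _ = np.histogram(pooled, bins=edges)
        counts[stage] = hist
    return DistributionTable(bin_edges=edges, counts=counts)


def _resample_even(values: np.ndarray, m: int) -> np.ndarray:
    idx = np.round(np.linspace(0, values.size - 1, m)).astype(int)
    return values[idx]


def group_concordance(profiles: Sequence[MeasurementProfile]) -> ConcordanceResult:
    """Mean pairwise Pearson correlation between a group's profiles.

    Profiles are aligned on normalized apex→root position by resampling
    every profile to the shortest length with evenly spaced indices; r and
    its t-transform p-value are computed for every unordered pair.  The
    mean is taken over all pairs.
    """
    if len(profiles) < 2:
        raise ValueError("group_concordance requires at least 2 profiles")
    vals = [p.finite_values() for p in profiles]
    m = min(v.size for v in vals)
    if m < 3:
        raise ValueError("profiles must have at least 3 unmasked values")
    vals = [_resample_even(v, m) for v in vals]
    pairs = []
    for i in range(len(vals)):
        for j in range(i + 1, len(vals)):
            r, p = sps.pearsonr(vals[i], vals[j])
            pairs.append((i, j, float(r), float(p)))
    rs = np.array([p[2] for p in pairs])
    return ConcordanceResult(
        mean_r=float(rs.mean()),
        min_r=float(rs.min()),
        max_r=float(rs.max()),
        pairs=pairs,
    )
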