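"""ROC analysis for G-value stage discrimination.

Pixel G-values from two stages are treated as scores of a one-dimensional
classifier; sweeping a threshold over the pooled values traces the ROC
curve, the trapezoidal area equals the tie-corrected Mann-Whitney U
statistic normalized by n1*n2, and the operating cutoff is chosen by the
Youden index (TPR - FPR).  A closed-form Gaussian AUC,
Phi(|mu2 - mu1| / sqrt(sd1^2 + sd2^2)), serves as an analytic oracle for
simulated Gaussian classes.

Conventions: the positive ("lesion") class is the higher-grade side of a
comparison; the scoring direction is chosen so that AUC >= 0.5 and is
recorded on the curve (lesions may be brighter or darker than the
reference depending on the stage pair).  Thresholds are placed at
midpoints between adjacent distinct observed values, so a reported cutoff
separates the classes rather than sitting on an observed value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RocCurve",
    "YoudenCutoff",
    "RocComparison",
    "roc_points",
    "auc_trapezoid",
    "youden_cutoff",
    "stage_comparison",
    "gaussian_auc_oracle",
    "mann_whitney_auc",
]


@dataclass
class RocCurve:
    """Ordered (FPR, TPR) points with the thresholds that generate them.

    ``thresholds`` live in score space (score = direction * G-value); the
    first entry is +inf for the (0, 0) point.  ``direction`` is +1 when the
    lesion class scores higher in G, -1 when it scores lower.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    direction: int
    lesion_mean: float
    reference_mean: float

    def cutoff_gvalues(self) -> np.ndarray:
        """Thresholds mapped back to the G-value axis."""
        return self.direction * self.thresholds


@dataclass
class YoudenCutoff:
    cutoff: float  # G-value
    youden_j: float
    sensitivity: float  # percent
    specificity: float  # percent
    degenerate: bool  # True when no threshold separates the classes


@dataclass
class RocComparison:
    """One row of a stage-discrimination table."""

    label: str
    cutoff: float
    auc: float
    p_value: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    direction: int
    degenerate: bool


def mann_whitney_auc(lesion: np.ndarray, reference: np.ndarray) -> float:
    """P(lesion > reference) + 0.5 P(=) via midranks (tie-corrected U/(n1 n2))."""
    lesion = np.asarray(lesion, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    n1, n2 = lesion.size, reference.size
    ranks = sps.rankdata(np.concatenate([lesion, reference]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def roc_points(
    lesion_values: Sequence[float] | np.ndarray,
    reference_values: Sequence[float] | np.ndarray,
    *,
    direction: int | None = None,
) -> RocCurve:
    """Sweep thresholds over all observed values and return the ROC curve.

    A sample is called "lesion" when its score (direction * G) is >= the
    threshold.  With ``direction=None`` the direction making AUC >= 0.5 is
    chosen automatically and recorded.  The curve starts at (0, 0) and ends
    at (1, 1).
    """
    lesion = np.asarray(lesion_values, dtype=np.float64).ravel()
    reference = np.asarray(reference_values, dtype=np.float64).ravel()
    lesion = lesion[np.isfinite(lesion)]
    reference = reference[np.isfinite(reference)]
    if lesion.size == 0 or reference.size == 0:
        raise ValueError("both groups must be non-empty")

    if direction is None:
        direction = 1 if mann_whitney_auc(lesion, reference) >= 0.5 else -1
    elif direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")

    s_les = direction * lesion
    s_ref = direction * reference
    uniq = np.unique(np.concatenate([s_les, s_ref]))[::-1]  # descending
    # thresholds: +inf (no positives), midpoints between adjacent distinct
    # values, then the minimum (all positive)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[np.inf], mids, [uniq[-1]]])
    tpr = (s_les[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (s_ref[None, :] >= thresholds[:, None]).mean(axis=1)
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        direction=direction,
        lesion_mean=float(lesion.mean()),
        reference_mean=float(reference.mean()),
    )


def auc_trapezoid(roc: RocCurve | tuple[np.ndarray, np.ndarray]) -> float:
    """Trapezoidal area under the curve; equals tie-corrected U/(n1 n2)."""
    if isinstance(roc, RocCurve):
        fpr, tpr = roc.fpr, roc.tpr
    else:
        fpr, tpr = np.asarray(roc[0]), np.asarray(roc[1])
    return float(np.trapezoid(tpr, fpr))


def youden_cutoff(roc: RocCurve, *, tol: float = 1e-12) -> YoudenCutoff:
    """Threshold maximizing TPR - FPR, reported as a G-value cutoff.

    Ties are broken toward the threshold nearest the midpoint of the two
    group means.  When no threshold beats J = 0 (indistinguishable groups)
    the result carries ``degenerate=True``.
    """
    j = roc.tpr - roc.fpr
    jmax = float(j.max())
    degenerate = jmax < tol
    cand = np.flatnonzero(j >= jmax - tol)
    gvals = roc.cutoff_gvalues()[cand]
    finite = np.isfinite(gvals)
    cand, gvals = cand[finite], gvals[finite]
    if cand.size == 0:  # only +inf qualified; fall back to all thresholds
        cand = np.arange(1, roc.thresholds.size)
        gvals = roc.cutoff_gvalues()[cand]
    midpoint = (roc.lesion_mean + roc.reference_mean) / 2.0
    best = cand[np.argmin(np.abs(gvals - midpoint))]
    return YoudenCutoff(
        cutoff=float(roc.cutoff_gvalues()[best]),
        youden_j=float(j[best]),
        sensitivity=float(roc.tpr[best] * 100.0),
        specificity=float((1.0 - roc.fpr[best]) * 100.0),
        degenerate=degenerate,
    )


def _u_p_value(lesion: np.ndarray, reference: np.ndarray) -> float:
    """Two-sided normal approximation to the Mann-Whitney U test (tie-corrected)."""
    n1, n2 = lesion.size, reference.size
    n = n1 + n2
    auc = mann_whitney_auc(lesion, reference)
    u = auc * n1 * n2
    _, tie_counts = np.unique(np.concatenate([lesion, reference]), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (u - n1 * n2 / 2.0) / np.sqrt(sigma2)
    return float(2.0 * sps.norm.sf(abs(z)))


def stage_comparison(
    groups: Mapping[str, np.ndarray | Sequence[float]],
    comparisons: Sequence[tuple[str, Sequence[str], Sequence[str]]],
) -> list[RocComparison]:
    """Run one ROC per comparison row.

    Each comparison is (label, positive stages, negative stages); pooled
    rows take the union of the listed stages' values.  Sensitivity and
    specificity are reported at the Youden cutoff; the p-value is the
    normal approximation to the Mann-Whitney U test (two-sided).
    """
    out = []
    for label, pos_stages, neg_stages in comparisons:
        for s in list(pos_stages) + list(neg_stages):
            if s not in groups:
                raise ValueError(f"unknown stage label {s!r} in comparison {label!r}")
        pos = np.concatenate([np.asarray(groups[s], dtype=np.float64).ravel() for s in pos_stages])
        neg = np.concatenate([np.asarray(groups[s], dtype=np.float64).ravel() for s in neg_stages])
        curve = roc_points(pos, neg)
        yc = youden_cutoff(curve)
        out.append(
            RocComparison(
                label=label,
                cutoff=yc.cutoff,
                auc=auc_trapezoid(curve),
                p_value=_u_p_value(pos[np.isfinite(pos)], neg[np.isfinite(neg)]),
                sensitivity=yc.sensitivity,
                specificity=yc.specificity,
                n_pos=int(np.isfinite(pos).sum()),
                n_neg=int(np.isfinite(neg).sum()),
                direction=curve.direction,
                degenerate=yc.degenerate,
            )
        )
    return out


def gaussian_auc_oracle(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Exact AUC for two Gaussian classes: Phi(|mu2 - mu1| / sqrt(sd1^2 + sd2^2)).

    Analytic check for the simulation; undefined (raises) when both SDs are
    zero with equal means.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    denom = float(np.hypot(sd1, sd2))
    if denom == 0.0:
        if mu1 == mu2:
            raise ValueError("AUC undefined: both SDs zero with equal means")
        return 1.0
    return float(sps.norm.cdf(abs(mu2 - mu1) / denom))
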