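"""Organ-situs scoring and the classical tests used on count tables.

Situs categories follow the standard laterality nomenclature: *situs
solitus* (heart and gut both left, normal), *situs inversus* (both right,
full mirror reversal) and *heterotaxia* (every other combination,
including a centered heart).  The tests wrap scipy implementations with
the conventions of the original analyses: two-sided Fisher exact p-values
by minimum-likelihood summation, Welch's t from summary statistics
(mean/SEM/n) as well as raw samples, paired t with a zero-variance guard,
and tie-corrected two-sided Mann-Whitney U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SitusRecord",
    "call_situs",
    "fisher_exact",
    "welch_t",
    "welch_t_from_summary",
    "paired_t",
    "mann_whitney",
]

log = logging.getLogger(__name__)

HEART_LEVELS = ("left", "center", "right")
GUT_LEVELS = ("left", "right")


@dataclass(frozen=True)
class SitusRecord:
    embryo_id: str
    heart: str
    gut: str
    dand5_pattern: str | None = None

    def __post_init__(self) -> None:
        if self.heart not in HEART_LEVELS:
            raise ValueError(f"heart must be one of {HEART_LEVELS}")
        if self.gut not in GUT_LEVELS:
            raise ValueError(f"gut must be one of {GUT_LEVELS}")
        if self.dand5_pattern is not None and self.dand5_pattern not in (
            "right", "bilateral", "left", "absent"
        ):
            raise ValueError("invalid dand5 pattern")


def call_situs(record: SitusRecord) -> str:
    """Classify one embryo: solitus, inversus, or heterotaxia."""
    if record.heart == "left" and record.gut == "left":
        return "solitus"
    if record.heart == "right" and record.gut == "right":
        return "inversus"
    return "heterotaxia"


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table -> (odds ratio, p).

    The two-sided p sums hypergeometric probabilities no larger than the
    observed table's (minimum-likelihood rule).  Degenerate margins give
    p = 1 by convention.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return np.nan, 1.0
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test on raw samples -> (t, df, p)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_t_from_summary(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t-test from per-group mean, SEM and n -> (t, df, p).

    Satterthwaite degrees of freedom computed from the squared SEMs.
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    v1, v2 = sem1**2, sem2**2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def paired_t(left, right) -> tuple[float, float]:
    """Paired t-test on per-embryo left/right counts -> (t, p).

    Identical vectors give p = 1; a constant non-zero difference has zero
    variance, for which p = 0 is returned with a warning rather than NaN.
    """
    left, right = np.asarray(left, float), np.asarray(right, float)
    if left.shape != right.shape:
        raise ValueError("paired vectors must have equal length")
    if len(left) < 2:
        raise ValueError("need n >= 2 pairs")
    d = left - right
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        log.warning("zero-variance paired differences; reporting p = 0")
        return float(np.sign(d[0]) * np.inf), 0.0
    res = stats.ttest_rel(left, right)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction -> (U, p).

    Uses the exact null distribution for small tie-free samples and the
    corrected normal approximation otherwise.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
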