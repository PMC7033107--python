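"""Correlation statistics: Pearson/Spearman, Fisher-z summaries, Bonferroni.

The layer mirrors how correlational movement studies report results: a
group-level correlation over pooled points, a per-participant Fisher-z mean
with a 95% confidence interval as a robustness check, a Shapiro-Wilk gate
that switches to rank correlation when normality fails, and a
Bonferroni-corrected significance level formatted the way journals print it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_DOWN, Decimal
from functools import lru_cache

import numpy as np
from scipy import stats as ss

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "CorrelationSummary",
    "pearson",
    "spearman",
    "normality_gate",
    "fisher_summary",
    "bonferroni_alpha",
    "format_alpha_percent",
]

EXACT_PERMUTATION_MAX_N = 10


@dataclass(frozen=True)
class CorrelationSummary:
    """One row of a correlation results table."""

    analysis_id: str
    method: str  # "pearson" | "spearman"
    n: int
    r: float
    p: float
    mean_z: float | None = None
    ci95_r: tuple | None = None
    alpha: float | None = None

    @property
    def significant(self) -> bool | None:
        return None if self.alpha is None else bool(self.p < self.alpha)


def _check_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    if x.size < min_n:
        raise ParameterError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance input: correlation undefined")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-distribution p-value."""
    x, y = _check_xy(x, y)
    res = ss.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@lru_cache(maxsize=2)
def _all_permutations(n: int) -> np.ndarray:
    """All n! permutations of 0..n-1 as an int8 matrix (cached; n <= 10)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def spearman(x, y) -> tuple[float, float]:
    """Rank correlation (mid-ranks for ties).

    For n <= 10 the p-value is exact, from the full permutation null of one
    rank vector (two-sided: fraction of permutations with |r| at least the
    observed, the identity included); above that a t approximation is used.
    """
    x, y = _check_xy(x, y)
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)
    rx = (rx - rx.mean()) / np.sqrt(np.sum((rx - rx.mean()) ** 2))
    ry = (ry - ry.mean()) / np.sqrt(np.sum((ry - ry.mean()) ** 2))
    r = float(np.clip(np.dot(rx, ry), -1.0, 1.0))

    n = x.size
    if n <= EXACT_PERMUTATION_MAX_N:
        perms = _all_permutations(n)
        # permute the x ranks over all n! orders and correlate with fixed y ranks
        null = rx[perms].dot(ry)
        p = float(np.mean(np.abs(null) >= abs(r) - 1e-12))
    else:
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = float(2 * ss.t.sf(abs(t), n - 2))
    return r, p


def normality_gate(samples, alpha: float = 0.05) -> str:
    """Choose the correlation method by Shapiro-Wilk normality tests.

    ``samples`` is an iterable of 1-D arrays (the variables entering the
    analysis). If any variable rejects normality at ``alpha``, rank
    correlation is indicated.
    """
    for s in samples:
        s = np.asarray(s, float)
        if not 3 <= s.size <= 5000:
            raise ParameterError("Shapiro-Wilk needs 3 <= n <= 5000")
        if ss.shapiro(s).pvalue < alpha:
            return "spearman"
    return "pearson"


def fisher_summary(per_participant_r) -> tuple[float, tuple]:
    """Mean Fisher z of individual correlations and the 95% CI in r units.

    z_i = atanh(r_i); CI = tanh(mean_z +/- 1.96 * sd(z) / sqrt(n)), with the
    sample sd of the individual z values (ddof=1). Identical r's collapse
    the interval onto the point.
    """
    r = np.asarray(per_participant_r, float)
    if r.size < 2:
        raise ParameterError("need at least 2 per-participant correlations")
    if np.any(np.abs(r) >= 1):
        raise ParameterError("|r| = 1 has infinite Fisher z; summary undefined")
    z = np.arctanh(r)
    mean_z = float(np.mean(z))
    se = float(np.std(z, ddof=1) / np.sqrt(z.size))
    ci = (float(np.tanh(mean_z - 1.96 * se)), float(np.tanh(mean_z + 1.96 * se)))
    return mean_z, ci


def bonferroni_alpha(base_alpha: float, k_comparisons: int) -> float:
    """Corrected per-comparison significance level base_alpha / k."""
    if not 0 < base_alpha < 1:
        raise ParameterError("base_alpha must lie in (0, 1)")
    if k_comparisons < 1:
        raise ParameterError("k_comparisons must be >= 1")
    return base_alpha / k_comparisons


def format_alpha_percent(alpha: float) -> str:
    """Format alpha as a percentage, truncated (not rounded) to 2 decimals.

    0.05/12 -> "0.41%", 0.025 -> "2.5%" (trailing zeros stripped).
    """
    pct = Decimal(str(alpha * 100)).quantize(Decimal("0.01"), rounding=ROUND_DOWN)
    s = str(pct).rstrip("0").rstrip(".")
    return f"{s}%"
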