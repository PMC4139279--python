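"""Nonparametric statistics for small cohorts.

The study-level inference uses only distribution-free tools suited to
seven animals: Spearman rank correlation between AC/DC and acid-base
biomarkers, the paired Wilcoxon signed-rank test between consecutive
protocol phases (Bonferroni-corrected over the three consecutive-phase
comparisons), interquartile summaries, and SDNN as a total-variability
reference.  With n this small the exact null distributions matter, so
both tests enumerate them exactly for small samples instead of relying
on asymptotics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .io_formats import DegenerateInputError, RRSeries

__all__ = [
    "CorrelationResult",
    "PhaseComparison",
    "spearman",
    "wilcoxon_signed_rank_paired",
    "significant_T_ranges",
    "quartile_summary",
    "sdnn",
]

BONFERRONI_FACTOR = 3
ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho between a capacity and a biomarker at one T."""

    capacity: str          # "AC" or "DC"
    T: int
    variant: str           # "entire" or "stable"
    biomarker: str         # "pH", "lactate" or "base_deficit"
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class PhaseComparison:
    """Per-T paired comparison between two consecutive phases."""

    pair: str              # e.g. "MODERATE-SEVERE"
    capacity: str
    variant: str
    p_raw: dict            # T -> raw two-sided p
    p_corrected: dict      # T -> min(1, raw * BONFERRONI_FACTOR)
    significant_T_ranges: list


class QuartileSummary(NamedTuple):
    median: float
    q1: float
    q3: float
    mean: float


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        raise DegenerateInputError("zero variance in ranks")
    return float((rx * ry).sum() / denom)


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman correlation with a two-sided p-value.

    ``rho`` is Pearson correlation of mid-ranks (ties averaged).  The
    p-value is an exact permutation probability for ``n <= exact_max_n``
    (all ``n!`` orderings of one rank vector) and the usual t
    approximation on ``n - 2`` degrees of freedom otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if y.size != n or n < 3:
        raise DegenerateInputError("need two equal-length vectors with n >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise DegenerateInputError("missing values not allowed")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_rho(rx, ry)
    if n <= exact_max_n:
        # exact permutation null: correlate rx with every ordering of ry
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
        perms = np.array(list(permutations(ryc)))
        rhos = perms @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tstat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(tstat), n - 2))
    return rho, min(1.0, p)


# ---------------------------------------------------------------------------
# Wilcoxon signed rank
# ---------------------------------------------------------------------------


def _wilcoxon_exact_p(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided p for doubled signed ranks via subset-sum counting."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        counts[r:] += counts[: counts.size - r]
    counts /= counts.sum()
    p_le = float(counts[: w2 + 1].sum())
    p_ge = float(counts[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank_paired(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 25
) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (at least five informative pairs
    required).  For ``n <= exact_max_n`` the p-value enumerates the exact
    sign-assignment null (ties handled with mid-ranks); above that a
    normal approximation with continuity and tie corrections is used.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size:
        raise DegenerateInputError("paired vectors differ in length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    if n < 5:
        raise DegenerateInputError(
            f"only {n} non-zero differences (need >= 5 for a meaningful test)"
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.rint(2.0 * ranks).astype(np.int64)
        w2 = int(round(2.0 * w_plus))
        return _wilcoxon_exact_p(ranks2, w2)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / math.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Range extraction, quartiles, SDNN
# ---------------------------------------------------------------------------


def significant_T_ranges(
    per_T_pvalues: dict,
    alpha: float = ALPHA,
    bonferroni_factor: int = BONFERRONI_FACTOR,
) -> list[tuple[int, int]]:
    """Maximal contiguous runs of T with Bonferroni-corrected p < alpha.

    ``per_T_pvalues`` maps T -> raw two-sided p; NaN entries never count
    as significant.  Contiguity is in T (consecutive integers present in
    the mapping).
    """
    ts = sorted(per_T_pvalues)
    ranges: list[tuple[int, int]] = []
    run_start: int | None = None
    prev_t: int | None = None
    for t in ts:
        p = per_T_pvalues[t]
        sig = (not np.isnan(p)) and min(1.0, p * bonferroni_factor) < alpha
        contiguous = prev_t is not None and t == prev_t + 1
        if sig:
            if run_start is None or not contiguous:
                if run_start is not None:
                    ranges.append((run_start, prev_t))
                run_start = t
        else:
            if run_start is not None:
                ranges.append((run_start, prev_t))
                run_start = None
        prev_t = t
    if run_start is not None:
        ranges.append((run_start, prev_t))
    return ranges


def quartile_summary(values: Sequence[float]) -> QuartileSummary:
    """Median, quartiles (linear interpolation at 1 + p(n-1)) and mean."""
    v = np.asarray(values, float)
    if v.size < 1:
        raise DegenerateInputError("empty vector")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return QuartileSummary(float(med), float(q1), float(q3), float(v.mean()))


def sdnn(series: RRSeries, window: tuple[float, float] | None = None) -> float:
    """Sample standard deviation (ms) of original RR intervals in a window.

    Reconstructed beats are excluded; the n-1 denominator is used.
    """
    keep = ~series.reconstructed
    if window is not None:
        t0, t1 = window
        keep &= (series.onset_time >= t0) & (series.onset_time <= t1)
    rr = series.rr[keep]
    if rr.size < 2:
        raise DegenerateInputError("need at least 2 original beats for SDNN")
    return float(np.std(rr, ddof=1))
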