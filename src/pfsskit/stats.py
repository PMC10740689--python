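"""Benchmark statistics: rankings, correlation with standard metrics,
regression outlier diagnostics, and pairwise Mann-Whitney comparisons.

The regression diagnostics follow the standard internally-studentized
residual: for an ordinary least squares fit of a metric on gPFSS (one point
per group), ``std_residual_i = e_i / (s * sqrt(1 - h_ii))`` with ``s`` the
residual standard error and ``h_ii`` the leverage; points beyond |3| are
flagged as outliers under the three-sigma rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Collection, Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import (ComparisonError, CorrelationError, DomainValueError,
                     LeverageError, RankingError)
from .io import ASCENDING_METRICS, METRICS, MetricRecord

__all__ = [
    "RankEntry", "PointDiagnostic", "RegressionDiagnostics", "PairwiseComparison",
    "rank_groups", "metric_averages", "overlap_top_k",
    "correlate", "regression_diagnostics",
    "mann_whitney_compare", "bonferroni_threshold", "pairwise_campaign",
]

#: Ranking keys drawn from the group assessment rather than a metric table.
ASSESSMENT_KEYS = ("cumpfss", "gpfss")


@dataclass(frozen=True)
class RankEntry:
    rank: int  # dense rank: tied scores share a rank
    group_name: str
    score: float


@dataclass(frozen=True)
class PointDiagnostic:
    group_name: str
    x: float
    y: float
    leverage: float
    std_residual: float
    outlier: bool


@dataclass(frozen=True)
class RegressionDiagnostics:
    """OLS fit of one standard metric against gPFSS, with per-point
    leverages, standardized residuals and outlier flags."""

    metric_name: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    points: list[PointDiagnostic]


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    n_common: int
    u_statistic: float
    p_value: float
    significant_after_bonferroni: bool
    alpha_corrected: float


# ---------------------------------------------------------------------------
# rankings


def rank_groups(scores: Mapping[str, float], key: str) -> list[RankEntry]:
    """Order groups by a score, best first.

    ``key`` decides the direction: cumPFSS/gPFSS and the LDDT/GDT/GDC family
    rank descending, RMS metrics ascending (smaller deviation is better).
    Ties share a dense rank and are ordered lexicographically by group name.
    """
    if key not in ASSESSMENT_KEYS + METRICS:
        raise RankingError(f"unknown ranking key {key!r}")
    if not scores:
        raise RankingError("rank_groups requires at least one group")
    ascending = key in ASCENDING_METRICS
    ordered = sorted(scores.items(),
                     key=lambda kv: (kv[1] if ascending else -kv[1], kv[0]))
    entries: list[RankEntry] = []
    rank = 0
    previous: float | None = None
    for group, score in ordered:
        if previous is None or score != previous:
            rank += 1
            previous = score
        entries.append(RankEntry(rank=rank, group_name=group, score=score))
    return entries


def metric_averages(records: Iterable[MetricRecord], metric_name: str,
                    domains: Collection[str] | None = None) -> dict[str, float]:
    """Per-group mean of one standard metric, optionally restricted to a
    domain set (e.g. the domains of one difficulty category)."""
    if metric_name not in METRICS:
        raise RankingError(f"unknown metric {metric_name!r}")
    values: dict[str, list[float]] = {}
    for r in records:
        if r.metric_name != metric_name:
            continue
        if domains is not None and r.domain_id not in domains:
            continue
        values.setdefault(r.group_name, []).append(r.value)
    return {g: float(np.mean(v)) for g, v in values.items()}


def _top_k_set(ranking: Sequence, k: int) -> set[str]:
    names = [e.group_name if isinstance(e, RankEntry) else e for e in ranking]
    if k > len(names):
        raise RankingError(f"k={k} exceeds ranking length {len(names)}")
    return set(names[:k])


def overlap_top_k(rank1: Sequence, rank2: Sequence, k: int) -> tuple[int, float]:
    """Size and percentage of the intersection of two top-k group sets.

    Accepts rankings as lists of :class:`RankEntry` or of plain group names.
    """
    count = len(_top_k_set(rank1, k) & _top_k_set(rank2, k))
    return count, 100.0 * count / k


# ---------------------------------------------------------------------------
# correlation and regression diagnostics


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise CorrelationError(f"correlation requires >=3 paired points, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationError("correlation undefined: zero variance in a coordinate")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def regression_diagnostics(groups: Sequence[str],
                           x: Sequence[float],
                           y: Sequence[float],
                           metric_name: str = "",
                           outlier_threshold: float = 3.0) -> RegressionDiagnostics:
    """OLS fit of y on x with leverages and internally studentized residuals.

    Requires >=4 points so the residual standard error has at least two
    degrees of freedom.  ``h_ii = 1/n + (x_i - mean)^2 / Sxx``; leverages sum
    to 2 for a simple regression with intercept.  A point is an outlier when
    ``|std_residual| > outlier_threshold`` (default 3, the three-sigma rule).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not (len(groups) == n == len(y)):
        raise LeverageError("groups, x and y must have equal length")
    if n < 4:
        raise LeverageError(f"regression diagnostics require >=4 points, got {n}")
    if np.ptp(x) == 0:
        raise LeverageError("leverages undefined: all x values identical")

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    influence = OLSInfluence(fit)
    leverages = influence.hat_matrix_diag
    std_residuals = influence.resid_studentized_internal
    pearson_r, p_value = correlate(x, y)

    points = [PointDiagnostic(
        group_name=g, x=float(xi), y=float(yi),
        leverage=float(h), std_residual=float(t),
        outlier=bool(abs(t) > outlier_threshold),
    ) for g, xi, yi, h, t in zip(groups, x, y, leverages, std_residuals)]
    return RegressionDiagnostics(
        metric_name=metric_name,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        pearson_r=pearson_r,
        p_value=p_value,
        points=points,
    )


# ---------------------------------------------------------------------------
# pairwise comparisons

#: Exact Mann-Whitney null distribution is used up to this combined sample
#: size, provided there are no ties; beyond it the tie-corrected normal
#: approximation applies.
EXACT_MW_LIMIT = 20


def mann_whitney_compare(a: Sequence[float], b: Sequence[float], *,
                         group_a: str = "a", group_b: str = "b",
                         alpha_corrected: float = 0.05) -> PairwiseComparison:
    """Two-sided Mann-Whitney U comparison of two score arrays.

    Uses the exact null distribution when the combined sample is small
    (<= ``EXACT_MW_LIMIT``) and tie-free, and the tie-corrected normal
    approximation otherwise.  ``significant_after_bonferroni`` compares the
    p-value against ``alpha_corrected``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ComparisonError("Mann-Whitney comparison requires non-empty samples")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MW_LIMIT and not has_ties) else "asymptotic"
    result = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return PairwiseComparison(
        group_a=group_a,
        group_b=group_b,
        n_common=min(len(a), len(b)),
        u_statistic=float(result.statistic),
        p_value=float(result.pvalue),
        significant_after_bonferroni=bool(result.pvalue < alpha_corrected),
        alpha_corrected=alpha_corrected,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance threshold ``alpha / m``."""
    if not 0 < alpha < 1:
        raise DomainValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise DomainValueError(f"number of comparisons must be >= 1, got {m}")
    return alpha / m


def pairwise_campaign(per_domain: Mapping[str, Mapping[str, float]],
                      domains: Collection[str],
                      alpha: float = 0.05) -> list[PairwiseComparison]:
    """Head-to-head Mann-Whitney comparisons of per-domain gPFSS arrays.

    Restricted to groups that addressed every domain in ``domains`` (full
    coverage), mirroring a campaign where each of the qualifying groups is
    compared against every other; the Bonferroni divisor is the number of
    comparisons per group, i.e. (number of qualifying groups - 1).
    """
    domain_set = set(domains)
    full = sorted(g for g, dom in per_domain.items() if domain_set <= set(dom))
    if len(full) < 2:
        return []
    m = len(full) - 1
    threshold = bonferroni_threshold(alpha, m)
    ordered = sorted(domain_set)
    comparisons = []
    for ga, gb in combinations(full, 2):
        comparison = mann_whitney_compare(
            [per_domain[ga][d] for d in ordered],
            [per_domain[gb][d] for d in ordered],
            group_a=ga, group_b=gb, alpha_corrected=threshold)
        comparisons.append(comparison)
    return comparisons
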