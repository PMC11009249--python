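"""Experiment-level statistics: encapsulation λ, outliers, group comparisons.

The mean number of cells per droplet (λ) under Poisson encapsulation is
estimated by the sample mean of per-droplet counts (the Poisson MLE), with
the empty-fraction estimator ``-ln(P(empty))`` kept as a cross-check.
Per-animal summary values can be screened with a single-pass two-sided
Grubbs test, and distribution comparisons delegate to SciPy's
Kolmogorov-Smirnov, Wilcoxon signed-rank, and Kruskal-Wallis routines, the
last followed by Dunn's post-hoc z-tests with Bonferroni adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LambdaEstimate",
    "OutlierReport",
    "estimate_lambda",
    "lambda_from_empty_fraction",
    "grubbs_test",
    "grubbs_critical_value",
    "dunn_posthoc",
    "compare_distributions",
    "significance_tier",
]


@dataclass(frozen=True)
class LambdaEstimate:
    """Poisson-MLE estimate of the mean cells-per-droplet occupancy."""

    lambda_hat: float
    n_droplets: int
    standard_error: float


@dataclass(frozen=True)
class OutlierReport:
    """Result of one Grubbs pass: at most one exclusion."""

    tested_values: tuple
    excluded_index: Optional[int]
    G_statistic: float
    critical_value: float
    alpha: float


def estimate_lambda(occupancy_counts: Sequence[int]) -> LambdaEstimate:
    """λ as the sample mean of per-droplet counts; SE = sqrt(λ/n)."""
    counts = np.asarray(occupancy_counts)
    if counts.size == 0:
        raise ValueError("occupancy counts must be nonempty")
    if np.any(counts < 0):
        raise ValueError("occupancy counts must be >= 0")
    lam = float(counts.mean())
    return LambdaEstimate(
        lambda_hat=lam,
        n_droplets=int(counts.size),
        standard_error=math.sqrt(lam / counts.size),
    )


def lambda_from_empty_fraction(occupancy_counts: Sequence[int]) -> float:
    """Cross-check estimator: ``-ln(fraction of empty droplets)``."""
    counts = np.asarray(occupancy_counts)
    if counts.size == 0:
        raise ValueError("occupancy counts must be nonempty")
    frac_empty = float(np.mean(counts == 0))
    if frac_empty == 0:
        raise ValueError("no empty droplets; empty-fraction estimator undefined")
    return -math.log(frac_empty)


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> OutlierReport:
    """Single-pass two-sided Grubbs outlier test.

    ``G = max |x - mean| / SD`` is compared against the t-based critical
    value; at most the single most extreme value is flagged. A zero-SD
    sample yields a no-outlier report.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test requires n >= 3")
    sd = float(x.std(ddof=1))
    if sd == 0:
        return OutlierReport(
            tested_values=tuple(x),
            excluded_index=None,
            G_statistic=0.0,
            critical_value=grubbs_critical_value(x.size, alpha),
            alpha=alpha,
        )
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    G = float(dev[idx] / sd)
    crit = grubbs_critical_value(x.size, alpha)
    return OutlierReport(
        tested_values=tuple(x),
        excluded_index=idx if G > crit else None,
        G_statistic=G,
        critical_value=crit,
        alpha=alpha,
    )


def significance_tier(p: float) -> str:
    """Star notation for a p-value: <0.05 *, <0.01 **, <0.001 ***, <0.0001 ****."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def dunn_posthoc(
    groups: Sequence[Sequence[float]], p_adjust: str = "bonferroni"
) -> dict[tuple[int, int], float]:
    """Dunn's multiple-comparison z-tests on pooled mean ranks.

    Follows a Kruskal-Wallis test: pooled ranks with tie correction, pairwise
    z statistics on mean-rank differences, two-sided normal p-values adjusted
    by Bonferroni (the only supported adjustment).
    """
    if p_adjust != "bonferroni":
        raise ValueError("only Bonferroni adjustment is supported")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction: sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    mean_ranks = []
    start = 0
    for arr in arrays:
        mean_ranks.append(float(ranks[start : start + arr.size].mean()))
        start += arr.size
    m = len(arrays) * (len(arrays) - 1) // 2
    out: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(len(arrays)), 2):
        var = (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))) * (
            1.0 / arrays[i].size + 1.0 / arrays[j].size
        )
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
        out[(i, j)] = min(1.0, p * m)
    return out


def compare_distributions(
    a: Sequence[float],
    b: Optional[Sequence[float]] = None,
    method: str = "kolmogorov_smirnov",
    groups: Optional[Sequence[Sequence[float]]] = None,
) -> dict:
    """Distribution comparison with the study's standard tests.

    ``kolmogorov_smirnov``: two-sample KS on a vs b. ``wilcoxon_paired``:
    signed-rank test on paired samples of equal length (all-zero differences
    return p = 1 by convention). ``kruskal_wallis_dunn``: Kruskal-Wallis
    over ``groups`` followed by Bonferroni-adjusted Dunn post-hoc p-values.
    Returns a dict with the statistic, p-value(s) and significance tier.
    """
    if method == "kolmogorov_smirnov":
        if b is None:
            raise ValueError("KS test needs two samples")
        res = stats.ks_2samp(np.asarray(a, float), np.asarray(b, float))
        return {
            "method": method,
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "tier": significance_tier(float(res.pvalue)),
        }
    if method == "wilcoxon_paired":
        if b is None:
            raise ValueError("paired test needs two samples")
        x = np.asarray(a, float)
        y = np.asarray(b, float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        if np.all(x == y):
            return {"method": method, "statistic": 0.0, "p_value": 1.0, "tier": "ns"}
        res = stats.wilcoxon(x, y)
        return {
            "method": method,
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "tier": significance_tier(float(res.pvalue)),
        }
    if method == "kruskal_wallis_dunn":
        if groups is None:
            groups = [a, b] if b is not None else None
        if groups is None or len(groups) < 2:
            raise ValueError("Kruskal-Wallis needs >= 2 groups")
        res = stats.kruskal(*[np.asarray(g, float) for g in groups])
        posthoc = dunn_posthoc(groups)
        return {
            "method": method,
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "tier": significance_tier(float(res.pvalue)),
            "dunn_p_values": {f"{i}-{j}": p for (i, j), p in posthoc.items()},
        }
    raise ValueError(f"unknown method {method!r}")
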