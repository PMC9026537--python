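"""Nonparametric two-group comparisons and mean ± SD summary tables.

Two tests are provided, matching common OCTA-cohort practice:

* Wilcoxon signed-rank — a paired test. Zero differences are dropped
  (Wilcoxon convention); absolute differences are mid-ranked. The exact
  two-sided p comes from full enumeration of all 2^n sign assignments
  whenever n <= 12 (ties are then handled exactly), from the standard
  exact distribution for 13 <= n <= 25 without ties, and otherwise from
  the normal approximation with continuity and tie correction.
* Mann–Whitney U — an independent-samples rank-sum test. Exact by full
  enumeration of group assignments for m + n <= 14 (mid-ranks, so ties
  are exact), by the standard exact distribution for m + n <= 20
  without ties, and otherwise by the tie-corrected normal approximation
  with continuity correction.

Applying a paired signed-rank test to two independent cohorts pairs the
samples by row order, which is statistically questionable; when asked
to do so, :func:`summarize_groups` emits a warning documenting the
caveat and proceeds, so that the conventional analysis can still be
reproduced verbatim.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "GroupComparison",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "summarize_groups",
    "comparisons_to_frame",
]

_ENUM_LIMIT_SIGNED_RANK = 12  # 2^12 sign vectors
_ENUM_LIMIT_RANK_SUM = 14  # C(14, 7) = 3432 assignments


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p_value: float
    n: int
    method: str  # "enumeration", "exact", "normal_approx", "degenerate"
    degenerate: bool = False
    note: str = ""


@dataclass(frozen=True)
class GroupComparison:
    """One summary-table row: a metric compared between two groups."""

    metric: str
    radius_px: int
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    result: TestResult = field(repr=False)

    @property
    def p_value(self) -> float:
        return self.result.p_value

    def formatted(self) -> dict[str, str]:
        """Mean ± SD to two decimals, table-presentation style."""
        return {
            "metric": self.metric,
            "radius_px": str(self.radius_px),
            self.group_a: f"{self.mean_a:.2f} ± {self.sd_a:.2f}",
            self.group_b: f"{self.mean_b:.2f} ± {self.sd_b:.2f}",
            "p": "degenerate" if self.result.degenerate else f"{self.p_value:.3g}",
        }


def _two_sided_from_distribution(observed: float, distribution: np.ndarray) -> float:
    """Two-sided p = 2·min(P(T<=obs), P(T>=obs)), capped at 1."""
    total = distribution.size
    lo = np.count_nonzero(distribution <= observed + 1e-9) / total
    hi = np.count_nonzero(distribution >= observed - 1e-9) / total
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples (paired by order).

    Returns the smaller signed-rank sum W = min(W+, W-) as the statistic.
    All-zero differences are degenerate: no information against the null,
    reported with p = nan and the degenerate flag set.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"paired samples must be 1-D and equal-length, got {x.shape} vs {y.shape}"
            " (for independent groups use mann_whitney_u)"
        )
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return TestResult(
            test="wilcoxon_signed_rank",
            statistic=float("nan"),
            p_value=float("nan"),
            n=0,
            method="degenerate",
            degenerate=True,
            note="all paired differences are zero",
        )
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks.sum() - w_plus)
    w = min(w_plus, w_minus)
    has_ties = np.unique(np.abs(d)).size < n

    if n <= _ENUM_LIMIT_SIGNED_RANK:
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        distribution = signs @ ranks  # W+ for every sign assignment
        p = _two_sided_from_distribution(w_plus, distribution)
        method = "enumeration"
    elif not has_ties and n <= 25:
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="exact")
        p, method = float(res.pvalue), "exact"
    else:
        mu = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        if var == 0.0:
            p, method = 1.0, "normal_approx"
        else:
            # continuity correction toward the mean
            z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(var)
            p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
            method = "normal_approx"
    return TestResult(
        test="wilcoxon_signed_rank", statistic=w, p_value=p, n=n, method=method
    )


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test on independent samples.

    Returns U = min(U1, U2) as the statistic (mid-ranks under ties).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty 1-D arrays")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = float(n1 * n2 - u1)
    u = min(u1, u2)
    has_ties = np.unique(combined).size < n1 + n2

    if n1 + n2 <= _ENUM_LIMIT_RANK_SUM:
        base = n1 * (n1 + 1) / 2.0
        distribution = np.array(
            [sum(c) - base for c in itertools.combinations(ranks, n1)]
        )
        p = _two_sided_from_distribution(u1, distribution)
        method = "enumeration"
    elif not has_ties and n1 + n2 <= 20:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p, method = float(res.pvalue), "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p, method = float(res.pvalue), "normal_approx"
    return TestResult(test="mann_whitney_u", statistic=u, p_value=p, n=n1 + n2, method=method)


_TESTS = {
    "wilcoxon_signed_rank": wilcoxon_signed_rank,
    "mann_whitney_u": mann_whitney_u,
}

_EYE_METRICS = ("fd_percent", "n_fd", "mean_fd_size_um2", "total_fd_area_mm2")
_METRIC_LABELS = {
    "fd_percent": "mean FD%",
    "n_fd": "mean number of FDs",
    "mean_fd_size_um2": "mean FD size (um2)",
    "total_fd_area_mm2": "mean total FD area (mm2)",
}


def _compare(metric, radius, group_a, group_b, a, b, test) -> GroupComparison:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if test == "wilcoxon_signed_rank":
        if a.size != b.size:
            raise ValueError(
                "signed-rank requested on unequal group sizes "
                f"({a.size} vs {b.size}); use mann_whitney_u"
            )
        result = wilcoxon_signed_rank(a, b)
    else:
        result = _TESTS[test](a, b)
    return GroupComparison(
        metric=metric,
        radius_px=radius,
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_a=a.size,
        n_b=b.size,
        result=result,
    )


def summarize_groups(
    records,
    radius_px: int,
    test: str = "wilcoxon_signed_rank",
    group_a: str = "angioid_streaks",
    group_b: str = "control",
) -> list[GroupComparison]:
    """Compare the two groups metric by metric at one window radius.

    Produces one row per per-eye-averaged metric (FD%, FD count, mean FD
    size, total FD area) and one row per corner-quadrant FD%, each with
    group mean ± SD and the requested test's two-sided p.

    ``records`` are :class:`~ccflow.fd_metrics.EyeRecord` objects; both
    groups need at least two eyes.
    """
    if test not in _TESTS:
        raise ValueError(f"test must be one of {sorted(_TESTS)}, got {test!r}")
    rec_a = [r for r in records if r.group == group_a]
    rec_b = [r for r in records if r.group == group_b]
    for name, rec in ((group_a, rec_a), (group_b, rec_b)):
        if len(rec) < 2:
            raise ValueError(f"group {name!r} has {len(rec)} eye(s); need >= 2")
    if test == "wilcoxon_signed_rank":
        if len(rec_a) != len(rec_b):
            warnings.warn(
                "signed-rank needs equal group sizes to pair by row order; "
                f"groups have {len(rec_a)} vs {len(rec_b)} eyes — "
                "falling back to the rank-sum (Mann-Whitney) test",
                stacklevel=2,
            )
            test = "mann_whitney_u"
        else:
            warnings.warn(
                "signed-rank is a paired test; applying it to independent groups "
                "pairs eyes by row order — interpret p with caution",
                stacklevel=2,
            )
    rows: list[GroupComparison] = []
    for metric in _EYE_METRICS:
        rows.append(
            _compare(
                _METRIC_LABELS[metric],
                radius_px,
                group_a,
                group_b,
                [getattr(r.averages[radius_px], metric) for r in rec_a],
                [getattr(r.averages[radius_px], metric) for r in rec_b],
                test,
            )
        )
    from .fd_metrics import CORNERS

    for corner in CORNERS:
        rows.append(
            _compare(
                f"FD% in the {corner} quadrant",
                radius_px,
                group_a,
                group_b,
                [r.corner_metrics[radius_px][corner].fd_percent for r in rec_a],
                [r.corner_metrics[radius_px][corner].fd_percent for r in rec_b],
                test,
            )
        )
    return rows


def comparisons_to_frame(rows: list[GroupComparison]):
    """Summary rows as a tidy DataFrame (numeric) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "metric": [r.metric for r in rows],
            "radius_px": [r.radius_px for r in rows],
            "group_a": [r.group_a for r in rows],
            "group_b": [r.group_b for r in rows],
            "mean_a": [r.mean_a for r in rows],
            "sd_a": [r.sd_a for r in rows],
            "mean_b": [r.mean_b for r in rows],
            "sd_b": [r.sd_b for r in rows],
            "n_a": [r.n_a for r in rows],
            "n_b": [r.n_b for r in rows],
            "test": [r.result.test for r in rows],
            "statistic": [r.result.statistic for r in rows],
            "p_value": [r.result.p_value for r in rows],
            "method": [r.result.method for r in rows],
        }
    )
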