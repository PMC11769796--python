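"""Condition comparisons: Mann-Whitney U per section and overall.

The per-section comparison asks, at each optical height, whether coverage
differs between conditions (e.g. static vs dynamic culture) across
replicates.  Because replicates — not sections — are the independent
units, the *overall* comparison collapses each replicate's profile to a
single scalar (the trapezoidal area under coverage vs height) and runs one
Mann-Whitney U test on those summaries; pooling sections across replicates
would pseudo-replicate.

The U statistic follows the convention U = #{(x_i, y_j) : x_i > y_j} +
(ties)/2, so U = 0 when every x lies below every y.  For small samples
(n1 + n2 <= 12 by default) the two-sided p-value is exact, from full
enumeration of the C(n1+n2, n1) group labelings of the pooled data (ties
handled naturally, since enumeration permutes the observed values); larger
samples use the tie-corrected normal approximation with continuity
correction.  Raw p-values are reported alongside Holm-adjusted ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erfc, sqrt
from typing import Sequence

import numpy as np

from .morpho import CoverageProfile

EXACT_LIMIT = 12


@dataclass
class TestResult:
    """One Mann-Whitney comparison."""

    statistic: float  # U
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "normal-approx"
    comparison: str = ""
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.statistic <= self.n1 * self.n2):
            raise ValueError("U outside [0, n1*n2]")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{x_i > y_j} + half the tied pairs (pair counting)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float, alternative: str) -> float:
    """Permutation p by full enumeration of group labelings of the pooled data."""
    pooled = np.concatenate([x, y])
    n = pooled.size
    n1 = x.size
    total = comb(n, n1)
    mu = n1 * y.size / 2.0
    count = 0
    idx_all = frozenset(range(n))
    for picks in combinations(range(n), n1):
        xs = pooled[list(picks)]
        ys = pooled[list(idx_all - set(picks))]
        u = _u_statistic(xs, ys)
        if alternative == "two-sided":
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        elif alternative == "greater":
            if u >= u_obs - 1e-12:
                count += 1
        else:  # less
            if u <= u_obs + 1e-12:
                count += 1
    return count / total


def _normal_p(
    x: np.ndarray, y: np.ndarray, u_obs: float, alternative: str
) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    sd = sqrt(var)

    def sf(z: float) -> float:
        return 0.5 * erfc(z / sqrt(2.0))

    if alternative == "two-sided":
        z = (abs(u_obs - mu) - 0.5) / sd
        return min(1.0, 2.0 * sf(max(z, 0.0)))
    if alternative == "greater":
        return sf((u_obs - mu - 0.5) / sd)
    return sf((mu - u_obs - 0.5) / sd)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = EXACT_LIMIT,
    comparison: str = "",
) -> TestResult:
    """Mann-Whitney U test of two independent samples.

    Exact enumeration when n1 + n2 <= ``exact_limit``, tie-corrected normal
    approximation otherwise.  ``alternative`` follows the U convention
    above: "greater" means x tends to exceed y.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if x.size + y.size <= exact_limit:
        p = _exact_p(x, y, u, alternative)
        method = "exact"
    else:
        p = _normal_p(x, y, u, alternative)
        method = "normal-approx"
    return TestResult(
        statistic=u,
        p_value=max(p, np.finfo(float).tiny),
        n1=int(x.size),
        n2=int(y.size),
        method=method,
        comparison=comparison,
    )


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def per_section_comparison(
    profiles_a: Sequence[CoverageProfile],
    profiles_b: Sequence[CoverageProfile],
    alternative: str = "two-sided",
    comparison: str = "a-vs-b",
) -> tuple[list[TestResult], TestResult]:
    """Mann-Whitney per section plus one overall across-sections test.

    Per section, replicate coverage values of the two conditions are
    compared (sections where any replicate is missing are skipped).  The
    overall test compares per-replicate profile AUCs.  Holm adjustment is
    applied across the per-section tests and stored in ``adjusted_p``; raw
    p-values are kept.
    """
    if not profiles_a or not profiles_b:
        raise ValueError("both conditions need at least one replicate profile")
    heights = profiles_a[0].heights
    for p in list(profiles_a) + list(profiles_b):
        if p.heights.shape != heights.shape or not np.allclose(p.heights, heights):
            raise ValueError("profiles must share an aligned section grid")

    cov_a = np.vstack([p.coverage for p in profiles_a])
    cov_b = np.vstack([p.coverage for p in profiles_b])
    per_section: list[TestResult] = []
    for j in range(heights.size):
        xa, xb = cov_a[:, j], cov_b[:, j]
        if np.isnan(xa).any() or np.isnan(xb).any():
            continue
        res = mann_whitney_u(
            xa, xb, alternative=alternative, comparison=f"{comparison}/section{j}"
        )
        per_section.append(res)
    if per_section:
        adj = holm_adjust([r.p_value for r in per_section])
        for r, a in zip(per_section, adj):
            r.adjusted_p = float(a)

    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("overall test needs >= 2 replicates per condition")
    auc_a = [p.auc() for p in profiles_a]
    auc_b = [p.auc() for p in profiles_b]
    overall = mann_whitney_u(
        auc_a, auc_b, alternative=alternative, comparison=f"{comparison}/overall"
    )
    return per_section, overall
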