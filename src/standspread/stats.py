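"""Self-contained implementations of the statistics used by the analysis.

Three quantities are needed: the two-sample Kolmogorov-Smirnov statistic D,
the Wilcoxon rank-sum statistic (reported in the Mann-Whitney U convention,
i.e. the number of (x, y) pairs with x above y, ties counting one half), and
median / interquartile range under linear-interpolation quantiles.

p-values are large-sample approximations: the asymptotic Kolmogorov
distribution for D, and a normal approximation with tie-corrected variance
and continuity correction for the rank-sum.  Exact small-sample tables are
out of scope; the analysis operates at sample sizes well above 50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class EmptySampleError(ValueError):
    """A statistic was requested for an empty sample."""


@dataclass
class TestResult:
    statistic_name: str
    statistic_value: float
    n1: int
    n2: int
    p_value: float
    convention: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "value": self.statistic_value,
            "n1": self.n1,
            "n2": self.n2,
            "p_approx": self.p_value,
            "convention": self.convention,
            **self.extra,
        }


def _as_sample(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise EmptySampleError(f"{name} sample is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} sample contains non-finite values")
    return arr


def _kolmogorov_sf(t: float, terms: int = 101) -> float:
    """Survival function of the Kolmogorov distribution, Q(t) = 2 sum_{j>=1}
    (-1)^(j-1) exp(-2 j^2 t^2)."""
    if t <= 0:
        return 1.0
    total = 0.0
    for j in range(1, terms):
        term = 2.0 * (-1.0) ** (j - 1) * math.exp(-2.0 * j * j * t * t)
        total += term
        if abs(term) < 1e-16:
            break
    return min(1.0, max(0.0, total))


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov statistic D with asymptotic p-value.

    D is the supremum over thresholds of the absolute difference between the
    two empirical CDFs.  The p-value uses the asymptotic Kolmogorov
    distribution with effective sample size n1*n2/(n1+n2).
    """
    xs = np.sort(_as_sample(x, "x"))
    ys = np.sort(_as_sample(y, "y"))
    n1, n2 = xs.size, ys.size
    grid = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, grid, side="right") / n1
    cdf_y = np.searchsorted(ys, grid, side="right") / n2
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    ne = n1 * n2 / (n1 + n2)
    p = _kolmogorov_sf(math.sqrt(ne) * d)
    return TestResult(
        statistic_name="ks_D",
        statistic_value=d,
        n1=n1,
        n2=n2,
        p_value=p,
        convention="sup |ECDF_x - ECDF_y|; asymptotic p, effective n = n1*n2/(n1+n2)",
    )


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with tied values sharing the mean of their rank range."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum / Mann-Whitney test in the U convention.

    The reported statistic W is the Mann-Whitney count of (x_i, y_j) pairs
    with x_i > y_j, ties counting 1/2 — equivalently the rank sum of x
    (midranks for ties) minus n1(n1+1)/2.  The raw rank sum is also carried
    in ``extra`` for transparency.  ``alternative`` is one of ``two-sided``,
    ``greater`` (x tends larger), ``less``.
    """
    if alternative not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    xs = _as_sample(x, "x")
    ys = _as_sample(y, "y")
    n1, n2 = xs.size, ys.size
    combined = np.concatenate([xs, ys])
    ranks = _midranks(combined)
    rank_sum = float(np.sum(ranks[:n1]))
    w = rank_sum - n1 * (n1 + 1) / 2.0

    n = n1 + n2
    mean = n1 * n2 / 2.0
    # tie-corrected variance of U
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    if n > 1:
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:  # pragma: no cover - degenerate
        var = 0.0

    if var <= 0:
        p = 1.0
    else:
        sd = math.sqrt(var)
        if alternative == "greater":
            p = _norm_sf((w - mean - 0.5) / sd)
        elif alternative == "less":
            p = _norm_sf((mean - w - 0.5) / sd)
        else:
            z = (abs(w - mean) - 0.5) / sd
            p = min(1.0, 2.0 * _norm_sf(z))
    p = min(1.0, max(0.0, p))
    return TestResult(
        statistic_name="wilcoxon_W",
        statistic_value=float(w),
        n1=n1,
        n2=n2,
        p_value=p,
        convention=(
            "Mann-Whitney U for the first sample (pairs with x > y, ties 1/2); "
            f"normal approximation, tie-corrected, continuity-corrected, {alternative}"
        ),
        extra={"rank_sum": rank_sum},
    )


def median_iqr(values) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1), linear-interpolation
    quantiles."""
    arr = _as_sample(values, "values")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    return float(med), float(q3 - q1)
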