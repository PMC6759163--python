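"""Penalized-contrast change-point segmentation (Lavielle method).

The series is partitioned into K contiguous segments minimising the
within-segment sum of squared deviations from segment means; the optimum
for every K up to Kmax is found exactly by dynamic programming.  K itself
is chosen by the penalized-contrast rule used by the standard animal-
trajectory implementations: the contrast curve J(K) is rescaled to decrease
from Kmax to 1, and the largest K whose discrete second difference of the
rescaled curve exceeds a threshold S (default 0.75) is retained; if no K
qualifies the series is left unsegmented (K = 1).
"""

from __future__ import annotations

import numpy as np

from .tracks import FPTSeries, Segmentation


def sse_cost_matrix(x: np.ndarray) -> np.ndarray:
    """C[i, j] = sum of squared deviations of x[i..j] from its mean."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = j - i + 1
    sum1 = s1[j + 1] - s1[i]
    sum2 = s2[j + 1] - s2[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        c = sum2 - sum1 * sum1 / length
    c[length < 1] = np.inf
    return np.maximum(c, 0.0)


def optimal_partitions(
    x: np.ndarray, lmin: int, kmax: int
) -> tuple[np.ndarray, list[list[int]]]:
    """Exact DP optimum of the SSE contrast for K = 1..kmax.

    Returns ``(J, bounds_per_k)`` where ``J[K-1]`` is the minimal contrast
    with K segments (NaN when infeasible under ``lmin``) and
    ``bounds_per_k[K-1]`` the segment start indices of that optimum.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if lmin < 1:
        raise ValueError("lmin must be >= 1")
    kmax = max(1, min(kmax, n // lmin))
    cost = sse_cost_matrix(x)
    # forbid segments shorter than lmin
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cost[(j - i + 1) < lmin] = np.inf

    dp = np.full((kmax, n), np.inf)
    back = np.zeros((kmax, n), dtype=int)
    dp[0] = cost[0]
    for k in range(1, kmax):
        # candidate start i of the last segment: dp[k-1][i-1] + cost[i, j]
        prev = dp[k - 1]
        cand = prev[:-1, None] + cost[1:, :]  # rows i-1 = 0..n-2 -> start i = 1..n-1
        best = np.argmin(cand, axis=0)
        dp[k] = cand[best, np.arange(n)]
        back[k] = best + 1  # start index of last segment

    J = dp[:, n - 1]
    bounds: list[list[int]] = []
    for k in range(kmax):
        if not np.isfinite(J[k]):
            bounds.append([])
            continue
        starts = []
        j_end = n - 1
        for kk in range(k, 0, -1):
            s = int(back[kk, j_end])
            starts.append(s)
            j_end = s - 1
        starts.append(0)
        bounds.append(sorted(starts))
    return J, bounds


def choose_k(J: np.ndarray, threshold: float = 0.75) -> int:
    """Penalized-contrast choice of the number of segments.

    J is rescaled so that it decreases from Kmax (at K=1) to 1 (at K=Kmax);
    the chosen K is the largest with second difference D(K) =
    Jt(K-1) - 2 Jt(K) + Jt(K+1) > threshold, or 1 if none qualifies
    (including flat/degenerate contrast curves).
    """
    J = np.asarray(J, dtype=float)
    finite = np.isfinite(J)
    if finite.sum() < 3:
        return 1
    kmax_eff = int(np.max(np.flatnonzero(finite))) + 1
    Jf = J[:kmax_eff]
    span = Jf[0] - Jf[-1]
    if span <= 0 or not np.isfinite(span) or Jf[0] <= 1e-300:
        return 1
    jt = (Jf - Jf[-1]) / span * (kmax_eff - 1) + 1
    best = 1
    for k in range(2, kmax_eff):
        d = jt[k - 2] - 2.0 * jt[k - 1] + jt[k]
        if d > threshold:
            best = k
    return best


def lavielle_partition(
    x: np.ndarray, lmin: int = 5, kmax: int = 30, threshold: float = 0.75
) -> tuple[list[tuple[int, int]], int, np.ndarray]:
    """Segment a plain series; returns (bounds, K, J)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * lmin:
        raise ValueError(
            f"series of length {n} too short to segment with lmin={lmin}"
        )
    J, bounds_per_k = optimal_partitions(x, lmin, kmax)
    # a (numerically) constant series has nothing to segment; the prefix-sum
    # SSE carries cancellation noise of order eps * sum(x^2)
    if J[0] <= 1e-10 * max(1.0, float(np.sum(x * x))):
        k = 1
    else:
        k = choose_k(J, threshold)
    starts = bounds_per_k[k - 1]
    bounds = [
        (starts[m], (starts[m + 1] - 1) if m + 1 < len(starts) else n - 1)
        for m in range(len(starts))
    ]
    return bounds, k, J


def lavielle_segment(
    series: FPTSeries, lmin: int = 5, kmax: int = 30, threshold: float = 0.75
) -> Segmentation:
    """Segment the defined portion of an FPT profile.

    Undefined (border) values are excluded; segmentation runs on the longest
    contiguous defined run and its bounds are reported in the coordinates of
    the full profile.
    """
    from .fpt import longest_defined_run

    lo, hi = longest_defined_run(series.values)
    if lo < 0 or (hi - lo + 1) < 2 * lmin:
        raise ValueError(
            f"FPT series at r={series.radius_km} km has a defined run shorter "
            f"than 2*lmin={2 * lmin} vertices"
        )
    x = series.values[lo : hi + 1]
    bounds, k, J = lavielle_partition(x, lmin=lmin, kmax=kmax, threshold=threshold)
    shifted = [(s + lo, e + lo) for s, e in bounds]
    means = np.array([np.mean(series.values[s : e + 1]) for s, e in shifted])
    return Segmentation(bounds=shifted, means=means, k=k, contrasts=J)


def classify_segments(seg: Segmentation, threshold_hours: float) -> np.ndarray:
    """ARS flag per segment: mean FPT strictly above the threshold."""
    if threshold_hours < 0:
        raise ValueError("threshold must be non-negative")
    return seg.means > threshold_hours
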