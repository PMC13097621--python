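"""Rank statistics used by the rest of the package.

The Mann-Whitney U test is implemented here from first principles:
exact enumeration of the null distribution of U for small tie-free
samples, and a tie-corrected normal approximation with continuity
correction otherwise.  This keeps the distance-versus-splicing test
self-contained and lets an external implementation serve as an
independent cross-check rather than the computation itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["MWUResult", "mann_whitney_u", "median", "bootstrap_ci"]


@dataclass(frozen=True)
class MWUResult:
    """Result of a two-sided Mann-Whitney U test.

    ``u`` is the statistic for the first sample; ``u + u_other = n1*n2``.
    """

    u: float
    n1: int
    n2: int
    method: str  # "exact" or "normal-approximation"
    p_value: float
    tie_corrected_variance: float

    @property
    def u_other(self) -> float:
        return self.n1 * self.n2 - self.u


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties assigned the mean of their rank range."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled), dtype=float)
    sorted_vals = pooled[order]
    i = 0
    n = len(pooled)
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        # ranks i+1 .. j+1 share the midrank
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _exact_u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Counts of each U value (0..n1*n2) under the tie-free null.

    Classic recurrence f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u), where i
    and j are the group sizes: the largest x either beats all j ys
    (contributing j to U) or is the overall maximum of a (i, j-1) problem.
    """
    max_u = n1 * n2
    # table[j] = distribution of U for group sizes (i, j), rolled over i
    table = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
    for j in range(n2 + 1):
        table[j][0] = 1.0
    for _ in range(1, n1 + 1):
        new = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
        new[0][0] = 1.0
        for j in range(1, n2 + 1):
            new[j][j:] = table[j][: max_u + 1 - j]
            new[j] += new[j - 1]
        table = new
    return table[n2]


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> MWUResult:
    """Two-sided Mann-Whitney U test.

    Parameters
    ----------
    x, y : sequences of numbers
        The two samples; both must be non-empty and finite.
    method : {"auto", "exact", "asymptotic"}
        ``auto`` uses exact enumeration when ``n1*n2 <= 400`` and the pooled
        data contain no ties, the normal approximation (tie-corrected, with
        0.5 continuity correction) otherwise.

    Returns
    -------
    MWUResult
        U for the first sample and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")

    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    n = n1 + n2
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0

    if method == "exact" and has_ties:
        raise ValueError("exact method requires tie-free data")
    use_exact = method == "exact" or (
        method == "auto" and not has_ties and n1 * n2 <= 400
    )

    if use_exact:
        counts = _exact_u_null_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        lower = counts[: ui + 1].sum() / total
        upper = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return MWUResult(u, n1, n2, "exact", float(p), var)

    mean_u = n1 * n2 / 2.0
    if var <= 0:
        # all pooled values identical: no evidence against the null
        return MWUResult(u, n1, n2, "normal-approximation", 1.0, var)
    # continuity correction toward the mean
    z = (u - mean_u - 0.5 * np.sign(u - mean_u)) / math.sqrt(var)
    p = min(1.0, math.erfc(abs(z) / math.sqrt(2.0)))
    return MWUResult(u, n1, n2, "normal-approximation", float(p), var)


def median(values: Sequence[float]) -> float:
    """Sample median; even n averages the two central order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty sequence")
    return float(np.median(arr))


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    values: Sequence[float],
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seed-reproducible percentile bootstrap interval for a statistic."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("bootstrap of empty sequence")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    stats = np.array([statistic(arr[row]) for row in idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
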