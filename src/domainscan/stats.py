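"""Length-proportional binomial enrichment test, computed in log space.

Under the null, somatic mutations fall independently and uniformly over the
tested universe, so the count on a region of length ``l`` out of total
length ``L`` is Binomial(n, l/L).  Because n reaches millions while l/L is
tiny, every quantity is evaluated in log space:

    log Pr(X = k) = log C(n, k) + k log p + (n - k) log(1 - p)

with log-factorials from the Stirling asymptotic series (exact table below
n = 64, where the series is weakest and exact values are cheap).  A region
is a candidate when its upper tail P(X >= k) falls below the
Bonferroni-corrected level alpha/m.  The upper tail is summed directly in
log space when k exceeds the mean — computing 1 - P(X < k) there would
cancel to zero exactly in the regime of interest.
"""

from __future__ import annotations

import math

import numpy as np

from .types import RegionTestResult

__all__ = [
    "log_factorial",
    "log_binomial_pmf",
    "lower_tail",
    "upper_tail",
    "bonferroni_level",
    "test_region",
]

_EXACT_LIMIT = 64
# log(n!) for n in [0, 63]; math.log on the exact big integer is correctly
# rounded, so these carry full double precision.
_EXACT_LOG_FACT = np.array(
    [math.log(math.factorial(n)) if n > 1 else 0.0 for n in range(_EXACT_LIMIT)]
)
_HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)

# Truncation for tail sums: terms this many log-units below the running
# maximum contribute < 1e-17 relative and are dropped.
_LOG_TERM_CUTOFF = 40.0


def log_factorial(n):
    """log(n!) — exact below 64, Stirling series above.

    Accepts scalars or arrays of non-negative integers.  The series
    ``(n+1/2) log n - n + log(2*pi)/2 + 1/(12n) - 1/(360n^3) + 1/(1260n^5)``
    is accurate to well under 1e-10 relative everywhere it is used.
    """
    arr = np.asarray(n)
    if np.any(arr < 0):
        raise ValueError("log_factorial requires n >= 0")
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr).astype(np.float64)
    out = np.empty_like(arr)
    small = arr < _EXACT_LIMIT
    if small.any():
        out[small] = _EXACT_LOG_FACT[arr[small].astype(np.int64)]
    if (~small).any():
        x = arr[~small]
        inv = 1.0 / x
        inv2 = inv * inv
        series = inv / 12.0 * (1.0 - inv2 / 30.0 * (1.0 - 2.0 * inv2 / 7.0))
        out[~small] = (x + 0.5) * np.log(x) - x + _HALF_LOG_2PI + series
    return float(out[0]) if scalar else out


def _check_nk(n: int, k) -> None:
    karr = np.asarray(k)
    if n < 0 or np.any(karr < 0) or np.any(karr > n):
        raise ValueError(f"require 0 <= k <= n, got n={n}, k={k}")


def log_binomial_pmf(n: int, k, p: float):
    """log Pr(X = k) for X ~ Binomial(n, p); vectorised over k.

    p = 0 and p = 1 are handled as point masses at 0 and n.
    """
    _check_nk(n, k)
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    karr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    scalar = np.asarray(k).ndim == 0
    if p == 0.0 or p == 1.0:
        target = 0 if p == 0.0 else n
        out = np.where(karr == target, 0.0, -np.inf)
        return float(out[0]) if scalar else out.astype(np.float64)
    log_coef = log_factorial(n) - log_factorial(karr) - log_factorial(n - karr)
    out = log_coef + karr * math.log(p) + (n - karr) * math.log1p(-p)
    return float(out[0]) if scalar else out


def _logsumexp_sorted_desc(logs: np.ndarray) -> float:
    if logs.size == 0:
        return -np.inf
    mx = logs[0]
    if not np.isfinite(mx):
        return mx
    return mx + math.log(np.exp(logs - mx).sum())


def lower_tail(n: int, k: int, p: float) -> float:
    """P(X < k) = sum_{j=0}^{k-1} Pr(X = j), accumulated in log space.

    Strict inequality: k = 0 gives 0, k = n + 1 gives 1.
    """
    if not (0 <= k <= n + 1):
        raise ValueError(f"require 0 <= k <= n+1, got n={n}, k={k}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if k == 0:
        return 0.0
    if k == n + 1:
        return 1.0
    kmax = k - 1  # largest included term
    mode = p * n
    if kmax >= mode:
        # includes the mode: sum everything (mass near the mode dominates,
        # truncation saves nothing worth the complexity at the low side)
        logs = log_binomial_pmf(n, np.arange(0, k), p)
        logs = np.sort(logs)[::-1]
        return float(min(1.0, math.exp(_logsumexp_sorted_desc(logs))))
    # terms increase toward j = kmax; walk downward and stop when negligible
    total = _tail_logsum(n, p, start=kmax, step=-1, stop=-1)
    return float(min(1.0, math.exp(total)))


def upper_tail(n: int, k: int, p: float) -> float:
    """P(X >= k), computed directly when k is above the mean.

    The direct log-space sum keeps full relative precision for extreme
    significance levels, where 1 - P(X < k) would round to 0.
    """
    if not (0 <= k <= n + 1):
        raise ValueError(f"require 0 <= k <= n+1, got n={n}, k={k}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if k == 0:
        return 1.0
    if k == n + 1:
        return 0.0
    if k <= p * n:
        # lower tail is the small side; complement is well-conditioned here
        return float(max(0.0, 1.0 - lower_tail(n, k, p)))
    total = _tail_logsum(n, p, start=k, step=1, stop=n + 1)
    return float(min(1.0, math.exp(total)))


def _tail_logsum(n: int, p: float, start: int, step: int, stop: int) -> float:
    """log of sum of pmf terms from ``start`` moving by ``step`` while terms
    remain within _LOG_TERM_CUTOFF of the leading (largest) term."""
    if p == 0.0 or p == 1.0:
        target = 0 if p == 0.0 else n
        included = range(start, stop, step)
        return 0.0 if target in included else -np.inf
    chunk = 256
    lead = log_binomial_pmf(n, start, p)
    acc = [np.array([lead])]
    j = start + step
    while (step > 0 and j < stop) or (step < 0 and j > stop):
        if step > 0:
            js = np.arange(j, min(j + chunk, stop))
        else:
            js = np.arange(j, max(j - chunk, stop), -1)
        logs = log_binomial_pmf(n, js, p)
        keep = logs >= lead - _LOG_TERM_CUTOFF
        acc.append(logs[keep])
        if not keep.all():
            break
        j = int(js[-1]) + step
    logs = np.concatenate(acc)
    mx = logs.max()
    return float(mx + math.log(np.exp(logs - mx).sum()))


def bonferroni_level(alpha: float, m: int) -> float:
    """Per-test level alpha/m controlling the family-wise error rate."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha / m


def test_region(
    region_id: str,
    l: int,
    L: int,
    n: int,
    k: int,
    m: int,
    alpha: float = 0.05,
) -> RegionTestResult:
    """Test one region of length ``l`` against the uniform null over ``L``.

    Returns the full result record; ``candidate`` is True iff
    ``P(X >= k) < alpha / m``.
    """
    if not (0 < l <= L):
        raise ValueError(f"require 0 < l <= L, got l={l}, L={L}")
    if not (0 <= k <= n):
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    p = l / L
    if p == 1.0 and k != n:
        raise ValueError("l = L forces every mutation into the region (k must equal n)")
    p_up = upper_tail(n, k, p)
    threshold = bonferroni_level(alpha, m)
    return RegionTestResult(
        region_id=region_id,
        l=l,
        L=L,
        n=n,
        k=k,
        p=p,
        p_upper=p_up,
        m=m,
        alpha=alpha,
        candidate=bool(p_up < threshold),
    )
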