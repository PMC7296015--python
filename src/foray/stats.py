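"""Paired and correlation tests, Holm adjustment, AICc.

The signed-rank test here reports W as the sum of ranks of positive
differences (mid-ranks under ties, so W can be half-integer), with an
exact 2^n enumeration p-value for small tie-free samples and a
tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class PairedTestResult:
    statistic_W: float
    p_value: float
    n_pairs: int            # pairs remaining after zero differences dropped
    n_zeros_dropped: int
    method: str             # exact | normal_approx
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationTestResult:
    r: float
    t_statistic: float
    df: int
    p_value: float


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def wilcoxon_signed_rank(pairs, *, exact_max_n: int = 15) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on (a, b) pairs, differences a - b.

    Zero differences are dropped (their count is reported). With n <=
    ``exact_max_n`` tie-free differences the null distribution of W is
    enumerated exactly over all 2^n sign assignments; otherwise a normal
    approximation with tie correction is used.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (a, b) tuples")
    d = arr[:, 0] - arr[:, 1]
    zeros = d == 0
    n_zeros = int(zeros.sum())
    d = d[~zeros]
    n = len(d)
    if n == 0:
        return PairedTestResult(0.0, 1.0, 0, n_zeros, "exact", degenerate=True)
    if n < 2:
        # a single pair cannot reach two-sided significance; still well-defined
        ranks = _midranks(np.abs(d))
        w = float(ranks[d > 0].sum())
        return PairedTestResult(w, 1.0, n, n_zeros, "exact")

    absd = np.abs(d)
    ranks = _midranks(absd)
    w = float(ranks[d > 0].sum())
    has_ties = len(np.unique(absd)) < n

    if n <= exact_max_n and not has_ties:
        # exact two-sided p by full enumeration of sign assignments
        total = 0
        w_int = ranks.astype(int)  # tie-free integer ranks 1..n
        counts = np.zeros(int(n * (n + 1) / 2) + 1, dtype=np.int64)
        counts[0] = 1
        for r in w_int:
            counts[r:] = counts[r:] + counts[:-r if r else None]
        cdf = np.cumsum(counts)
        m = counts.sum()  # 2^n
        wi = int(round(w))
        p_le = cdf[wi] / m
        p_ge = (m - (cdf[wi - 1] if wi > 0 else 0)) / m
        p = min(1.0, 2 * min(p_le, p_ge))
        return PairedTestResult(w, float(p), n, n_zeros, "exact")

    mean = n * (n + 1) / 4
    tie_counts = np.unique(absd, return_counts=True)[1]
    tie_term = (tie_counts**3 - tie_counts).sum() / 48
    var = n * (n + 1) * (2 * n + 1) / 24 - tie_term
    if var <= 0:
        return PairedTestResult(w, 1.0, n, n_zeros, "normal_approx", degenerate=True)
    z = (w - mean) / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return PairedTestResult(w, float(min(1.0, p)), n, n_zeros, "normal_approx")


def wilcoxon_exact_bruteforce(pairs) -> float:
    """Independent oracle: two-sided exact p by explicit 2^n sign enumeration.

    Exponential-time reference for testing `wilcoxon_signed_rank`; only
    sensible for n <= ~15.
    """
    arr = np.asarray(pairs, dtype=float)
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    n = len(d)
    ranks = _midranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    le = ge = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        le += w <= w_obs + 1e-12
        ge += w >= w_obs - 1e-12
    m = 2**n
    return min(1.0, 2 * min(le / m, ge / m))


def pearson_test(x, y) -> CorrelationTestResult:
    """Pearson product-moment correlation with the t test (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = 2 * sps.t.sf(abs(t), df)
    return CorrelationTestResult(r=r, t_statistic=float(t), df=df, p_value=float(p))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a vector of p-values."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (n - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return np.inf
    aic = -2 * log_likelihood + 2 * k
    return aic + 2 * k * (k + 1) / (n - k - 1)
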