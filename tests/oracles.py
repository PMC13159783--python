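"""Independent brute-force reference implementations used only by tests.

These deliberately favour clarity over speed (explicit loops, O(n²)/O(n³))
and share no code with the package's estimators.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_brute(x, m: int = 2, r: float = 0.2) -> float:
    """O(n²) template-counting sample entropy (Richman–Moorman)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    tol = r * x.std()

    def count(length: int) -> int:
        c = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= tol:
                    c += 1
        return c

    B = count(m)
    A = count(m + 1)
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def visibility_brute(y, t) -> np.ndarray:
    """O(n³) all-pairs natural-visibility adjacency (strict inequality)."""
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    n = len(y)
    adj = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            visible = True
            for c in range(a + 1, b):
                bound = y[b] + (y[a] - y[b]) * (t[b] - t[c]) / (t[b] - t[a])
                if not y[c] < bound:
                    visible = False
                    break
            adj[a, b] = adj[b, a] = visible
    return adj


def time_domain_brute(rr) -> dict[str, float]:
    """Arithmetic-by-hand time-domain statistics (population variance)."""
    rr = [float(v) for v in rr]
    n = len(rr)
    mean = sum(rr) / n
    sdnn = math.sqrt(sum((v - mean) ** 2 for v in rr) / n)
    d = [b - a for a, b in zip(rr, rr[1:])]
    rmssd = math.sqrt(sum(v**2 for v in d) / len(d))
    dmean = sum(d) / len(d)
    sdsd = math.sqrt(sum((v - dmean) ** 2 for v in d) / len(d))
    return {
        "mean_nn": mean,
        "sdnn": sdnn,
        "rmssd": rmssd,
        "sdsd": sdsd,
        "pnn20": sum(1 for v in d if abs(v) > 20) / len(d),
        "pnn50": sum(1 for v in d if abs(v) > 50) / len(d),
    }


def ranksum_exact_p(x, y) -> float:
    """Two-sided exact rank-sum p-value by full enumeration."""
    from itertools import combinations

    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = rankdata(pooled)
    n1 = len(x)
    expected = n1 * (len(pooled) + 1) / 2.0
    observed = abs(ranks[: n1].sum() - expected)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - expected) >= observed - 1e-12:
            hits += 1
    return hits / total
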