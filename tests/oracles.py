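"""Brute-force statistical oracles, independent of the package's code paths."""

import math

import numpy as np


def poisson_upper_tail_oracle(k: int, mu: float) -> float:
    """P(X >= k | mu) by term-by-term pmf summation."""
    if k <= 0:
        return 1.0
    if k <= mu:
        lower = sum(math.exp(-mu) * mu**x / math.factorial(x) for x in range(k))
        return 1.0 - lower
    total, term = 0.0, math.exp(-mu) * mu**k / math.factorial(k)
    x = k
    while term > 1e-300 and x < k + 2000:
        total += term
        x += 1
        term *= mu / x
    return total


def bh_oracle(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p by the sorted-threshold scan."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        adj[i] = prev
    return adj


def holm_oracle(p) -> np.ndarray:
    """Holm step-down adjusted p by the sorted-threshold scan."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 0.0
    for rank, i in enumerate(order, start=1):
        running = max(running, min(1.0, p[i] * (n - rank + 1)))
        adj[i] = running
    return adj
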