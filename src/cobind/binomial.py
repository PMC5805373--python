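"""Log-space binomial upper-tail probabilities.

The enrichment tests report -log10 p at magnitudes far below the smallest
positive double (the interesting scale is 1e-300 .. 1e-1500), so the survival
function is evaluated entirely in log space via a log-sum-exp over the exact
log pmf terms.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["binom_log_sf", "binom_neg_log10_sf", "binom_sf"]


def _log_pmf(k: np.ndarray, n: int, p: float) -> np.ndarray:
    log_p = math.log(p)
    log_q = math.log1p(-p)
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * log_p
        + (n - k) * log_q
    )


def binom_log_sf(k: int, n: int, p: float) -> float:
    """Natural log of P(X >= k) for X ~ Binom(n, p), exact in log space.

    Returns 0.0 (p-value 1) for k <= 0 and -inf only when the tail is truly
    empty (k > n).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0,1], got {p}")
    if n < 0:
        raise ValueError("n must be non-negative")
    if k <= 0:
        return 0.0
    if k > n:
        return -math.inf
    if p == 0.0:
        return -math.inf
    if p == 1.0:
        return 0.0
    ks = np.arange(k, n + 1, dtype=float)
    return float(logsumexp(_log_pmf(ks, n, p)))


def binom_neg_log10_sf(k: int, n: int, p: float) -> float:
    """-log10 P(X >= k); 0.0 for an empty upper tail condition k <= 0."""
    log_sf = binom_log_sf(k, n, p)
    return -log_sf / math.log(10)


def binom_sf(k: int, n: int, p: float) -> float:
    """P(X >= k); underflows to 0.0 below ~1e-308 (use the log form for reporting)."""
    return math.exp(binom_log_sf(k, n, p))
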