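"""Log-space exact binomial tails shared by the mosaicism and cohort tests.

scipy's ``binom.logsf`` saturates to -inf once the linear survival function
underflows; summing ``logpmf`` terms with logsumexp keeps tails like
0.5^2000 representable.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import logsumexp


def log_binom_tail(x: int, n: int, p: float, tail: str) -> float:
    """Natural log of P(X >= x) (``upper``) or P(X <= x) (``lower``)."""
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    mean = n * p
    if tail == "upper":
        if x == 0:
            return 0.0
        ks, comp, small = np.arange(x, n + 1), np.arange(0, x), x >= mean
    elif tail == "lower":
        if x == n:
            return 0.0
        ks, comp, small = np.arange(0, x + 1), np.arange(x + 1, n + 1), x <= mean
    else:
        raise ValueError(f"unknown tail {tail!r}")
    with np.errstate(divide="ignore"):
        if small:
            # the requested tail is the small-probability side: sum it directly
            out = float(logsumexp(stats.binom.logpmf(ks, n, p)))
        else:
            # complement the opposite (small) side — no cancellation, since
            # its probability is bounded away from 1
            log_comp = float(logsumexp(stats.binom.logpmf(comp, n, p)))
            out = float(np.log(-np.expm1(min(log_comp, -1e-300))))
    return min(out, 0.0)  # guard accumulated rounding just above log(1)


def binom_tail(x: int, n: int, p: float, tail: str) -> float:
    return float(np.exp(log_binom_tail(x, n, p, tail)))
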