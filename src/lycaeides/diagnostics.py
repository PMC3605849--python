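"""MCMC convergence diagnostics and posterior summaries.

The potential scale reduction factor (PSRF) follows Gelman & Rubin: with m
chains of n draws each, W is the mean within-chain variance, B/n the variance
of the chain means, and

    PSRF = sqrt( ((n-1)/n * W + B/n) / W ).

Values near 1 indicate the chains are sampling the same distribution; the
conventional threshold used throughout this package is 1.1.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

__all__ = ["gelman_rubin", "summarize"]


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for a scalar parameter.

    Parameters
    ----------
    chains : array, shape (m_chains, n_iterations)
        Post-burn-in draws, one row per chain. Requires at least two chains
        of at least 10 draws each.

    Returns
    -------
    float
        PSRF; ``inf`` if the within-chain variance is zero while chains
        disagree, and ``sqrt((n-1)/n)`` (slightly below 1) for identical
        non-constant chains.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise InvalidInputError("PSRF requires >= 2 chains (2-D array).")
    m, n = chains.shape
    if n < 10:
        raise InvalidInputError("PSRF requires >= 10 iterations per chain.")
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    B = float(n * np.var(np.mean(chains, axis=1), ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else float("inf")
    v_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(v_hat / W))


def summarize(draws: np.ndarray, interval_mass: float = 0.95) -> tuple[float, float, float]:
    """Median and equal-tailed probability interval (ETPI) of posterior draws.

    Quantiles use linear interpolation between order statistics (type 7),
    numpy's default, fixed here for reproducibility.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise InvalidInputError("summarize: empty draw vector.")
    if not 0.0 < interval_mass < 1.0:
        raise InvalidInputError("interval_mass must lie in (0, 1).")
    tail = (1.0 - interval_mass) / 2.0
    lo, med, hi = np.quantile(draws, [tail, 0.5, 1.0 - tail])
    return float(med), float(lo), float(hi)
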