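"""Independent numerical oracles used only by the test suite."""

import numpy as np
from scipy import integrate, special, stats


def studentized_range_sf(q: float, k: int, df: int) -> float:
    """P(Q > q) for the studentized range, by direct double quadrature.

    Integrates the classical CDF representation over the range statistic
    (inner normal integral) and the independent scaled-chi variance factor
    (outer integral). Independent of scipy.stats.studentized_range.
    """
    if q <= 0:
        return 1.0

    def inner(s):
        def f(z):
            return stats.norm.pdf(z) * (stats.norm.cdf(z) - stats.norm.cdf(z - q * s)) ** (k - 1)

        val, _ = integrate.quad(f, -np.inf, np.inf)
        return k * val

    def outer(s):
        logc = (df / 2) * np.log(df) - special.gammaln(df / 2) - (df / 2 - 1) * np.log(2)
        dens = np.exp(logc + (df - 1) * np.log(s) - df * s * s / 2)
        return dens * inner(s)

    cdf, _ = integrate.quad(outer, 0, np.inf, limit=200)
    return 1.0 - cdf


def g_via_loglik(table: np.ndarray) -> float:
    """G as twice the saturated-minus-independence multinomial log-likelihood."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    p_sat = table / n
    p_ind = np.outer(table.sum(axis=1), table.sum(axis=0)) / n**2
    mask = table > 0
    ll_sat = (table[mask] * np.log(p_sat[mask])).sum()
    ll_ind = (table[mask] * np.log(p_ind[mask])).sum()
    return 2.0 * (ll_sat - ll_ind)


def hypergeom_tail(a: int, n: int, K: int, N: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N, K, n), by direct pmf summation."""
    return float(sum(stats.hypergeom.pmf(i, N, K, n) for i in range(a, min(n, K) + 1)))
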