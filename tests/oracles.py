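"""Independent brute-force oracles the tests compare the library against.

Everything here is deliberately naive — plain accumulation loops, textbook
formulas, normal-equation solves — and shares no code path with the
implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def brute_force_centroid(mz, intensity):
    """Plain accumulation of sum(mz*I)/sum(I)."""
    num = 0.0
    den = 0.0
    for m, i in zip(mz, intensity):
        num += m * i
        den += i
    return num / den


def textbook_paired_t(d, alpha=0.05):
    """Paired t-test from the textbook formulas: returns
    (mean, t, df, p, ci_low, ci_high)."""
    d = np.asarray(d, float)
    n = len(d)
    mean = sum(d) / n
    var = sum((x - mean) ** 2 for x in d) / (n - 1)
    se = (var / n) ** 0.5
    t = mean / se
    df = n - 1
    p = 2 * stats.t.sf(abs(t), df)
    crit = stats.t.ppf(1 - alpha / 2, df)
    return mean, t, df, p, mean - crit * se, mean + crit * se


def normal_equations_ols(X, y):
    """OLS by explicitly solving (X'X) b = X'y; returns (beta, cov, sigma2,
    df_resid)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(xtx)
    return beta, cov, sigma2, df


def brute_force_envelope_centroid(base_mz, charge, n_exchangeable, d_fraction,
                                  natural_profile, c13_spacing, dh_spacing):
    """Centroid of the natural x binomial convolution by full enumeration."""
    num = 0.0
    den = 0.0
    for k, nat in enumerate(natural_profile):
        for j in range(n_exchangeable + 1):
            w = nat * stats.binom.pmf(j, n_exchangeable, d_fraction)
            m = base_mz + (k * c13_spacing + j * dh_spacing) / charge
            num += w * m
            den += w
    return num / den
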