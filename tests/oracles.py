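"""Independent reference computations used to check the implementation.

These deliberately take different routes than the package code: simple
regression parametrizations, brute-force grids, and exhaustive
enumeration.
"""

from itertools import combinations

import numpy as np
from scipy import stats as sps
from scipy.special import ndtr


def ols_mixture_reference(y, c):
    """(mu_gm, mu_wm, sigma) via the slope/intercept parametrization.

    y = mu_wm + (mu_gm - mu_wm) * c, fit as a straight line in c.
    """
    y = np.asarray(y, float)
    c = np.asarray(c, float)
    slope, intercept = np.polyfit(c, y, 1)
    resid = y - (intercept + slope * c)
    sigma = np.sqrt(np.mean(resid ** 2))
    return intercept + slope, intercept, sigma


def grid_search_nll(y, sigma, lo=600.0, hi=1800.0, step=1.0):
    """Brute-force minimum of the marginal NLL over the (mu_gm, mu_wm) grid.

    Sigma is held fixed; every ordered pair on the 1-ms grid is evaluated.
    Returns (min_nll, (mu_gm, mu_wm)).
    """
    y = np.asarray(y, float)
    vals = np.arange(lo, hi + step / 2, step)
    n = y.size
    cdf_table = ndtr((y[None, :] - vals[:, None]) / sigma)  # Phi((y - v)/sigma)
    best = np.inf
    arg = None
    for k in range(1, len(vals)):
        z = np.maximum(cdf_table[:k] - cdf_table[k][None, :], 1e-300)
        nll = n * np.log(vals[k] - vals[:k]) - np.log(z).sum(axis=1)
        j = int(nll.argmin())
        if nll[j] < best:
            best = float(nll[j])
            arg = (float(vals[k]), float(vals[j]))
    return best, arg


def exhaustive_permutation_pvalue(values, n_first):
    """Exact two-tailed permutation p of the pooled t over all group splits."""
    values = np.asarray(values, float)
    n = values.size
    idx = np.arange(n)
    obs = abs(sps.ttest_ind(values[:n_first], values[n_first:],
                            equal_var=True).statistic)
    count = 0
    total = 0
    for subset in combinations(idx, n_first):
        sel = np.zeros(n, bool)
        sel[list(subset)] = True
        t = sps.ttest_ind(values[sel], values[~sel], equal_var=True).statistic
        count += abs(t) >= obs - 1e-12
        total += 1
    return count / total
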