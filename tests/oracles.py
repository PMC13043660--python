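"""Independent reference implementations used to validate the package.

These deliberately share no code with the implementation: exact rational
enumeration for the Hardy-Weinberg test, statsmodels OLS for the
per-variant regression, a generalized-eigenvalue solution of the
canonical-correlation problem, and a plain re-statement of the greedy
clumping rule over a precomputed correlation matrix.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided HWE p by full enumeration in rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    n_alt = 2 * n_aa + n_Aa
    n_minor = min(n_alt, 2 * n - n_alt)
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        weights[h] = Fraction(comb(n, hom_minor) * comb(n - hom_minor, h)
                              * 2 ** h)
    total = sum(weights.values())
    w_obs = weights[n_Aa]
    return float(sum(w for w in weights.values() if w <= w_obs) / total)


def ols_oracle(x: np.ndarray, y: np.ndarray):
    """Simple-regression beta/se/p via statsmodels."""
    import statsmodels.api as sm

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return fit.params[1], fit.bse[1], fit.pvalues[1]


def cca_rho2_oracle(g: np.ndarray, Y: np.ndarray) -> float:
    """Squared canonical correlation of a vector vs a matrix via the
    generalized-eigenvalue formulation rho^2 = Sxy Syy^-1 Syx / Sxx."""
    gc = g - g.mean()
    Yc = Y - Y.mean(axis=0)
    Sxx = float(gc @ gc)
    Sxy = gc @ Yc
    Syy = Yc.T @ Yc
    return float(Sxy @ np.linalg.solve(Syy, Sxy)) / Sxx


def clump_oracle(ids, chroms, positions, pvals, dosages, p1, p2, r2_min,
                 window_bp):
    """Reference greedy clumping over a precomputed full r^2 matrix.

    Returns the sorted list of index variant ids.
    """
    m = len(ids)
    r2 = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            si, sj = dosages[:, i].std(), dosages[:, j].std()
            if si == 0 or sj == 0:
                r2[i, j] = 0.0
            else:
                r2[i, j] = np.corrcoef(dosages[:, i], dosages[:, j])[0, 1] ** 2
    order = sorted(range(m), key=lambda i: (pvals[i], chroms[i], positions[i],
                                            ids[i]))
    assigned = set()
    indices = []
    for i in order:
        if pvals[i] >= p1 or i in assigned:
            continue
        indices.append(i)
        assigned.add(i)
        for j in order:
            if j in assigned or pvals[j] >= p2:
                continue
            if (chroms[j] == chroms[i]
                    and abs(positions[j] - positions[i]) <= window_bp
                    and r2[i, j] > r2_min):
                assigned.add(j)
    return sorted(ids[i] for i in indices)
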