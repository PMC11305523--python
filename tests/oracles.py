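"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the code paths they validate: partial correlation
via the recursive formula (not residuals), model selection via exhaustive
subset enumeration (not a stepwise path), chi-squared via an explicit
O/E loop (not scipy), and OLS via the normal equations.
"""

import itertools
import math

import numpy as np
from scipy import stats as sps


def pearson_r(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.corrcoef(x, y)[0, 1])


def partial_corr_recursive(data, x, y, controls):
    """First-order recursion: remove one control at a time."""
    if not controls:
        return pearson_r(data[x], data[y])
    z, rest = controls[0], list(controls[1:])
    rxy = partial_corr_recursive(data, x, y, rest)
    rxz = partial_corr_recursive(data, x, z, rest)
    ryz = partial_corr_recursive(data, y, z, rest)
    return (rxy - rxz * ryz) / math.sqrt((1.0 - rxz**2) * (1.0 - ryz**2))


def ols_normal_equations(X, y):
    """Betas, standard errors and two-sided p-values via (X'X)^-1 X'y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return beta, se, p


def chi2_loop(counts):
    """Pearson chi-squared via an explicit sum of (O - E)^2 / E."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    chi2 = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            expected = rows[i] * cols[j] / total
            chi2 += (counts[i, j] - expected) ** 2 / expected
    return chi2


def coefficient_p(data, response, predictors, target):
    """Two-sided p of one coefficient, via the normal equations."""
    X = np.column_stack(
        [np.ones(len(data))] + [np.asarray(data[v], dtype=float) for v in predictors]
    )
    _, _, p = ols_normal_equations(X, np.asarray(data[response], dtype=float))
    return float(p[1 + predictors.index(target)])


def stable_subsets(data, response, candidates, p_enter=0.05, p_remove=0.10):
    """All subsets no stepwise move can change, by exhaustive enumeration.

    A subset is stable when every included variable survives the removal
    test (partial-F p < p_remove) and no excluded candidate qualifies for
    entry (partial-F p <= p_enter).
    """
    stable = []
    for k in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, k):
            subset = list(subset)
            if any(
                coefficient_p(data, response, subset, v) >= p_remove for v in subset
            ):
                continue
            excluded = [v for v in candidates if v not in subset]
            if any(
                coefficient_p(data, response, subset + [v], v) <= p_enter
                for v in excluded
            ):
                continue
            stable.append(tuple(sorted(subset)))
    return stable


def prevalence_by_sampling(arch, freq, n_draws, seed):
    """Monte-Carlo obesity prevalence from genotype + noise draws."""
    rng = np.random.default_rng(seed)
    slots = arch.ploidy_factor * arch.n_loci
    counts = rng.binomial(slots, freq, size=n_draws)
    phenotypes = (
        arch.baseline_bmi
        + arch.effect_per_allele * (counts - slots * arch.reference_freq)
        + rng.normal(0.0, arch.env_sd, size=n_draws)
    )
    obese = phenotypes > arch.obesity_threshold
    prevalence = obese.mean()
    se = math.sqrt(max(prevalence * (1 - prevalence), 1e-12) / n_draws)
    return float(prevalence), se
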