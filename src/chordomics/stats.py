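"""Shared statistical helpers: t tests with degenerate-input conventions,
Benjamini-Hochberg adjustment, and the Grubbs outlier critical value.

Degenerate inputs (zero variance) are mapped to deterministic results rather
than NaN: identical groups give p = 1, while a perfectly consistent non-zero
difference is treated as the significant limit (p = smallest positive float).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: p-value reported for the zero-variance, non-zero-effect limit.
P_LIMIT = float(np.finfo(float).tiny)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def student_t_unpaired(x, y) -> tuple[float, float]:
    """Two-sided equal-variance (Student) two-sample t test.

    Conventions: if both groups have zero variance, p = 1 for equal means and
    the significant limit otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    pooled_var = (
        ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
        / (x.size + y.size - 2)
    )
    if pooled_var == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), P_LIMIT
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def student_t_paired(x, y) -> tuple[float, float]:
    """Two-sided paired Student t test on matched pairs.

    Conventions for zero-variance differences: all differences zero -> p = 1;
    all differences equal and non-zero -> the significant limit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    if d.var(ddof=1) == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), P_LIMIT
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs test critical value for sample size ``n``.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t-quantile(1 - alpha/(2n), n - 2 df).
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def geometric_mean(x, axis=None):
    """Geometric mean of strictly positive values."""
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return np.exp(np.mean(np.log(x), axis=axis))


def geometric_sd(x, axis=None, ddof: int = 1):
    """Geometric standard deviation, exp(sd(log x))."""
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("geometric sd requires strictly positive values")
    return np.exp(np.std(np.log(x), axis=axis, ddof=ddof))
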