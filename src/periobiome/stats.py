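"""Shared statistical primitives.

The same pooled-variance two-sample t-test backs the content comparisons,
the per-taxon differential-abundance tests and the host-assay group tests;
the same Benjamini-Hochberg step-up backs every FDR family in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

#: significance tiers used on the heatmaps: *** q<0.1, ** q<0.2, * q<0.3
DEFAULT_TIER_CUTOFFS: tuple[float, float, float] = (0.1, 0.2, 0.3)


@dataclass(frozen=True)
class TTestResult:
    """Pooled-variance two-sample t-test outcome.

    ``degenerate`` is set when the pooled variance is zero, in which case
    the two-sided p-value is 1 if the group means agree and 0 otherwise
    (the t statistic is reported as 0 or +/-inf accordingly).
    """

    t: float
    df: int
    p: float
    degenerate: bool = False


def pooled_t_test(a, b) -> TTestResult:
    """Two-sided two-sample t-test assuming equal variance.

    Parameters
    ----------
    a, b : array-like
        Group observations; each must contain at least two values.

    Returns
    -------
    TTestResult
        ``df = len(a) + len(b) - 2``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    df = a.size + b.size - 2
    # pooled variance; zero-variance groups need an explicit policy because
    # the t statistic is 0/0 there
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0, degenerate=True)
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return TTestResult(t=sign * np.inf, df=df, p=0.0, degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(t), df=df, p=float(p), degenerate=False)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j>=i} (p_(j) * m / j), capped at 1, where p_(1) <= ... <=
    p_(m) are the sorted p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def tier_for(q: float, cutoffs=DEFAULT_TIER_CUTOFFS) -> str:
    """Map a q-value to its significance tier string.

    With the default cutoffs: ``"***"`` for q < 0.1, ``"**"`` for q < 0.2,
    ``"*"`` for q < 0.3, and ``""`` (not significant) otherwise.
    """
    c1, c2, c3 = cutoffs
    if not (0 < c1 < c2 < c3):
        raise ConfigError(f"tier cutoffs must be strictly increasing: {cutoffs}")
    if q < c1:
        return "***"
    if q < c2:
        return "**"
    if q < c3:
        return "*"
    return ""
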