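"""Non-sequencing host-assay statistics.

Covers the bench-side readouts of the mouse infection model: qPCR
pathogen load as a percentage of total 16S copies and per-pathogen
detection frequency, comparative-CT (2^-ddCT) relative gene expression,
alveolar bone loss averaged over the 28 standard measurement sites,
Pearson chi-square on intrabony-defect proportions over the 72 scored
tooth surfaces per group, one-way ANOVA with Tukey's HSD, and the shared
pooled-variance Student t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import TTestResult, pooled_t_test

#: bone-loss measurement sites per mouse: (3 + 2 + 2) molar sites x 2 sides x 2 jaws
BONE_LOSS_SITES = 28

#: scored tooth surfaces per group: 6 mice x 36 molars x 2 sides
SURFACES_PER_GROUP = 72


def pathogen_percentage(pathogen_copies: float, total_copies: float) -> float:
    """Pathogen copy number as a percentage of total-bacteria copies."""
    if total_copies <= 0:
        raise ValueError("total-bacteria copy number must be positive")
    if pathogen_copies < 0 or pathogen_copies > total_copies:
        raise ValueError("pathogen copies must lie in [0, total]")
    return 100.0 * pathogen_copies / total_copies


def detection_frequency(flags) -> tuple[int, int, float]:
    """Count of positive detections and percent of collected samples.

    Returns ``(n_detected, percent_display, percent_exact)`` where the
    display percent is rounded to the nearest integer (ties away from
    zero) and the exact value is retained.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("need at least one sample")
    count = int(flags.sum())
    exact = 100.0 * count / flags.size
    display = int(math.floor(exact + 0.5))
    return count, display, exact


def ddct_fold_change(records: pd.DataFrame, reference_group: str) -> pd.DataFrame:
    """Per-sample relative expression by the comparative-CT (2^-ddCT) method.

    dCT = CT_target - CT_GAPDH per sample; ddCT = dCT - mean(dCT of the
    reference group); fold = 2^-ddCT.  Fold is 1 on average (geometric
    mean) within the reference group by construction.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``sample_id``, ``group``, ``target_ct``, ``gapdh_ct``
        (an optional ``gene`` column is carried through).
    """
    required = {"sample_id", "group", "target_ct", "gapdh_ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"ddCT records missing column(s): {sorted(missing)}")
    if records["gapdh_ct"].isna().any():
        bad = records.loc[records["gapdh_ct"].isna(), "sample_id"].tolist()
        raise ValueError(f"missing housekeeping (GAPDH) CT for sample(s): {bad}")
    if reference_group not in set(records["group"]):
        raise ValueError(f"reference group '{reference_group}' absent from records")
    out = records.copy()
    out["dct"] = out["target_ct"] - out["gapdh_ct"]
    ref_mean = out.loc[out["group"] == reference_group, "dct"].mean()
    out["ddct"] = out["dct"] - ref_mean
    out["fold"] = 2.0 ** (-out["ddct"])
    return out


def bone_loss_mean(sites) -> float:
    """Mean alveolar bone loss (mm) over the 28 standard sites of one mouse."""
    sites = np.asarray(sites, dtype=float)
    if sites.size != BONE_LOSS_SITES:
        raise ValueError(f"expected {BONE_LOSS_SITES} sites, got {sites.size}")
    if np.any(sites < 0):
        raise ValueError("bone-loss measurements must be nonnegative")
    return float(sites.mean())


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


def defect_chi_square(
    defects_a: int, total_a: int, defects_b: int, total_b: int, correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 defect-by-group contingency table.

    No Yates continuity correction by default.  A zero margin (no defects
    in either group, or all surfaces defective) leaves the statistic
    undefined and raises ``ValueError``.
    """
    for d, t in ((defects_a, total_a), (defects_b, total_b)):
        if not 0 <= d <= t:
            raise ValueError("defect count must lie in [0, total]")
    table = np.array(
        [[defects_a, total_a - defects_a], [defects_b, total_b - defects_b]], dtype=float
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a margin of the 2x2 table is zero")
    res = sps.chi2_contingency(table, correction=correction)
    return ChiSquareResult(chi2=float(res.statistic), df=1, p=float(res.pvalue))


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA F-test plus all-pairs Tukey HSD.

    ``pairwise`` has one row per group pair with the mean difference and
    the studentized-range-adjusted p-value.  ``degenerate`` marks zero
    within-group variance everywhere (F undefined).
    """

    F: float
    df_between: int
    df_within: int
    p: float
    pairwise: pd.DataFrame
    degenerate: bool = False


def anova_tukey(groups, labels=None) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey's HSD post-hoc test.

    Parameters
    ----------
    groups : sequence of array-like
        At least two groups with >= 2 values each.
    labels : sequence of str, optional
        Group names for the pairwise table (default g1, g2, ...).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(arrays))]
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    within = sum((a.size - 1) * a.var(ddof=1) for a in arrays)
    if within == 0:
        pairs = [
            {"group_a": labels[i], "group_b": labels[j],
             "diff": arrays[i].mean() - arrays[j].mean(), "p_adj": np.nan}
            for i in range(k) for j in range(i + 1, k)
        ]
        return AnovaTukeyResult(
            F=np.nan, df_between=k - 1, df_within=n_total - k, p=np.nan,
            pairwise=pd.DataFrame(pairs), degenerate=True,
        )
    F, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            pairs.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "diff": arrays[i].mean() - arrays[j].mean(),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return AnovaTukeyResult(
        F=float(F), df_between=k - 1, df_within=n_total - k, p=float(p),
        pairwise=pd.DataFrame(pairs),
    )


def two_group_t(group_a, group_b) -> TTestResult:
    """Student's t-test for two independent groups (pooled variance)."""
    return pooled_t_test(group_a, group_b)
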