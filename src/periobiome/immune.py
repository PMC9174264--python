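"""Correlation of differentially abundant taxa with immune-marker levels.

Taxa significant in at least one differential-abundance comparison (any
tier) are correlated, across all retained animals, with cytokine /
chemokine expression levels.  Both sides enter in log space — the marker
values get the same log10(x + 0.1) transform as the abundances — and
Pearson's r with a t-based p-value (df = n - 2) is corrected per marker
across taxa with Benjamini-Hochberg, coded in the same significance
tiers as the abundance heatmaps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .da import DEFAULT_PSEUDOCOUNT, LogAbundanceTable
from .stats import DEFAULT_TIER_CUTOFFS, bh_fdr, tier_for

#: the immune markers profiled in the gingival tissues
DEFAULT_MARKERS = ("IL-1b", "IL-6", "TNF-a", "IFN-g", "CCL2", "CXCL2", "TGF-b1")


def select_significant_taxa(da_results: pd.DataFrame) -> set[str]:
    """Taxa with a non-empty significance tier in at least one comparison."""
    if len(da_results) == 0:
        return set()
    hit = da_results["tier"].astype(str) != ""
    return set(da_results.loc[hit, "taxon"])


def correlate_with_markers(
    table: LogAbundanceTable,
    markers: pd.DataFrame,
    taxa=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    tier_cutoffs=DEFAULT_TIER_CUTOFFS,
) -> pd.DataFrame:
    """Pearson correlation of taxa log abundances with log marker levels.

    Parameters
    ----------
    table : LogAbundanceTable
        Already log10(RPM + pseudocount)-transformed abundances.
    markers : pandas.DataFrame
        Samples x markers raw (nonnegative) expression values, indexed by
        sample id; transformed here as log10(value + pseudocount).  Samples
        missing from either side are dropped pairwise, with n reported.
    taxa : iterable of str, optional
        Taxa to test (default: every taxon in the table).

    Returns
    -------
    pandas.DataFrame
        One row per (taxon, marker): ``n``, ``r``, ``t``, ``p``, ``q``
        (BH within each marker across taxa), ``tier``, ``undefined``
        (constant vector — excluded from the BH family).
    """
    if taxa is None:
        taxa = list(table.taxa.index)
    else:
        taxa = [t for t in taxa if t in table.taxa.index]
    log_markers = np.log10(markers + pseudocount)
    shared = [s for s in table.data.columns if s in log_markers.index]
    rows = []
    for marker in log_markers.columns:
        m_all = log_markers[marker].reindex(shared)
        for taxon in taxa:
            y_all = table.data.loc[taxon, shared]
            ok = ~(m_all.isna() | y_all.isna())
            y = y_all[ok].to_numpy()
            m = m_all[ok].to_numpy()
            n = y.size
            if n < 3 or np.ptp(y) == 0 or np.ptp(m) == 0:
                rows.append(
                    {"taxon": taxon, "marker": marker, "n": n, "r": np.nan,
                     "t": np.nan, "p": np.nan, "undefined": True}
                )
                continue
            r, p = sps.pearsonr(y, m)
            with np.errstate(divide="ignore"):
                t = r * np.sqrt((n - 2) / max(1.0 - r * r, 0.0)) if abs(r) < 1 else np.inf * np.sign(r)
            rows.append(
                {"taxon": taxon, "marker": marker, "n": n, "r": float(r),
                 "t": float(t), "p": float(p), "undefined": False}
            )
    out = pd.DataFrame(rows)
    if len(out) == 0:
        return out.assign(q=[], tier=[])
    out["q"] = np.nan
    out["tier"] = ""
    for marker in out["marker"].unique():
        mask = (out["marker"] == marker) & (~out["undefined"])
        if mask.any():
            q = bh_fdr(out.loc[mask, "p"].to_numpy())
            out.loc[mask, "q"] = q
            out.loc[mask, "tier"] = [tier_for(v, tier_cutoffs) for v in q]
    return out


def correlation_matrix(results: pd.DataFrame, value: str = "r") -> pd.DataFrame:
    """Pivot long-format correlation results into a taxa x marker matrix."""
    return results.pivot(index="taxon", columns="marker", values=value)
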