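"""Tiered-FDR differential abundance on log10(RPM + 0.1).

For each non-reference group and each taxon, the analysis computes the
mean log10 difference against the reference group (Control or Infection),
its pooled-variance two-sided t-test, and a Benjamini-Hochberg q-value
whose family is all taxa of one taxonomic level within one comparison.
Significance is coded in tiers: *** q < 0.1, ** q < 0.2, * q < 0.3.
Fold change is 10^(mean log difference), i.e. the ratio of geometric
means of (RPM + pseudocount).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .stats import DEFAULT_TIER_CUTOFFS, TTestResult, bh_fdr, pooled_t_test, tier_for
from .tables import AbundanceTable

#: pseudocount added before log10, in RPM units
DEFAULT_PSEUDOCOUNT = 0.1


@dataclass
class LogAbundanceTable:
    """y = log10(RPM + pseudocount) with the abundance table's indexing."""

    data: pd.DataFrame
    taxa: pd.DataFrame
    samples: pd.DataFrame
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    provenance: list = field(default_factory=list)

    @property
    def floor(self) -> float:
        """Lowest attainable value, log10(pseudocount) (= -1 by default)."""
        return float(np.log10(self.pseudocount))


def log_transform(table: AbundanceTable, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> LogAbundanceTable:
    """Elementwise y = log10(x + pseudocount) of an RPM table."""
    if pseudocount <= 0:
        raise ConfigError(f"pseudocount must be positive, got {pseudocount}")
    return LogAbundanceTable(
        data=np.log10(table.data + pseudocount),
        taxa=table.taxa.copy(),
        samples=table.samples.copy(),
        pseudocount=pseudocount,
        provenance=table.provenance + [{"step": "log_transform", "pseudocount": pseudocount}],
    )


def taxon_t_test(y_group, y_ref) -> TTestResult:
    """Pooled-variance two-sided t-test of one taxon's log abundances."""
    return pooled_t_test(y_group, y_ref)


def differential_abundance(
    table: LogAbundanceTable,
    reference_group: str,
    groups=None,
    levels=("genus", "species"),
    tier_cutoffs=DEFAULT_TIER_CUTOFFS,
) -> pd.DataFrame:
    """Per-taxon comparisons of every group against a reference group.

    Parameters
    ----------
    table : LogAbundanceTable
        log10(RPM + pseudocount) values with group metadata.
    reference_group : str
        Group every other group is compared against; must have >= 2 samples.
    groups : iterable of str, optional
        Comparison groups (default: all non-reference groups present).
    levels : iterable of str
        Taxonomic levels analysed; BH correction is applied separately
        within each (comparison, level) family across its taxa.

    Returns
    -------
    pandas.DataFrame
        Long format, one row per (comparison, taxon): ``comparison``,
        ``level``, ``taxon``, ``delta_log10`` (group mean minus reference
        mean), ``fold`` (10^delta), ``t``, ``df``, ``p``, ``q``, ``tier``,
        ``degenerate``.
    """
    if "group" not in table.samples.columns:
        raise ConfigError("sample metadata lacks a 'group' column")
    grp = table.samples["group"]
    if reference_group not in set(grp):
        raise ConfigError(f"reference group '{reference_group}' not in metadata")
    ref_ids = grp.index[grp == reference_group]
    if len(ref_ids) < 2:
        raise ConfigError(f"reference group '{reference_group}' has fewer than 2 samples")
    if groups is None:
        groups = [g for g in pd.unique(grp) if g != reference_group]
    rows = []
    for level in levels:
        taxa = table.taxa.index[table.taxa["level"] == level]
        if len(taxa) == 0:
            continue
        ref_mat = table.data.loc[taxa, ref_ids]
        for g in groups:
            g_ids = grp.index[grp == g]
            if len(g_ids) < 2:
                raise ConfigError(f"group '{g}' has fewer than 2 samples")
            g_mat = table.data.loc[taxa, g_ids]
            block = []
            for taxon in taxa:
                res = pooled_t_test(g_mat.loc[taxon], ref_mat.loc[taxon])
                delta = float(g_mat.loc[taxon].mean() - ref_mat.loc[taxon].mean())
                block.append(
                    {
                        "comparison": f"{g} vs {reference_group}",
                        "level": level,
                        "taxon": taxon,
                        "delta_log10": delta,
                        "fold": 10.0**delta,
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                        "degenerate": res.degenerate,
                    }
                )
            block = pd.DataFrame(block)
            block["q"] = bh_fdr(block["p"].to_numpy())
            block["tier"] = [tier_for(q, tier_cutoffs) for q in block["q"]]
            rows.append(block)
    if not rows:
        return pd.DataFrame(
            columns=[
                "comparison", "level", "taxon", "delta_log10", "fold",
                "t", "df", "p", "degenerate", "q", "tier",
            ]
        )
    return pd.concat(rows, ignore_index=True)


def fold_change_matrix(da_results: pd.DataFrame, level: str, value: str = "fold") -> pd.DataFrame:
    """Pivot long-format results into a taxa x comparison heatmap matrix."""
    sub = da_results[da_results["level"] == level]
    return sub.pivot(index="taxon", columns="comparison", values=value)
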