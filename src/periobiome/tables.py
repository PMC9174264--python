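"""Taxa-table containers, I/O, RPM normalization, filtering and exclusion.

Tables are taxa-by-sample matrices carried in :class:`pandas.DataFrame`
objects together with per-taxon annotations (``name``, ``level`` in
{genus, species}, ``kingdom`` in {bacteria, virus}, optionally ``genus``)
and per-sample metadata (group, mouse id, raw total reads).

The normalization contract is the standard shotgun-metagenomics one:
each sample column is rescaled to one million reads (reads per million,
RPM), taxa whose mean RPM across retained samples falls below a threshold
(default 1 RPM) are dropped, and low-coverage samples can be excluded
either by id or by a minimum raw-read threshold.  RPM values are computed
once and never renormalized after filtering, so each sample keeps its
original per-million basis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableFormatError

LEVELS = ("genus", "species")
KINGDOMS = ("bacteria", "virus")

#: taxon-annotation columns recognized in table files (in written order)
ANNOTATION_COLUMNS = ("name", "level", "kingdom", "genus")

_FLOAT_FMT = "%.6g"  # serialized precision for abundance values


def _name_axes(data: pd.DataFrame, taxa: pd.DataFrame, samples: pd.DataFrame) -> None:
    data.index.name = "taxon_id"
    data.columns.name = None
    taxa.index.name = "taxon_id"
    samples.index.name = "sample_id"


def _check_ids(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate {what} id(s): {dups}")


def _check_taxa(taxa: pd.DataFrame) -> None:
    for col in ("name", "level", "kingdom"):
        if col not in taxa.columns:
            raise TableFormatError(f"missing taxon annotation column '{col}'")
        if taxa[col].isna().any():
            bad = taxa.index[taxa[col].isna()].tolist()
            raise TableFormatError(f"missing '{col}' annotation for taxa {bad}")
    bad_level = taxa.index[~taxa["level"].isin(LEVELS)].tolist()
    if bad_level:
        raise TableFormatError(f"level must be one of {LEVELS}; bad taxa: {bad_level}")
    bad_kingdom = taxa.index[~taxa["kingdom"].isin(KINGDOMS)].tolist()
    if bad_kingdom:
        raise TableFormatError(
            f"kingdom must be one of {KINGDOMS}; bad taxa: {bad_kingdom}"
        )


@dataclass
class CountTable:
    """Taxa x samples integer read counts with annotations and metadata.

    Attributes
    ----------
    data : pandas.DataFrame
        Nonnegative integer counts, index = taxon ids, columns = sample ids.
    taxa : pandas.DataFrame
        Per-taxon annotations, index aligned with ``data.index``; must
        contain ``name``, ``level`` and ``kingdom`` columns.
    samples : pandas.DataFrame
        Per-sample metadata, index aligned with ``data.columns``; carries
        ``group``, ``mouse_id`` and ``total_reads`` when available.
    """

    data: pd.DataFrame
    taxa: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _check_ids(self.data.index, "taxon")
        _check_ids(self.data.columns, "sample")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise TableFormatError("counts must be numeric")
        if np.any(vals < 0):
            raise TableFormatError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise TableFormatError("counts must be integers")
        self.data = self.data.astype(np.int64)
        self.taxa = self.taxa.reindex(self.data.index)
        _check_taxa(self.taxa)
        self.samples = self.samples.reindex(self.data.columns)
        _name_axes(self.data, self.taxa, self.samples)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def totals(self) -> pd.Series:
        """Per-sample total read counts (column sums)."""
        return self.data.sum(axis=0)

    def to_tsv(self, path) -> None:
        """Write the table with annotation columns followed by samples."""
        _write_table(self.data, self.taxa, path, float_fmt=None)


@dataclass
class AbundanceTable:
    """RPM-normalized taxa x samples table with filter provenance.

    ``provenance`` is an append-only list of records describing the
    normalization basis and every filter/exclusion applied, so a result
    table documents how it was derived.
    """

    data: pd.DataFrame
    taxa: pd.DataFrame
    samples: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_ids(self.data.index, "taxon")
        _check_ids(self.data.columns, "sample")
        if np.any(self.data.to_numpy() < 0):
            raise TableFormatError("abundances must be nonnegative")
        self.data = self.data.astype(float)
        self.taxa = self.taxa.reindex(self.data.index)
        _check_taxa(self.taxa)
        self.samples = self.samples.reindex(self.data.columns)
        _name_axes(self.data, self.taxa, self.samples)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def subset_kingdom(self, kingdom: str) -> "AbundanceTable":
        if kingdom not in KINGDOMS:
            raise ValueError(f"kingdom must be one of {KINGDOMS}")
        keep = self.taxa.index[self.taxa["kingdom"] == kingdom]
        return AbundanceTable(
            data=self.data.loc[keep].copy(),
            taxa=self.taxa.loc[keep].copy(),
            samples=self.samples.copy(),
            provenance=self.provenance + [{"step": "subset_kingdom", "kingdom": kingdom}],
        )

    def subset_level(self, level: str) -> "AbundanceTable":
        if level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}")
        keep = self.taxa.index[self.taxa["level"] == level]
        return AbundanceTable(
            data=self.data.loc[keep].copy(),
            taxa=self.taxa.loc[keep].copy(),
            samples=self.samples.copy(),
            provenance=self.provenance + [{"step": "subset_level", "level": level}],
        )

    def to_tsv(self, path, write_provenance: bool = True) -> None:
        """Write values at 6 significant digits plus a provenance sidecar."""
        _write_table(self.data, self.taxa, path, float_fmt=_FLOAT_FMT)
        if write_provenance:
            side = Path(str(path) + ".provenance.json")
            side.write_text(json.dumps(self.provenance, indent=2, default=str) + "\n")


def _write_table(data: pd.DataFrame, taxa: pd.DataFrame, path, float_fmt) -> None:
    out = pd.concat(
        [taxa[[c for c in ANNOTATION_COLUMNS if c in taxa.columns]], data], axis=1
    )
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t", float_format=float_fmt)


def _read_table(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    # check the raw header first: pandas silently renames duplicate columns
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dups = sorted({c for c in header if header.count(c) > 1})
        raise TableFormatError(f"{path}: duplicated sample header(s): {dups}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise TableFormatError(f"{path}: expected tab-separated columns")
    raw = raw.set_index(header[0])
    raw.index.name = "taxon_id"
    _check_ids(raw.index, "taxon")
    annot_cols = [c for c in ANNOTATION_COLUMNS if c in raw.columns]
    sample_cols = [c for c in raw.columns if c not in ANNOTATION_COLUMNS]
    taxa = raw[annot_cols].copy()
    data = raw[sample_cols].copy()
    for col in sample_cols:
        try:
            data[col] = pd.to_numeric(data[col])
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}: non-numeric value in column '{col}'") from exc
        if data[col].isna().any():
            row = data.index[data[col].isna()][0]
            raise TableFormatError(f"{path}: missing value at taxon '{row}', sample '{col}'")
    return data, taxa


def read_count_table(path, metadata=None) -> CountTable:
    """Parse a tab-separated count table.

    Layout: first column = taxon id, annotation columns ``name``/``level``/
    ``kingdom`` (and optionally ``genus``), remaining columns = one sample
    each.  Raises :class:`TableFormatError` naming the offending row or
    column on malformed input.

    Parameters
    ----------
    metadata : pandas.DataFrame or path, optional
        Sample metadata; a path is read with :func:`read_sample_metadata`.
    """
    data, taxa = _read_table(path)
    if isinstance(metadata, (str, Path)):
        metadata = read_sample_metadata(metadata)
    if metadata is None:
        metadata = pd.DataFrame(index=data.columns)
    return CountTable(data=data, taxa=taxa, samples=metadata)


def read_abundance_table(path) -> AbundanceTable:
    """Parse a tab-separated RPM table (with its provenance sidecar if present)."""
    data, taxa = _read_table(path)
    side = Path(str(path) + ".provenance.json")
    provenance = json.loads(side.read_text()) if side.exists() else []
    return AbundanceTable(
        data=data, taxa=taxa, samples=pd.DataFrame(index=data.columns), provenance=provenance
    )


def read_sample_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV indexed by ``sample_id``."""
    meta = pd.read_csv(path, sep="\t")
    if "sample_id" not in meta.columns:
        raise TableFormatError(f"{path}: metadata needs a 'sample_id' column")
    meta = meta.set_index("sample_id")
    _check_ids(meta.index, "sample")
    return meta


def write_sample_metadata(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def normalize_rpm(counts: CountTable) -> AbundanceTable:
    """Rescale every sample to one million reads (RPM).

    value(t, s) = count(t, s) / total(s) * 10^6, so each column sums to
    10^6 exactly (up to float round-off).  Samples with zero total reads
    cannot be normalized and raise ``ValueError`` naming them.
    """
    totals = counts.totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"cannot normalize samples with zero total reads: {zero}")
    rpm = counts.data / totals * 1e6
    samples = counts.samples.copy()
    samples["total_reads"] = totals
    return AbundanceTable(
        data=rpm,
        taxa=counts.taxa.copy(),
        samples=samples,
        provenance=[{"step": "normalize_rpm", "basis": "per-sample 1e6"}],
    )


def filter_low_abundance(table: AbundanceTable, threshold: float = 1.0) -> AbundanceTable:
    """Drop taxa whose mean RPM across retained samples is below ``threshold``.

    The cut is strict (< threshold removed; mean exactly at the threshold is
    retained) and the surviving values are left on their original per-sample
    RPM basis — no renormalization.
    """
    means = table.data.mean(axis=1)
    removed = means.index[means < threshold].tolist()
    kept = means.index[means >= threshold]
    out = AbundanceTable(
        data=table.data.loc[kept].copy(),
        taxa=table.taxa.loc[kept].copy(),
        samples=table.samples.copy(),
        provenance=table.provenance
        + [
            {
                "step": "filter_low_abundance",
                "threshold_rpm": threshold,
                "removed_taxa": removed,
            }
        ],
    )
    return out


def exclude_samples(table, excluded=None, min_total_reads=None):
    """Drop samples by explicit id list or by a minimum raw-read threshold.

    Exactly one of ``excluded`` (list of sample ids) and ``min_total_reads``
    must be given.  Works on :class:`CountTable` and :class:`AbundanceTable`
    alike; threshold mode requires per-sample ``total_reads`` metadata.
    Unknown ids raise ``KeyError``.
    """
    if (excluded is None) == (min_total_reads is None):
        raise ValueError("give exactly one of 'excluded' and 'min_total_reads'")
    if excluded is not None:
        excluded = list(excluded)
        unknown = [s for s in excluded if s not in table.data.columns]
        if unknown:
            raise KeyError(f"unknown sample id(s): {unknown}")
        record = {"step": "exclude_samples", "mode": "list", "excluded": excluded}
    else:
        if min_total_reads <= 0:
            raise ValueError("min_total_reads must be positive")
        if isinstance(table, CountTable):
            totals = table.totals()
        else:
            if "total_reads" not in table.samples.columns:
                raise ValueError("threshold mode needs 'total_reads' sample metadata")
            totals = table.samples["total_reads"]
        excluded = totals.index[totals < min_total_reads].tolist()
        record = {
            "step": "exclude_samples",
            "mode": "min_total_reads",
            "threshold": min_total_reads,
            "excluded": excluded,
        }
    keep = [s for s in table.data.columns if s not in set(excluded)]
    if isinstance(table, CountTable):
        return CountTable(
            data=table.data[keep].copy(),
            taxa=table.taxa.copy(),
            samples=table.samples.loc[keep].copy(),
        )
    return AbundanceTable(
        data=table.data[keep].copy(),
        taxa=table.taxa.copy(),
        samples=table.samples.loc[keep].copy(),
        provenance=table.provenance + [record],
    )


def collapse_to_genus(counts: CountTable) -> CountTable:
    """Sum species-level counts into a genus-level table.

    Requires a ``genus`` annotation column on the species rows; genus-level
    rows already present are passed through unchanged.
    """
    species = counts.taxa["level"] == "species"
    if "genus" not in counts.taxa.columns or counts.taxa.loc[species, "genus"].isna().any():
        raise TableFormatError("collapse_to_genus needs a 'genus' annotation for species")
    sp_data = counts.data.loc[species]
    grouped = sp_data.groupby(counts.taxa.loc[species, "genus"]).sum()
    kingdoms = (
        counts.taxa.loc[species].groupby("genus")["kingdom"].agg(lambda k: k.iloc[0])
    )
    taxa = pd.DataFrame(
        {
            "name": grouped.index,
            "level": "genus",
            "kingdom": kingdoms.reindex(grouped.index),
        },
        index=grouped.index,
    )
    passthrough = counts.taxa.index[counts.taxa["level"] == "genus"]
    if len(passthrough):
        grouped = pd.concat([grouped, counts.data.loc[passthrough]])
        taxa = pd.concat([taxa, counts.taxa.loc[passthrough, ["name", "level", "kingdom"]]])
    grouped.index.name = "taxon_id"
    return CountTable(data=grouped, taxa=taxa, samples=counts.samples.copy())
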