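"""Diversity, content summaries, Bray-Curtis PCoA and confidence ellipses.

Implements the between-group community comparisons: per-sample Shannon
diversity, per-group kingdom content (total RPM) with 95% t-intervals and
pooled-variance t-tests, and classical-scaling ordination (PCoA) of the
Bray-Curtis dissimilarity matrix — restricted beforehand to species below
a mean-RPM cap (default 500) so that a handful of dominant species does
not determine the embedding — with normal-theory 95% confidence ellipses
per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .stats import TTestResult, pooled_t_test
from .tables import AbundanceTable


def shannon_index(abundances) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) of one abundance vector.

    Proportions are taken over the positive entries; the vector's scale is
    irrelevant.  An all-zero vector has no defined diversity and raises
    ``ValueError``.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector has undefined diversity")
    p = x[x > 0] / total
    return float(sps.entropy(p))


def shannon_by_sample(table: AbundanceTable, kingdom: str | None = None) -> pd.DataFrame:
    """Per-sample Shannon diversity, optionally scoped to one kingdom.

    Returns a frame with columns ``sample_id``, ``group``, ``kingdom``,
    ``H`` and ``n_taxa`` (taxa with nonzero abundance).  Samples with no
    reads in the scope get ``H = NaN``.
    """
    sub = table.subset_kingdom(kingdom) if kingdom else table
    rows = []
    groups = table.samples.get("group")
    for s in sub.sample_ids:
        col = sub.data[s].to_numpy()
        h = shannon_index(col) if col.sum() > 0 else np.nan
        rows.append(
            {
                "sample_id": s,
                "group": None if groups is None else groups.get(s),
                "kingdom": kingdom or "all",
                "H": h,
                "n_taxa": int((col > 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def group_content_summary(table: AbundanceTable, kingdom: str) -> pd.DataFrame:
    """Per-group mean total RPM of one kingdom with a 95% t-interval.

    The per-sample total is the sum of RPM over taxa of the kingdom; per
    group the summary is mean +/- t_{n-1,0.975} * s / sqrt(n).  Groups with
    fewer than two samples raise ``ValueError``.
    """
    sub = table.subset_kingdom(kingdom)
    totals = sub.data.sum(axis=0)
    groups = table.samples["group"]
    rows = []
    for g, ids in groups.groupby(groups).groups.items():
        vals = totals.loc[list(ids)].to_numpy()
        n = vals.size
        if n < 2:
            raise ValueError(f"group '{g}' has fewer than 2 samples")
        mean = vals.mean()
        half = sps.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
        rows.append(
            {
                "group": g,
                "kingdom": kingdom,
                "n": n,
                "mean_rpm": mean,
                "ci_low": mean - half,
                "ci_high": mean + half,
            }
        )
    return pd.DataFrame(rows)


def compare_content(group_a, group_b) -> TTestResult:
    """Pooled-variance two-sided t-test between two groups of totals."""
    return pooled_t_test(group_a, group_b)


def restrict_species_for_pcoa(
    table: AbundanceTable, cap: float = 500.0
) -> tuple[AbundanceTable, list[str]]:
    """Drop species whose mean RPM reaches ``cap`` before ordination.

    Species with mean RPM >= cap are removed (strictly-below-cap species are
    retained), preventing ubiquitous high-abundance species from dominating
    the Bray-Curtis geometry.  Returns the restricted table and the list of
    removed species ids.
    """
    means = table.data.mean(axis=1)
    is_species = table.taxa["level"] == "species"
    removed = means.index[(means >= cap) & is_species].tolist()
    kept = [t for t in table.taxon_ids if t not in set(removed)]
    out = AbundanceTable(
        data=table.data.loc[kept].copy(),
        taxa=table.taxa.loc[kept].copy(),
        samples=table.samples.copy(),
        provenance=table.provenance
        + [{"step": "restrict_species_for_pcoa", "cap_rpm": cap, "removed_taxa": removed}],
    )
    return out, removed


def bray_curtis_matrix(table) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between samples.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i), in [0, 1]; requires at least
    two samples and no all-zero sample.
    """
    if isinstance(table, AbundanceTable):
        mat = table.data.to_numpy().T
        ids = table.sample_ids
    else:
        df = pd.DataFrame(table)
        mat = df.to_numpy().T
        ids = list(df.columns)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.any(mat < 0):
        raise ValueError("abundances must be nonnegative")
    zero = [ids[i] for i in range(mat.shape[0]) if mat[i].sum() == 0]
    if zero:
        raise ValueError(f"all-zero sample(s): {zero}")
    d = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class PcoaResult:
    """Classical-scaling (PCoA) decomposition of a dissimilarity matrix.

    Attributes
    ----------
    eigenvalues : numpy.ndarray
        All eigenvalues of the Gower-centered matrix, descending; negative
        values (the metric may be non-Euclidean) are reported but excluded
        from ``proportion_explained``.
    proportion_explained : numpy.ndarray
        lambda_i / sum of positive eigenvalues, one entry per positive axis.
    coordinates : pandas.DataFrame
        Samples x positive axes (columns ``PC1``, ``PC2``, ...); each axis
        is eigenvector * sqrt(lambda), sign-fixed so its largest-|value|
        coordinate is positive.
    """

    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    coordinates: pd.DataFrame
    metric: str = "braycurtis"

    @property
    def n_positive(self) -> int:
        return self.coordinates.shape[1]


def pcoa(dissimilarity, n_axes: int | None = None, metric: str = "braycurtis") -> PcoaResult:
    """Principal coordinates analysis via Gower double-centering.

    B = -1/2 J (D o D) J with J = I - 11^T/n is eigendecomposed; sample
    coordinates on each positive-eigenvalue axis are eigenvector *
    sqrt(lambda).  For a Euclidean-embeddable input the coordinates over
    all positive axes reproduce the input distances.

    ``n_axes`` truncates the returned coordinate columns only; eigenvalues
    and explained-variance fractions always cover every axis.
    """
    if isinstance(dissimilarity, pd.DataFrame):
        ids = list(dissimilarity.index)
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        ids = [f"s{i}" for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # numerically-zero eigenvalues are neither axes nor deficits
    tol = max(abs(evals[0]), 1.0) * 1e-10 if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    # reproducible axis orientation: largest-|coordinate| entry positive
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    frac = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        eigenvalues=evals,
        proportion_explained=frac,
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        metric=metric,
    )


@dataclass
class Ellipse:
    """A 2-D normal-theory confidence ellipse.

    ``semi_axes`` are sqrt(eigenvalue * chi2_{2,level}) along the sample
    covariance eigenvectors; ``angle`` is the major axis orientation in
    radians, in (-pi/2, pi/2].  ``degenerate`` marks a singular covariance
    (collinear or duplicated points), in which case the axes are not usable.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float
    level: float
    degenerate: bool = False


def confidence_ellipse(points, level: float = 0.95) -> Ellipse:
    """Confidence ellipse of 2-D points under a bivariate-normal model.

    The contour encloses ``level`` probability for a normal with the sample
    mean and covariance: semi-axis_i = sqrt(lambda_i * chi2_{2,level})
    (chi2_{2,0.95} = 5.9915).  Needs n >= 3; a singular covariance returns
    a degenerate-flagged ellipse rather than raising.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    center = tuple(pts.mean(axis=0))
    cov = np.cov(pts, rowvar=False)
    evals, evecs = linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[-1] <= max(evals[0], 1.0) * 1e-12:
        return Ellipse(center=center, semi_axes=(0.0, 0.0), angle=0.0, level=level, degenerate=True)
    scale = sps.chi2.ppf(level, df=2)
    semi = tuple(np.sqrt(evals * scale))
    major = evecs[:, 0]
    angle = float(np.arctan2(major[1], major[0]))
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return Ellipse(center=center, semi_axes=semi, angle=angle, level=level)


def group_ellipses(
    coordinates: pd.DataFrame, groups: pd.Series, axes=("PC1", "PC2"), level: float = 0.95
) -> dict[str, Ellipse]:
    """Confidence ellipse per group on two ordination axes."""
    out = {}
    for g, ids in groups.groupby(groups).groups.items():
        pts = coordinates.loc[list(ids), list(axes)].to_numpy()
        if pts.shape[0] >= 3:
            out[g] = confidence_ellipse(pts, level=level)
    return out
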