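"""Differential intron retention with borrowed normalization.

Intron read counts are a small subset of the library totals, so
size factors estimated from the intron sub-matrix alone would absorb
genuine global shifts in retention (e.g. a mutant that retains most
introns more). The retention test therefore borrows the per-library
size factors estimated from the complete gene-level matrix of the same
libraries, and never re-estimates them from the intron matrix. The
testing machinery and the significance criteria are identical to the
gene-level analysis.

Also provides the two clustering displays: complete-linkage clustering
of the DR-intron fold-change matrix, and average-linkage clustering of
the libraries on correspondence-analysis coordinates of the quantile-
discretized count matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .counting import CountMatrix
from .diffexpr import (
    DEFAULT_ALPHA,
    DEFAULT_LFC_THRESHOLD,
    FilterSpec,
    SizeFactors,
    bh_adjust,
    classify_de,
    estimate_dispersion,
    low_count_filter,
    nb_wald_test,
)

logger = logging.getLogger(__name__)


def dr_test(
    intron_matrix: CountMatrix,
    gene_size_factors: SizeFactors,
    control: str,
    mutant: str,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """NB Wald test of intron retention, mutant vs control.

    ``gene_size_factors`` must come from the gene matrix of the same
    library set (hard error otherwise); the intron matrix is expected to
    be pre-filtered with the same low-count filter as the genes. The
    returned frame adds a ``direction`` column: more_retained for a
    positive fold change, less_retained for a negative one.
    """
    missing = set(intron_matrix.library_ids) - set(gene_size_factors.factors.index)
    if missing:
        raise ValueError(
            "gene size factors do not cover intron libraries: "
            f"{sorted(missing)}"
        )
    sf = SizeFactors(
        gene_size_factors.factors.loc[intron_matrix.library_ids],
        gene_size_factors.method,
    )
    disp = estimate_dispersion(intron_matrix, sf, intron_matrix.meta["strain"])
    res = nb_wald_test(intron_matrix, sf, disp, control, mutant)
    res["padj"] = bh_adjust(res["p"])
    res["dispersion"] = disp
    res["status"] = classify_de(res, lfc_threshold, alpha)
    res["significant"] = res["status"].isin(["up", "down"])
    res["direction"] = np.where(res["log2fc"] > 0, "more_retained",
                                np.where(res["log2fc"] < 0, "less_retained", "none"))
    res.index.name = "intron_id"
    return res


def union_dr(dr_results: dict[str, pd.DataFrame]) -> tuple[list[str], pd.DataFrame]:
    """Introns significantly DR in at least one mutant.

    ``dr_results`` maps mutant name to a dr_test frame over the same
    intron universe. Returns the sorted union and the introns x mutants
    log2 fold-change matrix over that union (for the heatmap), with a
    parallel boolean significance mask stored in attrs['significant'].
    """
    universes = {frozenset(df.index) for df in dr_results.values()}
    if len(universes) > 1:
        raise ValueError("dr_test results cover different intron universes")
    union: set[str] = set()
    for df in dr_results.values():
        union |= set(df.index[df["significant"]])
    ordered = sorted(union)
    fc = pd.DataFrame(
        {m: df.loc[ordered, "log2fc"] for m, df in dr_results.items()}
    )
    fc.attrs["significant"] = pd.DataFrame(
        {m: df.loc[ordered, "significant"] for m, df in dr_results.items()}
    )
    return ordered, fc


def restrict_to_nonde(
    dr_introns: list[str],
    intron_hosts: pd.Series,
    gene_de: pd.DataFrame,
) -> list[str]:
    """Keep DR introns whose host gene is not differentially expressed.

    ``intron_hosts`` maps intron_id to gene_id; ``gene_de`` is the gene
    DE frame for the same mutant. An intron is kept iff its host's
    status is 'ns'. Hosts removed by the gene low-count filter (status
    'filtered') cannot be certified non-DE and are excluded. An intron
    whose host is absent from the DE table is a hard error.
    """
    kept = []
    for intron in dr_introns:
        try:
            gene = intron_hosts.loc[intron]
        except KeyError as exc:
            raise KeyError(f"intron {intron!r} has no host-gene mapping") from exc
        if gene not in gene_de.index:
            raise KeyError(
                f"host gene {gene!r} of intron {intron!r} absent from DE table"
            )
        if gene_de.loc[gene, "status"] == "ns":
            kept.append(intron)
    return kept


@dataclass
class ClusterResult:
    """Deterministic agglomerative clustering output for one axis."""

    order: list[str]
    linkage: np.ndarray
    labels: list[str] = field(default_factory=list)


def _cluster_axis(mat: np.ndarray, labels: list[str], method: str) -> ClusterResult:
    if mat.shape[0] < 2:
        return ClusterResult(order=list(labels), linkage=np.empty((0, 4)),
                             labels=list(labels))
    # stable tie-breaking: sort rows lexicographically by label first
    idx = sorted(range(len(labels)), key=lambda i: labels[i])
    sorted_labels = [labels[i] for i in idx]
    d = pdist(mat[idx], metric="euclidean")
    link = hierarchy.linkage(d, method=method)
    leaf_order = hierarchy.leaves_list(
        hierarchy.optimal_leaf_ordering(link, d)
    )
    return ClusterResult(
        order=[sorted_labels[i] for i in leaf_order],
        linkage=link,
        labels=sorted_labels,
    )


def cluster_fold_changes(
    fc_matrix: pd.DataFrame,
) -> tuple[ClusterResult, ClusterResult]:
    """Complete-linkage Euclidean clustering of the fold-change heatmap.

    Rows (introns) and columns (mutants) are clustered independently;
    non-significant cells carry their estimated fold change. Returns
    (row clustering, column clustering).
    """
    mat = fc_matrix.to_numpy(dtype=float)
    rows = _cluster_axis(mat, list(fc_matrix.index), "complete")
    cols = _cluster_axis(mat.T, list(fc_matrix.columns), "complete")
    return rows, cols


def discretize_quantiles(counts: pd.DataFrame, n_levels: int = 5) -> pd.DataFrame:
    """Discretize a count table into quantile levels.

    Breaks are global 20/40/60/80% quantiles over the nonzero entries;
    zeros form their own lowest level (0), nonzero entries map to
    1..n_levels.
    """
    values = counts.to_numpy(dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return pd.DataFrame(np.zeros_like(values, dtype=int),
                            index=counts.index, columns=counts.columns)
    qs = np.quantile(nonzero, np.linspace(0, 1, n_levels + 1)[1:-1])
    levels = np.zeros_like(values, dtype=int)
    nz = values > 0
    levels[nz] = 1 + np.searchsorted(qs, values[nz], side="left")
    return pd.DataFrame(levels, index=counts.index, columns=counts.columns)


def correspondence_analysis(table: pd.DataFrame) -> pd.DataFrame:
    """Correspondence analysis of a nonnegative table.

    SVD of the standardized Pearson residuals; returns the principal
    coordinates of the columns (libraries) on all retained axes.
    Zero-sum rows are dropped; a zero-sum column is an error.
    """
    mat = table.to_numpy(dtype=float)
    row_keep = mat.sum(axis=1) > 0
    mat = mat[row_keep]
    if mat.size == 0:
        raise ValueError("empty table after dropping zero rows")
    if (mat.sum(axis=0) <= 0).any():
        raise ValueError("column with zero total")
    total = mat.sum()
    p = mat / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    s = (p - expected) / np.sqrt(expected)
    u, sing, vt = np.linalg.svd(s, full_matrices=False)
    # principal column coordinates; drop trivial zero-inertia axes
    keep = sing > 1e-12
    coords = (vt[keep].T * sing[keep]) / np.sqrt(c)[:, None]
    return pd.DataFrame(
        coords, index=table.columns,
        columns=[f"axis{i+1}" for i in range(int(keep.sum()))],
    )


def coa_library_clustering(
    matrix: CountMatrix, n_levels: int = 5
) -> tuple[pd.DataFrame, ClusterResult]:
    """Cluster libraries on correspondence-analysis coordinates.

    Counts are discretized into five quantile levels, a correspondence
    analysis is run on the discretized table, and the libraries are
    clustered by average linkage on Euclidean distances between their
    coordinates (all retained axes). Returns (coordinates, clustering).
    """
    if len(matrix.library_ids) < 2:
        coords = pd.DataFrame(index=matrix.library_ids)
        return coords, ClusterResult(order=list(matrix.library_ids),
                                     linkage=np.empty((0, 4)),
                                     labels=list(matrix.library_ids))
    disc = discretize_quantiles(matrix.counts, n_levels=n_levels)
    coords = correspondence_analysis(disc)
    clustering = _cluster_axis(coords.to_numpy(), list(coords.index), "average")
    return coords, clustering


def plot_fold_change_heatmap(
    fc_matrix: pd.DataFrame,
    rows: ClusterResult,
    cols: ClusterResult,
    path,
) -> None:
    """Render the clustered DR fold-change heatmap to a file.

    Cosmetic output only; the tested surface is the cluster orderings
    and merge heights, not the rendering.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = fc_matrix.loc[rows.order, cols.order]
    fig, ax = plt.subplots(
        figsize=(2 + 0.5 * len(cols.order), 2 + 0.18 * len(rows.order)))
    vmax = max(abs(ordered.to_numpy()).max(), 1e-6)
    im = ax.imshow(ordered.to_numpy(), cmap="RdYlGn", vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(len(cols.order)), cols.order, rotation=90)
    ax.set_yticks(range(len(rows.order)), rows.order, fontsize=5)
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dr_analysis(
    intron_matrix: CountMatrix,
    gene_size_factors: SizeFactors,
    control: str,
    mutants: list[str],
    filter_spec: FilterSpec | None = None,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[dict[str, pd.DataFrame], list[str], pd.DataFrame]:
    """Filter the intron matrix and run dr_test for every mutant.

    Returns (per-mutant results over the filtered universe, union of DR
    introns, fold-change matrix over the union).
    """
    kept, removed = low_count_filter(intron_matrix, filter_spec)
    logger.info("intron filter: %d kept, %d removed", len(kept), len(removed))
    sub = intron_matrix.subset_features(kept)
    results = {
        m: dr_test(sub, gene_size_factors, control, m,
                   lfc_threshold=lfc_threshold, alpha=alpha)
        for m in mutants
    }
    union, fc = union_dr(results)
    return results, union, fc
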