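"""Single-cell QC filtering, normalization, graph-based clustering and
marker-count-driven cluster merging.

The viable-barcode rule keeps barcodes with >= 2000 total UMIs (inclusive)
and a mitochondrial UMI fraction strictly below 8%.  Clusters whose
one-vs-rest expression elevates fewer than 30 genes at >= 1.5-fold are
iteratively merged into their most similar cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import CellMatrix

__all__ = [
    "QCReport",
    "qc_filter_barcodes",
    "normalize_cells",
    "cluster_cells",
    "merge_small_clusters",
    "count_qualifying_genes",
]


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    n_low_umi: int
    n_high_mito: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_kept


def qc_filter_barcodes(
    matrix: CellMatrix, min_umi: int = 2000, max_mito_fraction: float = 0.08
) -> tuple[CellMatrix, QCReport]:
    """Keep barcodes with total UMI >= min_umi AND mito fraction < max_mito.

    Both thresholds follow the viable-cell rule: the UMI bound is
    inclusive, the mitochondrial bound strict.  Warns (without failing)
    if no barcode survives.
    """
    totals = matrix.umi_totals()
    mito_frac = matrix.mito_fractions()
    pass_umi = totals >= min_umi
    pass_mito = mito_frac < max_mito_fraction
    keep = pass_umi & pass_mito
    report = QCReport(
        n_input=matrix.n_barcodes,
        n_kept=int(keep.sum()),
        n_low_umi=int((~pass_umi).sum()),
        n_high_mito=int((~pass_mito).sum()),
    )
    if report.n_kept == 0:
        warnings.warn(
            "QC filter removed every barcode; returning an empty matrix",
            stacklevel=2,
        )
    return matrix.subset_barcodes(keep), report


def normalize_cells(matrix: CellMatrix, scale: float = 1e4) -> np.ndarray:
    """Per-cell depth normalization to ``scale`` total, then log1p.

    Returns a dense genes x cells array of log1p(count * scale / total).
    Raises on zero-total barcodes (impossible after QC).
    """
    totals = matrix.umi_totals().astype(float)
    if np.any(totals == 0):
        raise ValueError("cannot normalize barcodes with zero total UMIs")
    x = matrix.counts.toarray().astype(float)
    x *= scale / totals[None, :]
    return np.log1p(x)


def _per_donor_standardize(x_cells: np.ndarray, donors: np.ndarray) -> np.ndarray:
    """Z-score genes within each donor (a light-weight stand-in for
    cross-donor alignment; synthetic data carry no donor shifts)."""
    out = np.empty_like(x_cells)
    for d in np.unique(donors):
        sel = donors == d
        block = x_cells[sel]
        mean = block.mean(axis=0)
        sd = block.std(axis=0)
        sd[sd == 0] = 1.0
        out[sel] = (block - mean) / sd
    return out


def cluster_cells(
    normalized: np.ndarray,
    k_neighbors: int = 15,
    resolution: float = 0.3,
    seed: int = 0,
    donors: np.ndarray | None = None,
    n_pcs: int = 30,
    method: str = "leiden",
    n_clusters: int = 8,
) -> np.ndarray:
    """Cluster cells on a kNN graph over PCA-reduced expression.

    ``normalized`` is genes x cells (from :func:`normalize_cells`).  Genes
    are standardized (per donor when labels are given) before PCA; the
    kNN graph is partitioned with the Leiden algorithm at the given
    resolution.  ``method="kmeans"`` substitutes a deterministic spherical
    k-means with ``n_clusters`` centers.  Deterministic given ``seed``.
    """
    from sklearn.decomposition import PCA

    n_cells = normalized.shape[1]
    if n_cells < 2 * k_neighbors:
        raise ValueError(
            f"need at least {2 * k_neighbors} cells for k_neighbors={k_neighbors}"
        )
    x = normalized.T
    if donors is not None:
        x = _per_donor_standardize(x, np.asarray(donors))
    else:
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mean) / sd
    n_comp = min(n_pcs, n_cells - 1, x.shape[1] - 1)
    pcs = PCA(
        n_components=n_comp, svd_solver="randomized", random_state=seed
    ).fit_transform(x)

    if method == "kmeans":
        from sklearn.cluster import KMeans

        norms = np.linalg.norm(pcs, axis=1)
        norms[norms == 0] = 1.0
        unit = pcs / norms[:, None]
        labels = KMeans(
            n_clusters=min(n_clusters, n_cells), n_init=10, random_state=seed
        ).fit_predict(unit)
        return _contiguous(labels)
    if method != "leiden":
        raise ValueError(f"unknown clustering method '{method}'")

    import igraph
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(pcs)
    adj = nn.kneighbors_graph(mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = igraph.Graph(n=n_cells, edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return _contiguous(np.asarray(part.membership))


def _contiguous(labels: np.ndarray) -> np.ndarray:
    """Re-index labels to 0..k-1 in order of first appearance."""
    labels = np.asarray(labels)
    mapping: dict[int, int] = {}
    out = np.empty(labels.size, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def count_qualifying_genes(
    normalized: np.ndarray,
    labels: np.ndarray,
    cluster: int,
    min_fold: float = 1.5,
    pseudocount: float = 1e-9,
) -> int:
    """Number of genes whose linear-scale mean expression in the cluster is
    >= min_fold times the mean in all other cells."""
    linear = np.expm1(normalized)
    in_mask = labels == cluster
    mean_in = linear[:, in_mask].mean(axis=1)
    mean_out = linear[:, ~in_mask].mean(axis=1)
    return int(np.sum(mean_in >= min_fold * (mean_out + pseudocount)))


def merge_small_clusters(
    normalized: np.ndarray,
    labels: np.ndarray,
    min_markers: int = 30,
    min_fold: float = 1.5,
) -> np.ndarray:
    """Iteratively merge clusters that elevate too few genes.

    A cluster with fewer than ``min_markers`` genes at >= ``min_fold``
    linear-scale one-vs-rest elevation is merged into the cluster whose
    log-space centroid it correlates with best (Pearson).  Repeats until
    every cluster qualifies or one remains; the result is re-indexed
    contiguously.  Never increases the cluster count.
    """
    labels = np.asarray(labels).copy()
    while True:
        ids = np.unique(labels)
        if ids.size <= 1:
            break
        counts = {
            c: count_qualifying_genes(normalized, labels, c, min_fold)
            for c in ids
        }
        failing = [c for c in ids if counts[c] < min_markers]
        if not failing:
            break
        # merge the weakest failing cluster first (ties -> smallest id)
        worst = min(failing, key=lambda c: (counts[c], c))
        centroids = {c: normalized[:, labels == c].mean(axis=1) for c in ids}
        best, best_r = None, -np.inf
        for c in ids:
            if c == worst:
                continue
            a, b = centroids[worst], centroids[c]
            sa, sb = a.std(), b.std()
            r = (
                float(np.corrcoef(a, b)[0, 1])
                if sa > 0 and sb > 0
                else -np.inf if sa != sb else 1.0
            )
            if r > best_r or (r == best_r and (best is None or c < best)):
                best, best_r = c, r
        if best is None:
            best = int(min(c for c in ids if c != worst))
        labels[labels == worst] = best
    return _contiguous(labels)
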