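"""One-vs-rest marker statistics per cluster and signature construction.

Markers are ranked by a two-sided Wilcoxon rank-sum test per gene (exact
enumeration when both groups have <= 10 cells, tie-corrected normal
approximation otherwise) with BH adjustment within each cluster.
Signatures keep genes with FDR < 0.01 and positive fold change, ordered
by descending log2 fold change, capped at 50 genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import benjamini_hochberg, rank_sum_exact, rank_sum_normal_p
from .containers import SignatureSet
from .io import read_gmt, write_gmt  # noqa: F401  (module surface)

__all__ = [
    "rank_sum_markers",
    "marker_table",
    "build_signature",
    "build_all_signatures",
    "read_gmt",
    "write_gmt",
]

#: Pseudocount guarding fold-change denominators.
FC_PSEUDOCOUNT = 1e-9

#: Largest per-group size for which the exact rank-sum enumeration is used.
EXACT_MAX_N = 10


def _log2_fold_change(linear: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    mean_in = linear[:, in_mask].mean(axis=1)
    mean_out = linear[:, ~in_mask].mean(axis=1)
    return np.log2((mean_in + FC_PSEUDOCOUNT) / (mean_out + FC_PSEUDOCOUNT))


def rank_sum_markers(
    normalized: np.ndarray,
    labels: np.ndarray,
    cluster: int,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene one-vs-rest Wilcoxon statistics for one cluster.

    ``normalized`` is genes x cells in log1p space; fold changes are
    computed on linear-scale means.  Returns a DataFrame with columns
    cluster, gene, log2fc, stat, p, fdr, frac_in, frac_out.
    """
    labels = np.asarray(labels)
    in_mask = labels == cluster
    n1 = int(in_mask.sum())
    n2 = int((~in_mask).sum())
    if n1 == 0:
        raise ValueError(f"cluster {cluster} is empty")
    if n2 == 0:
        raise ValueError(f"cluster {cluster} contains every cell")
    n_genes = normalized.shape[0]
    gene_ids = list(gene_ids) if gene_ids is not None else [
        f"g{i}" for i in range(n_genes)
    ]

    linear = np.expm1(normalized)
    log2fc = _log2_fold_change(linear, in_mask)
    frac_in = (normalized[:, in_mask] > 0).mean(axis=1)
    frac_out = (normalized[:, ~in_mask] > 0).mean(axis=1)

    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
        w = np.empty(n_genes)
        p = np.empty(n_genes)
        for g in range(n_genes):
            w[g], p[g] = rank_sum_exact(
                normalized[g, in_mask], normalized[g, ~in_mask]
            )
    else:
        ranks = stats.rankdata(normalized, axis=1)
        w = ranks[:, in_mask].sum(axis=1)
        tie_term = _tie_terms(normalized)
        p = rank_sum_normal_p(w, n1, n2, tie_term)

    fdr = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "cluster": cluster,
            "gene": gene_ids,
            "log2fc": log2fc,
            "stat": w,
            "p": p,
            "fdr": fdr,
            "frac_in": frac_in,
            "frac_out": frac_out,
        }
    )


def _tie_terms(x: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tied groups, per row."""
    s = np.sort(x, axis=1)
    n = x.shape[1]
    out = np.zeros(x.shape[0])
    # run-length encode ties per row
    boundaries = np.ones_like(s, dtype=bool)
    boundaries[:, 1:] = s[:, 1:] != s[:, :-1]
    for i in range(x.shape[0]):
        idx = np.flatnonzero(boundaries[i])
        runs = np.diff(np.append(idx, n)).astype(float)
        out[i] = float(np.sum(runs**3 - runs))
    return out


def marker_table(
    normalized: np.ndarray, labels: np.ndarray, gene_ids: list[str] | None = None
) -> pd.DataFrame:
    """Concatenated one-vs-rest marker statistics for every cluster."""
    frames = [
        rank_sum_markers(normalized, labels, int(c), gene_ids)
        for c in np.unique(labels)
    ]
    return pd.concat(frames, ignore_index=True)


def build_signature(
    markers: pd.DataFrame,
    cluster: int,
    max_genes: int = 50,
    fdr_cut: float = 0.01,
) -> tuple[list[str], list[float]]:
    """Genes with FDR < fdr_cut and positive log2FC for one cluster,
    ordered by descending log2FC (ties broken by gene id), capped at
    ``max_genes``.  Returns (genes, log2 fold changes); empty with a
    warning when nothing qualifies."""
    sub = markers[markers["cluster"] == cluster]
    qualifying = sub[(sub["fdr"] < fdr_cut) & (sub["log2fc"] > 0)]
    if qualifying.empty:
        warnings.warn(
            f"cluster {cluster}: no genes pass FDR < {fdr_cut} with positive "
            "fold change; signature is empty",
            stacklevel=2,
        )
        return [], []
    ordered = qualifying.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    ).head(max_genes)
    return ordered["gene"].tolist(), ordered["log2fc"].tolist()


def build_all_signatures(
    markers: pd.DataFrame,
    max_genes: int = 50,
    fdr_cut: float = 0.01,
    names: dict[int, str] | None = None,
) -> SignatureSet:
    """Signature set over every cluster present in the marker table."""
    sigs = SignatureSet(max_genes=max_genes)
    for cluster in sorted(markers["cluster"].unique()):
        genes, effects = build_signature(markers, cluster, max_genes, fdr_cut)
        name = names[cluster] if names else f"cluster_{cluster}"
        sigs.add(name, genes, effects)
    return sigs
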