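"""Concordance between treatment-induced and disease-activity-associated
per-gene expression changes.

The treatment axis is the mean paired week14 - screening log2-CPM change
within an arm; the activity axis is the active-vs-inactive coefficient
from the screening-only model.  An inverse correlation indicates that
treatment pushes expression away from the inflamed state.
"""

from __future__ import annotations

import pandas as pd
import numpy as np
from scipy import stats

from .bulkstats import DEResults, de_active_vs_inactive, log2cpm
from .containers import BulkStudy, build_pairs

__all__ = [
    "treatment_change_per_gene",
    "correlate_changes",
    "build_fold_change_pairs",
]


def treatment_change_per_gene(
    expression: pd.DataFrame, meta: pd.DataFrame, arm: str
) -> pd.Series:
    """Per-gene mean paired (week14 - screening) change within one arm.

    ``expression`` is a log2-CPM genes x samples matrix.  Raises when the
    arm has no complete pairs.
    """
    pairs, _ = build_pairs(meta)
    pairs = pairs[pairs["arm"] == arm]
    if len(pairs) == 0:
        raise ValueError(f"no complete pairs in arm '{arm}'")
    delta = (
        expression[pairs["week14"].tolist()].to_numpy()
        - expression[pairs["screening"].tolist()].to_numpy()
    )
    return pd.Series(delta.mean(axis=1), index=expression.index, name=f"fc_{arm}")


def build_fold_change_pairs(
    study: BulkStudy,
    arm: str = "treatment",
    activity: DEResults | None = None,
    genes: pd.Index | None = None,
    min_reads: int = 10,
    min_samples: int = 31,
) -> pd.DataFrame:
    """Per-gene (treatment log2FC, activity log2FC) table.

    ``activity`` defaults to the screening-only active-vs-inactive model;
    ``genes`` restricts the universe (defaults to the activity model's
    filtered genes).
    """
    if activity is None:
        activity = de_active_vs_inactive(study, min_reads, min_samples)
    expr = log2cpm(study.counts)
    fc_treat = treatment_change_per_gene(expr, study.meta, arm)
    universe = activity.table.index.intersection(fc_treat.index)
    if genes is not None:
        universe = universe.intersection(pd.Index(genes))
    out = pd.DataFrame(
        {
            "fc_treatment": fc_treat.loc[universe],
            "fc_activity": activity.table.loc[universe, "log2fc"],
        }
    )
    return out.dropna()


def correlate_changes(
    pairs: pd.DataFrame, gene_subset=None, method: str = "pearson"
) -> tuple[float, float, int]:
    """Correlation between the treatment and activity fold-change axes.

    Returns (r, two-sided p, n).  ``gene_subset`` restricts to the given
    genes (requires at least 3); zero variance on either axis raises.
    """
    if gene_subset is not None:
        pairs = pairs.loc[pairs.index.intersection(pd.Index(gene_subset))]
    x = pairs["fc_treatment"].to_numpy(dtype=float)
    y = pairs["fc_activity"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 genes to correlate fold changes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance on a fold-change axis")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method '{method}'")
    return float(r), float(p), int(x.size)
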