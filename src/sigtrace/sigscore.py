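"""Eigengene signature scoring of bulk samples, paired longitudinal
score changes, and between-arm comparison.

A signature score is the first right singular vector of the z-scored
(per gene, across samples) expression of the signature's genes, oriented
to correlate non-negatively with the per-sample mean of the z-scores and
reported on the z scale (mean 0, unit variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import benjamini_hochberg
from .bulkstats import log2cpm
from .containers import BulkStudy, SignatureSet, build_pairs

__all__ = [
    "eigengene_score",
    "paired_change",
    "compare_arms",
    "score_all_signatures",
    "ScoreTable",
    "ArmComparison",
]


def eigengene_score(expression: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Per-sample eigengene score of a gene set.

    ``expression`` is a log-scale genes x samples matrix.  Genes absent
    from the matrix are dropped with a warning if at least half remain
    (else an error); zero-variance genes are dropped with a warning.
    Scores are invariant to per-gene affine transforms and to gene order.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("a signature needs at least 2 genes")
    present = [g for g in genes if g in expression.index]
    missing = sorted(set(genes) - set(present))
    if len(present) < max(2, len(genes) / 2.0):
        raise ValueError(
            f"too few signature genes found in the expression matrix; "
            f"missing: {missing}"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} signature genes absent from the matrix "
            f"(e.g. {missing[:5]}); scoring the remaining {len(present)}",
            stacklevel=2,
        )
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples to score a signature")
    sub = expression.loc[present].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    if np.any(sd == 0):
        dropped = [present[i] for i in np.flatnonzero(sd == 0)]
        warnings.warn(
            f"dropping zero-variance signature genes: {dropped[:5]}"
            + ("..." if len(dropped) > 5 else ""),
            stacklevel=2,
        )
        keepers = sd > 0
        sub = sub[keepers]
        sd = sd[keepers]
        if sub.shape[0] < 2:
            raise ValueError("fewer than 2 signature genes with variance")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    # first right singular vector = leading sample-space component
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    mean_profile = z.mean(axis=0)
    orient = float(v @ mean_profile)
    if orient < 0 or (orient == 0 and v[np.argmax(np.abs(v))] < 0):
        v = -v
    score = (v - v.mean()) / v.std()
    return pd.Series(score, index=expression.columns, name="score")


def paired_change(
    scores: pd.Series, meta: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Per-patient paired score change (week14 - screening, same segment).

    Returns a DataFrame with columns (patient_id, location, arm, delta)
    and the list of sample_ids excluded for lack of a partner.  Duplicate
    pairs for one patient+location raise an error.
    """
    pairs, unpaired = build_pairs(meta)
    rows = [
        {
            "patient_id": row.patient_id,
            "location": row.location,
            "arm": row.arm,
            "delta": float(scores[row.week14] - scores[row.screening]),
        }
        for row in pairs.itertuples()
    ]
    deltas = pd.DataFrame(rows, columns=["patient_id", "location", "arm", "delta"])
    return deltas, unpaired


def compare_arms(
    deltas: pd.DataFrame, kind: str = "welch"
) -> tuple[float, float, float]:
    """Two-sample t-test on paired deltas, treatment minus placebo.

    Returns (mean difference, t statistic, two-sided p).  ``kind`` is
    ``welch`` (default, unequal variances) or ``student``.  Arms with
    fewer than 2 deltas raise; two zero-variance arms with equal means
    yield p = 1 with a warning.
    """
    tr = deltas.loc[deltas["arm"] == "treatment", "delta"].to_numpy(dtype=float)
    pl = deltas.loc[deltas["arm"] == "placebo", "delta"].to_numpy(dtype=float)
    if tr.size < 2 or pl.size < 2:
        raise ValueError("need at least 2 paired deltas per arm")
    diff = float(tr.mean() - pl.mean())
    if tr.std(ddof=1) == 0 and pl.std(ddof=1) == 0:
        warnings.warn(
            "both arms have zero-variance deltas; p-value is degenerate",
            stacklevel=2,
        )
        return diff, 0.0 if diff == 0 else np.inf, 1.0 if diff == 0 else 0.0
    res = stats.ttest_ind(tr, pl, equal_var=(kind == "student"))
    return diff, float(res.statistic), float(res.pvalue)


@dataclass
class ScoreTable:
    """Per-sample signature scores plus per-patient paired changes."""

    scores: pd.DataFrame  # samples x signatures
    deltas: pd.DataFrame  # patient_id, location, arm, signature, delta
    excluded: list[str] = field(default_factory=list)


@dataclass
class ArmComparison:
    """Per-signature arm comparison of paired score changes."""

    table: pd.DataFrame  # signature, delta_treatment, delta_placebo, diff, t, p, fdr

    def summary(self) -> str:
        return self.table.to_string(
            index=False, float_format=lambda v: f"{v:.4g}"
        )


def score_all_signatures(
    study: BulkStudy,
    signatures: SignatureSet,
    expression: pd.DataFrame | None = None,
    kind: str = "welch",
) -> tuple[ScoreTable, ArmComparison]:
    """Score every signature, compute paired changes and compare arms.

    ``expression`` defaults to log2-CPM of the study counts.  The arm
    comparison table carries one row per signature with the mean paired
    delta per arm, the difference, Welch t, p and BH-FDR across
    signatures.
    """
    if len(signatures) == 0:
        raise ValueError("signature set is empty")
    if expression is None:
        expression = log2cpm(study.counts)
    score_cols = {}
    delta_frames = []
    excluded: set[str] = set()
    comp_rows = []
    for name in signatures:
        s = eigengene_score(expression, signatures.genes(name))
        score_cols[name] = s
        deltas, unpaired = paired_change(s, study.meta)
        excluded.update(unpaired)
        deltas = deltas.assign(signature=name)
        delta_frames.append(deltas)
        diff, tstat, p = compare_arms(deltas, kind=kind)
        comp_rows.append(
            {
                "signature": name,
                "delta_treatment": float(
                    deltas.loc[deltas["arm"] == "treatment", "delta"].mean()
                ),
                "delta_placebo": float(
                    deltas.loc[deltas["arm"] == "placebo", "delta"].mean()
                ),
                "diff": diff,
                "t": tstat,
                "p": p,
            }
        )
    comp = pd.DataFrame(comp_rows)
    comp["fdr"] = benjamini_hochberg(comp["p"].to_numpy())
    table = ScoreTable(
        scores=pd.DataFrame(score_cols),
        deltas=pd.concat(delta_frames, ignore_index=True),
        excluded=sorted(excluded),
    )
    return table, ArmComparison(table=comp)
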