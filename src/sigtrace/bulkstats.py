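"""Bulk RNA-seq differential expression: gene filtering, log-CPM with
precision weights from the fitted mean-variance trend, per-gene weighted
least squares with empirical-Bayes variance moderation, BH adjustment,
and the three-clause treatment-modulated-gene call.

The central objects are :class:`DifferentialExpressionModel` (built from
counts and a design, or from a :class:`~sigtrace.containers.BulkStudy`
via :meth:`~DifferentialExpressionModel.from_study`) and the
:class:`DEResults` returned by ``fit()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import benjamini_hochberg, squeeze_variances
from .containers import BulkStudy

__all__ = [
    "cpm",
    "log2cpm",
    "filter_genes",
    "voom_weights",
    "fit_and_moderate",
    "adjust_bh",
    "call_treatment_modulated",
    "de_active_vs_inactive",
    "build_design",
    "DifferentialExpressionModel",
    "DEResults",
]


def cpm(counts, libsizes=None) -> pd.DataFrame | np.ndarray:
    """Counts per million: count * 1e6 / library size."""
    values = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    if libsizes is None:
        libsizes = values.sum(axis=0)
    libsizes = np.asarray(libsizes, dtype=float)
    if np.any(libsizes <= 0):
        raise ValueError("library sizes must be positive")
    out = values * 1e6 / libsizes[None, :]
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def log2cpm(counts) -> pd.DataFrame | np.ndarray:
    """log2 CPM with a 0.5 pseudocount on counts and +1 on library size."""
    values = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    lib = values.sum(axis=0).astype(float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    out = np.log2((values + 0.5) / (lib[None, :] + 1.0) * 1e6)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return out


def filter_genes(counts, min_reads: int = 10, min_samples: int = 31):
    """Genes with count > min_reads in > min_samples samples (both strict).

    Returns a pandas Index for DataFrame input, else an integer index
    array.
    """
    values = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    n_pass = (values > min_reads).sum(axis=1)
    keep = n_pass > min_samples
    if isinstance(counts, pd.DataFrame):
        return counts.index[keep]
    return np.flatnonzero(keep)


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        aliased = []
        cols = list(design.columns)
        kept: list[int] = []
        for j in range(x.shape[1]):
            trial = x[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(j)
            else:
                aliased.append(cols[j])
        raise ValueError(
            f"design matrix is rank-deficient; aliased columns: {aliased}"
        )


def voom_weights(
    counts, design: pd.DataFrame, span: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Observation-level precision weights from the mean-variance trend.

    Fits gene-wise OLS of log2-CPM on the design, smooths
    sqrt(residual sd) against average log2 count with lowess
    (``frac=span``), interpolates the trend at each observation's fitted
    log2 count, and returns ``(log2cpm, weights)`` with
    weight = trend^-4.  Degenerate trends (fewer than two genes, or a
    flat axis) fall back to unit weights with a warning.
    """
    values = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    x = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    if isinstance(design, pd.DataFrame):
        _check_full_rank(design)
    n_genes, n_samples = values.shape
    n_coef = x.shape[1]
    if n_samples - n_coef <= 0:
        raise ValueError("no residual degrees of freedom in the design")
    lib = values.sum(axis=0).astype(float)
    y = np.log2((values + 0.5) / (lib[None, :] + 1.0) * 1e6)

    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T
    fitted = beta @ x.T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n_samples - n_coef))

    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    if n_genes < 2 or np.ptp(sx) == 0:
        warnings.warn(
            "mean-variance trend is degenerate; using unit weights",
            stacklevel=2,
        )
        return y, np.ones_like(y)

    from statsmodels.nonparametric.smoothers_lowess import lowess

    lo = lowess(sy, sx, frac=span, it=3, return_sorted=True)
    lo_x, lo_y = lo[:, 0], lo[:, 1]
    fitted_count = fitted + np.log2(lib[None, :] + 1.0) - np.log2(1e6)
    trend = np.interp(fitted_count, lo_x, lo_y)
    trend = np.maximum(trend, 1e-6)
    weights = trend**-4
    return y, weights


@dataclass
class DEResults:
    """Per-gene moderated differential-expression results for one contrast.

    ``table`` is indexed by gene with columns log2fc, t, p, fdr.
    """

    table: pd.DataFrame
    stratum: str
    contrast: str
    df_residual: float
    df_prior: float
    var_prior: float
    n_samples: int

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def significant(self, fdr_cut: float = 0.05, fc_cut: float = 1.0) -> pd.Index:
        """Genes with FDR below ``fdr_cut`` and |fold change| >= ``fc_cut``."""
        t = self.table
        mask = (t["fdr"] < fdr_cut) & (t["log2fc"].abs() >= np.log2(fc_cut))
        return t.index[mask]

    def summary(self, top: int = 10) -> str:
        lines = [
            f"Differential expression: stratum={self.stratum}, "
            f"contrast={self.contrast}",
            f"genes={len(self.table)}, samples={self.n_samples}, "
            f"residual df={self.df_residual:.1f}, prior df={self.df_prior:.2f}, "
            f"prior variance={self.var_prior:.4f}",
            f"FDR<0.05: {int((self.table['fdr'] < 0.05).sum())} genes",
            "",
            self.table.sort_values("p").head(top).to_string(
                float_format=lambda v: f"{v:.4g}"
            ),
        ]
        return "\n".join(lines)


def fit_and_moderate(
    y,
    weights: np.ndarray,
    design: pd.DataFrame,
    contrast,
    stratum: str = "combined",
    df_prior: float | None = None,
) -> DEResults:
    """Per-gene weighted least squares with empirical-Bayes moderation.

    ``y`` is the log2-CPM matrix (genes x samples), ``weights`` the
    matching observation weights.  ``contrast`` is a design column name
    or a coefficient vector.  Residual variances are shrunk toward a
    scaled-F prior fitted by moment matching on log variances; the
    moderated t uses residual + prior degrees of freedom.  ``df_prior=0``
    forces ordinary (unmoderated) t-statistics.
    """
    if isinstance(y, pd.DataFrame):
        gene_index = y.index
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        gene_index = pd.RangeIndex(yv.shape[0])
    x = design.to_numpy(dtype=float) if isinstance(design, pd.DataFrame) else np.asarray(design, dtype=float)
    if isinstance(design, pd.DataFrame):
        _check_full_rank(design)
        columns = list(design.columns)
    else:
        columns = [f"x{j}" for j in range(x.shape[1])]
    w = np.asarray(weights, dtype=float)
    if w.shape != yv.shape:
        raise ValueError("weights must match the expression matrix shape")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    n_genes, n_samples = yv.shape
    n_coef = x.shape[1]
    df_res = n_samples - n_coef
    if df_res <= 0:
        raise ValueError("residual degrees of freedom must be positive")

    if isinstance(contrast, str):
        if contrast not in columns:
            raise ValueError(
                f"contrast '{contrast}' not among design columns {columns}"
            )
        cvec = np.zeros(n_coef)
        cvec[columns.index(contrast)] = 1.0
        cname = contrast
    else:
        cvec = np.asarray(contrast, dtype=float)
        if cvec.shape != (n_coef,):
            raise ValueError("contrast vector length must match design columns")
        cname = "custom"

    xtwx = np.einsum("sp,gs,sq->gpq", x, w, x)
    xtwy = np.einsum("sp,gs->gp", x, w * yv)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    fitted = beta @ x.T
    resid = yv - fitted
    s2 = np.einsum("gs,gs->g", w, resid**2) / df_res
    covu = np.linalg.inv(xtwx)
    c_var = np.einsum("p,gpq,q->g", cvec, covu, cvec)

    s2_post, var_prior, d0 = squeeze_variances(s2, df_res, df_prior=df_prior)
    coef = beta @ cvec
    se = np.sqrt(s2_post * c_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, coef / np.where(se > 0, se, 1.0), 0.0)
    df_total = df_res + d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tval))
    else:
        p = 2.0 * stats.t.sf(np.abs(tval), df_total)
    table = pd.DataFrame(
        {
            "log2fc": coef,
            "t": tval,
            "p": p,
            "fdr": benjamini_hochberg(p),
        },
        index=gene_index,
    )
    return DEResults(
        table=table,
        stratum=stratum,
        contrast=cname,
        df_residual=float(df_res),
        df_prior=float(d0),
        var_prior=float(var_prior),
        n_samples=n_samples,
    )


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return benjamini_hochberg(np.asarray(p, dtype=float))


def build_design(meta: pd.DataFrame, stratum: str = "combined") -> pd.DataFrame:
    """0/1-coded design matrix for the trial linear model.

    ``combined`` fits intercept + arm + anti_tnf + location + visit +
    arm:visit; the location-restricted strata drop the location column
    (the caller subsets samples); ``active_vs_inactive`` fits intercept +
    activity + location + anti_tnf on screening samples.
    """
    d = pd.DataFrame(index=meta.index)
    d["intercept"] = 1.0
    if stratum == "active_vs_inactive":
        d["activity"] = (meta["activity"] == "active").astype(float)
        d["location"] = (meta["location"] == "ileum").astype(float)
        d["anti_tnf"] = (meta["anti_tnf"] == "yes").astype(float)
        return d
    d["arm"] = (meta["arm"] == "treatment").astype(float)
    d["anti_tnf"] = (meta["anti_tnf"] == "yes").astype(float)
    if stratum == "combined":
        d["location"] = (meta["location"] == "ileum").astype(float)
    elif stratum not in ("colon_only", "ileum_only"):
        raise ValueError(f"unknown stratum '{stratum}'")
    d["visit"] = (meta["visit"] == "week14").astype(float)
    d["arm_visit"] = d["arm"] * d["visit"]
    return d


class DifferentialExpressionModel:
    """Precision-weighted linear model for bulk RNA-seq counts.

    Parameters
    ----------
    counts : DataFrame
        Filtered genes x samples raw counts.
    design : DataFrame
        Samples x coefficients design matrix (full rank).
    span : float
        Lowess span for the mean-variance trend.
    """

    def __init__(self, counts: pd.DataFrame, design: pd.DataFrame, span: float = 0.5):
        if list(counts.columns) != list(design.index):
            raise ValueError("counts columns and design rows must match")
        _check_full_rank(design)
        self.counts = counts
        self.design = design
        self.span = span
        self.stratum = "combined"
        self._y: pd.DataFrame | None = None
        self._weights: np.ndarray | None = None

    @classmethod
    def from_study(
        cls,
        study: BulkStudy,
        stratum: str = "combined",
        min_reads: int = 10,
        min_samples: int = 31,
        restrict_to_active_screening: bool = False,
        span: float = 0.5,
    ) -> "DifferentialExpressionModel":
        """Build the stratum-specific model from a trial study.

        ``restrict_to_active_screening`` applies the clinical inclusion
        rule: only patients with a complete pair whose screening biopsy
        was endoscopically active.
        """
        meta = study.meta
        keep = pd.Series(True, index=meta.index)
        if stratum == "colon_only":
            keep &= meta["location"] == "colon"
        elif stratum == "ileum_only":
            keep &= meta["location"] == "ileum"
        elif stratum == "active_vs_inactive":
            keep &= meta["visit"] == "screening"
        if restrict_to_active_screening and stratum != "active_vs_inactive":
            pairs, _ = study.pairs()
            active_scr = pairs["screening"][
                meta.loc[pairs["screening"], "activity"].to_numpy() == "active"
            ]
            ok_patients = set(pairs.loc[pairs["screening"].isin(active_scr), "patient_id"])
            keep &= meta["patient_id"].isin(ok_patients)
        sub = study.subset_samples(list(meta.index[keep]))
        if stratum == "active_vs_inactive":
            if sub.meta["activity"].nunique() < 2:
                raise ValueError(
                    "activity is constant across screening samples"
                )
        genes = filter_genes(sub.counts, min_reads, min_samples)
        design = build_design(sub.meta, stratum)
        model = cls(sub.counts.loc[genes], design, span=span)
        model.stratum = stratum
        return model

    def transform(self) -> tuple[pd.DataFrame, np.ndarray]:
        """log2-CPM and voom-style precision weights (cached)."""
        if self._y is None:
            y, w = voom_weights(self.counts, self.design, span=self.span)
            self._y = pd.DataFrame(
                y, index=self.counts.index, columns=self.counts.columns
            )
            self._weights = w
        return self._y, self._weights

    def fit(self, contrast: str | np.ndarray | None = None, df_prior=None) -> DEResults:
        if contrast is None:
            contrast = (
                "activity" if "activity" in self.design.columns else "arm_visit"
            )
        y, w = self.transform()
        return fit_and_moderate(
            y, w, self.design, contrast, stratum=self.stratum, df_prior=df_prior
        )


def call_treatment_modulated(
    combined: DEResults,
    colon: DEResults,
    ileum: DEResults,
    fc_cut: float = 1.5,
    fdr_cut: float = 0.05,
    nominal_cut: float = 0.05,
) -> pd.Index:
    """Genes significantly modulated by treatment under the three clauses:
    |fold change| >= fc_cut and FDR < fdr_cut in the combined analysis,
    and unadjusted p < nominal_cut in both location-restricted analyses.
    """
    universe = combined.table.index
    for other in (colon, ileum):
        if set(other.table.index) != set(universe):
            raise ValueError("gene universes of the three analyses differ")
    ct = combined.table
    mask = (
        (ct["log2fc"].abs() >= np.log2(fc_cut))
        & (ct["fdr"] < fdr_cut)
        & (colon.table.loc[universe, "p"] < nominal_cut)
        & (ileum.table.loc[universe, "p"] < nominal_cut)
    )
    return universe[mask]


def de_active_vs_inactive(
    study: BulkStudy,
    min_reads: int = 10,
    min_samples: int = 31,
    span: float = 0.5,
) -> DEResults:
    """Active-vs-inactive differential expression on screening biopsies
    only, adjusting for location and prior anti-TNF status.  Week-14
    samples are excluded before any computation (including the gene
    filter), so their content cannot influence the result."""
    scr = study.meta.index[study.meta["visit"] == "screening"]
    if len(scr) == 0:
        raise ValueError("no screening samples present")
    sub = study.subset_samples(list(scr))
    n_active = int((sub.meta["activity"] == "active").sum())
    n_inactive = int((sub.meta["activity"] == "inactive").sum())
    if n_active < 2 or n_inactive < 2:
        raise ValueError(
            "need at least 2 active and 2 inactive screening samples"
        )
    genes = filter_genes(sub.counts, min_reads, min_samples)
    design = build_design(sub.meta, "active_vs_inactive")
    model = DifferentialExpressionModel(sub.counts.loc[genes], design, span=span)
    model.stratum = "active_vs_inactive"
    return model.fit("activity")
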