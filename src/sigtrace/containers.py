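"""In-memory containers for single-cell and trial bulk RNA-seq data."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

ARM_LEVELS = ("placebo", "treatment")
VISIT_LEVELS = ("screening", "week14")
LOCATION_LEVELS = ("colon", "ileum")
ACTIVITY_LEVELS = ("active", "inactive")
ANTI_TNF_LEVELS = ("yes", "no")

#: Required bulk metadata columns (sample_id is the index on read).
META_COLUMNS = (
    "sample_id",
    "patient_id",
    "arm",
    "visit",
    "location",
    "activity",
    "anti_tnf",
)


class SigtraceError(Exception):
    """Base class for package errors."""


class ConfigurationError(SigtraceError, ValueError):
    """Invalid simulation or pipeline configuration."""


class MetadataError(SigtraceError, ValueError):
    """Invalid or inconsistent sample metadata."""


@dataclass
class CellMatrix:
    """Sparse UMI count matrix (genes x barcodes) with gene/mito annotation.

    ``counts`` holds non-negative integer exonic UMI counts; ``mito_flags``
    marks mitochondrial genes (one flag per gene); ``donor`` labels each
    barcode with its donor of origin.
    """

    counts: sp.spmatrix
    gene_ids: list[str]
    barcode_ids: list[str]
    mito_flags: np.ndarray
    donor: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.barcode_ids = list(self.barcode_ids)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        self.donor = np.asarray(self.donor, dtype=object)
        n_genes, n_barcodes = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.barcode_ids) != n_barcodes:
            raise ValueError("barcode_ids length does not match matrix columns")
        if self.mito_flags.shape != (n_genes,):
            raise ValueError("mito_flags must have one entry per gene")
        if self.donor.shape != (n_barcodes,):
            raise ValueError("donor must have one entry per barcode")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[1]

    def umi_totals(self) -> np.ndarray:
        """Total UMIs per barcode."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def mito_fractions(self) -> np.ndarray:
        """Fraction of UMIs from mitochondrial genes per barcode (0 if empty)."""
        totals = self.umi_totals()
        mito = np.asarray(self.counts[self.mito_flags, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        return frac

    def subset_barcodes(self, mask: np.ndarray) -> "CellMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellMatrix(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            barcode_ids=[self.barcode_ids[i] for i in idx],
            mito_flags=self.mito_flags,
            donor=self.donor[idx],
        )


def build_pairs(meta: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Complete screening/week-14 pairs sharing patient and location.

    Returns a DataFrame with columns (patient_id, location, arm,
    screening, week14) and a list of sample_ids that could not be
    paired.  Duplicate visits for one patient+location raise
    ``MetadataError``.
    """
    rows = []
    unpaired: list[str] = []
    for (patient, loc), grp in meta.groupby(["patient_id", "location"], sort=True):
        scr = grp.index[grp["visit"] == "screening"]
        wk = grp.index[grp["visit"] == "week14"]
        if len(scr) > 1 or len(wk) > 1:
            raise MetadataError(
                f"duplicate visit samples for patient {patient} at {loc}"
            )
        if len(scr) == 1 and len(wk) == 1:
            rows.append(
                {
                    "patient_id": patient,
                    "location": loc,
                    "arm": grp["arm"].iloc[0],
                    "screening": scr[0],
                    "week14": wk[0],
                }
            )
        else:
            unpaired.extend(list(scr) + list(wk))
    pairs = pd.DataFrame(
        rows, columns=["patient_id", "location", "arm", "screening", "week14"]
    )
    return pairs, unpaired


def _check_levels(series: pd.Series, levels: tuple[str, ...], name: str) -> None:
    bad = set(series.unique()) - set(levels)
    if bad:
        raise MetadataError(f"column '{name}' has invalid levels: {sorted(bad)}")


@dataclass
class BulkStudy:
    """Bulk RNA-seq counts (genes x samples) plus per-sample trial metadata.

    ``meta`` is indexed by sample_id with columns patient_id, arm, visit,
    location, activity and anti_tnf; its index must match the columns of
    ``counts`` exactly (same order).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        required = set(META_COLUMNS) - {"sample_id"}
        missing = required - set(self.meta.columns)
        if missing:
            raise MetadataError(f"metadata is missing columns: {sorted(missing)}")
        if list(self.counts.columns) != list(self.meta.index):
            raise MetadataError("counts columns and metadata sample_ids differ")
        _check_levels(self.meta["arm"], ARM_LEVELS, "arm")
        _check_levels(self.meta["visit"], VISIT_LEVELS, "visit")
        _check_levels(self.meta["location"], LOCATION_LEVELS, "location")
        _check_levels(self.meta["activity"], ACTIVITY_LEVELS, "activity")
        _check_levels(self.meta["anti_tnf"], ANTI_TNF_LEVELS, "anti_tnf")
        if (np.asarray(self.counts.values) < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def pairs(self) -> tuple[pd.DataFrame, list[str]]:
        """Complete screening/week-14 pairs sharing patient and location.

        See :func:`build_pairs`.
        """
        return build_pairs(self.meta)

    def subset_samples(self, sample_ids: list[str]) -> "BulkStudy":
        return BulkStudy(
            counts=self.counts[sample_ids], meta=self.meta.loc[sample_ids]
        )


@dataclass
class SignatureSet:
    """Named ordered gene lists (max 50 genes each) with optional effect sizes."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    effects: dict[str, list[float]] = field(default_factory=dict)
    max_genes: int = 50

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) > self.max_genes:
                raise ValueError(
                    f"signature '{name}' exceeds {self.max_genes} genes"
                )
            if len(set(genes)) != len(genes):
                raise ValueError(f"signature '{name}' contains duplicate genes")
            eff = self.effects.get(name)
            if eff is not None and len(eff) != len(genes):
                raise ValueError(
                    f"signature '{name}' effects length mismatch"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes(self, name: str) -> list[str]:
        return list(self.sets[name])

    def add(self, name: str, genes: list[str], effects=None) -> None:
        if len(genes) > self.max_genes:
            raise ValueError(f"signature '{name}' exceeds {self.max_genes} genes")
        seen: set[str] = set()
        deduped, deduped_eff = [], []
        for i, g in enumerate(genes):
            if g in seen:
                warnings.warn(
                    f"signature '{name}': duplicate gene '{g}' removed",
                    stacklevel=2,
                )
                continue
            seen.add(g)
            deduped.append(g)
            if effects is not None:
                deduped_eff.append(float(effects[i]))
        self.sets[name] = deduped
        if effects is not None:
            self.effects[name] = deduped_eff
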