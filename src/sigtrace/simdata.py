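"""Synthetic single-cell and trial-structured bulk RNA-seq generators.

Both modalities draw negative-binomial counts from shared cell-type
expression programs so that every downstream stage (QC, clustering,
marker discovery, signature scoring, treatment-effect modelling,
activity concordance) can be exercised against known ground truth.

The trial generator emulates a 1:4-randomized two-arm study with paired
screening / week-14 biopsies from the same bowel segment.  Treatment
multiplies the target cell type's mixture proportion by ``effect_size``
at week 14 and suppresses the latent segment severity (which drives the
planted inflammation program) by the same factor, so a planted cellular
effect and a planted activity-concordant effect co-occur, as they would
if the target population drove the inflammation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import BulkStudy, CellMatrix, ConfigurationError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_single_cell",
    "simulate_trial",
    "write_fixture",
    "default_type_names",
    "segment_score",
    "activity_from_score",
]

#: Expected UMI depth of a viable cell (scaled by the per-cell lognormal factor).
SC_CELL_DEPTH = 6000.0
#: Depth multiplier for planted low-UMI barcodes.
LOW_UMI_FACTOR = 0.2
#: Mitochondrial UMI share for viable cells / planted high-mito barcodes.
MITO_SHARE_GOOD = 0.03
MITO_SHARE_BAD = 0.25

_T_SUBTYPES = ["CD8_IEL", "CD8_LP", "CD4_Th", "CD4_Treg", "MAIT"]


def default_type_names(n: int) -> list[str]:
    """Cell-type names: T-cell subtype names first, then generic labels."""
    names = _T_SUBTYPES[:n]
    names += [f"Tsub_{i}" for i in range(len(names), n)]
    return names


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults define a 5-subtype single-cell experiment (40 markers per
    type at 8-fold) and a 100-patient 1:4-randomized trial in which
    treatment halves the CD8_IEL proportion at week 14.
    """

    n_cell_types: int = 5
    n_genes: int = 2000
    n_markers_per_type: int = 40
    marker_fold_change: float = 8.0
    nb_dispersion: float = 0.1
    cells_per_type: int = 200
    frac_low_quality_barcodes: float = 0.10
    mito_gene_count: int = 20
    n_patients: int = 100
    randomization_ratio: tuple[int, int] = (1, 4)
    effect_size: float = 0.5
    target_cell_type: str = "CD8_IEL"
    n_activity_genes: int = 100
    activity_fold_change: float = 3.0
    library_size_log_mean: float = math.log(2e6)
    library_size_log_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cell_types",
            "n_genes",
            "n_markers_per_type",
            "cells_per_type",
            "mito_gene_count",
            "n_patients",
            "n_activity_genes",
        ):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in ("marker_fold_change", "nb_dispersion", "activity_fold_change"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.frac_low_quality_barcodes < 1.0:
            raise ConfigurationError("frac_low_quality_barcodes must be in [0, 1)")
        if not 0.0 < self.effect_size <= 1.0:
            raise ConfigurationError("effect_size must lie in (0, 1]")
        self.randomization_ratio = (
            int(self.randomization_ratio[0]),
            int(self.randomization_ratio[1]),
        )
        if min(self.randomization_ratio) <= 0:
            raise ConfigurationError("randomization_ratio parts must be positive")
        if self.n_markers_per_type * self.n_cell_types > self.n_genes:
            raise ConfigurationError(
                "n_markers_per_type * n_cell_types exceeds n_genes"
            )
        if (
            self.n_markers_per_type * self.n_cell_types
            + self.n_activity_genes
            + self.mito_gene_count
            > self.n_genes
        ):
            raise ConfigurationError(
                "markers + activity genes + mitochondrial genes exceed n_genes"
            )
        if self.target_cell_type not in self.type_names:
            raise ConfigurationError(
                f"target_cell_type '{self.target_cell_type}' not among "
                f"{self.type_names}"
            )

    @property
    def type_names(self) -> list[str]:
        return default_type_names(self.n_cell_types)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        data = json.loads(text)
        if "randomization_ratio" in data:
            data["randomization_ratio"] = tuple(data["randomization_ratio"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted truth of a simulated dataset (single-cell and/or trial)."""

    true_markers: dict[str, list[str]]
    activity_genes: list[str]
    cell_labels: pd.Series | None = None
    low_quality_barcodes: list[str] = field(default_factory=list)
    sample_proportions: pd.DataFrame | None = None
    treated_delta: pd.Series | None = None
    type_profiles: pd.DataFrame | None = None
    severity: pd.Series | None = None
    segment_scores: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.sample_proportions is not None:
            sums = self.sample_proportions.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("sample proportions must sum to 1 per sample")

    def to_dict(self) -> dict:
        def ser(obj):
            if obj is None:
                return None
            if isinstance(obj, pd.Series):
                return {str(k): v for k, v in obj.items()}
            if isinstance(obj, pd.DataFrame):
                return {
                    "index": [str(i) for i in obj.index],
                    "columns": [str(c) for c in obj.columns],
                    "values": obj.to_numpy().tolist(),
                }
            return obj

        return {
            "true_markers": self.true_markers,
            "activity_genes": list(self.activity_genes),
            "cell_labels": ser(self.cell_labels),
            "low_quality_barcodes": list(self.low_quality_barcodes),
            "sample_proportions": ser(self.sample_proportions),
            "treated_delta": ser(self.treated_delta),
            "type_profiles": ser(self.type_profiles),
            "severity": ser(self.severity),
            "segment_scores": ser(self.segment_scores),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GroundTruth":
        def de_series(obj):
            return None if obj is None else pd.Series(obj)

        def de_frame(obj):
            if obj is None:
                return None
            return pd.DataFrame(
                np.asarray(obj["values"]), index=obj["index"], columns=obj["columns"]
            )

        return cls(
            true_markers={k: list(v) for k, v in data["true_markers"].items()},
            activity_genes=list(data["activity_genes"]),
            cell_labels=de_series(data.get("cell_labels")),
            low_quality_barcodes=list(data.get("low_quality_barcodes", [])),
            sample_proportions=de_frame(data.get("sample_proportions")),
            treated_delta=de_series(data.get("treated_delta")),
            type_profiles=de_frame(data.get("type_profiles")),
            severity=de_series(data.get("severity")),
            segment_scores=de_series(data.get("segment_scores")),
        )


def segment_score(severity: float, location: str) -> int:
    """Map latent severity in [0, 1] to an SES-CD-like segment score."""
    if location == "colon":
        return int(round(12 * severity))
    return int(round(8 * severity))


def activity_from_score(score: float, location: str) -> str:
    """Endoscopic activity rule: colonic score >= 7, ileal score >= 4."""
    if location == "colon":
        return "active" if score >= 7 else "inactive"
    if location == "ileum":
        return "active" if score >= 4 else "inactive"
    raise ValueError(f"unknown location '{location}'")


def _gene_ids(config: SimConfig) -> tuple[list[str], np.ndarray]:
    n_regular = config.n_genes - config.mito_gene_count
    ids = [f"G{i:05d}" for i in range(n_regular)]
    ids += [f"MT-{i + 1}" for i in range(config.mito_gene_count)]
    mito = np.zeros(config.n_genes, dtype=bool)
    mito[n_regular:] = True
    return ids, mito


def _shared_programs(config: SimConfig):
    """Deterministic gene programs shared by both modalities.

    Uses a dedicated RNG stream derived only from ``config.seed`` so that
    the single-cell and trial generators plant identical marker sets,
    activity genes and type expression profiles.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    gene_ids, mito = _gene_ids(config)
    base = rng.lognormal(0.0, 1.0, config.n_genes)
    # pin the mitochondrial share of a baseline cell at MITO_SHARE_GOOD
    non_mito_sum = base[~mito].sum()
    base[mito] *= (
        MITO_SHARE_GOOD / (1 - MITO_SHARE_GOOD) * non_mito_sum / base[mito].sum()
    )
    base /= base.sum()

    candidates = np.flatnonzero(~mito)
    n_mark = config.n_markers_per_type * config.n_cell_types
    special = rng.choice(candidates, size=n_mark + config.n_activity_genes, replace=False)
    marker_idx = special[:n_mark].reshape(config.n_cell_types, config.n_markers_per_type)
    activity_idx = np.sort(special[n_mark:])

    profiles = np.tile(base[:, None], (1, config.n_cell_types))
    for t in range(config.n_cell_types):
        profiles[marker_idx[t], t] *= config.marker_fold_change
    profiles /= profiles.sum(axis=0, keepdims=True)

    names = config.type_names
    true_markers = {
        names[t]: sorted(gene_ids[i] for i in marker_idx[t])
        for t in range(config.n_cell_types)
    }
    activity_genes = sorted(gene_ids[i] for i in activity_idx)
    profile_df = pd.DataFrame(profiles, index=gene_ids, columns=names)
    return gene_ids, mito, profile_df, true_markers, activity_genes, activity_idx


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_single_cell(config: SimConfig) -> tuple[CellMatrix, GroundTruth]:
    """Simulate a droplet single-cell UMI matrix with planted cell types.

    Viable cells draw NB counts around an expected depth of ~6000 UMIs
    with a ~3% mitochondrial share.  A configured fraction of barcodes is
    low quality: half at one-fifth depth (fails the >=2000-UMI rule), half
    with a ~25% mitochondrial share (fails the <8% rule).
    """
    gene_ids, mito, profile_df, true_markers, activity_genes, _ = _shared_programs(
        config
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    names = config.type_names
    profiles = profile_df.to_numpy()

    n_good = config.cells_per_type * config.n_cell_types
    frac = config.frac_low_quality_barcodes
    n_low = int(round(frac / (1.0 - frac) * n_good)) if frac > 0 else 0
    n_low_umi = (n_low + 1) // 2
    n_high_mito = n_low - n_low_umi
    n_cells = n_good + n_low

    type_of = np.repeat(np.arange(config.n_cell_types), config.cells_per_type)
    type_of = np.concatenate(
        [type_of, rng.integers(0, config.n_cell_types, size=n_low)]
    )
    quality = np.array(
        ["good"] * n_good + ["low_umi"] * n_low_umi + ["high_mito"] * n_high_mito,
        dtype=object,
    )

    # per-barcode expected depth
    depth = SC_CELL_DEPTH * np.exp(
        rng.normal(0.0, config.library_size_log_sd, size=n_cells)
    )
    depth[quality == "low_umi"] *= LOW_UMI_FACTOR

    # profile with boosted mitochondrial share for high-mito barcodes
    boosted = profiles.copy()
    mito_share = profiles[mito].sum(axis=0)
    boosted[mito] *= MITO_SHARE_BAD / (1 - MITO_SHARE_BAD) * (
        (1 - mito_share) / mito_share
    )
    boosted /= boosted.sum(axis=0, keepdims=True)

    counts = np.empty((config.n_genes, n_cells), dtype=np.int64)
    for t in range(config.n_cell_types):
        sel = type_of == t
        prof = np.where(
            (quality[sel] == "high_mito")[None, :], boosted[:, [t]], profiles[:, [t]]
        )
        mu = prof * depth[sel][None, :]
        counts[:, sel] = _nb_counts(rng, mu, config.nb_dispersion)

    perm = rng.permutation(n_cells)
    counts = counts[:, perm]
    type_of = type_of[perm]
    quality = quality[perm]

    barcodes = [f"BC{i:05d}" for i in range(n_cells)]
    donors = np.array([f"D{i % 4 + 1}" for i in range(n_cells)], dtype=object)
    matrix = CellMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        barcode_ids=barcodes,
        mito_flags=mito,
        donor=donors,
    )
    truth = GroundTruth(
        true_markers=true_markers,
        activity_genes=activity_genes,
        cell_labels=pd.Series([names[t] for t in type_of], index=barcodes),
        low_quality_barcodes=[
            bc for bc, q in zip(barcodes, quality) if q != "good"
        ],
        type_profiles=profile_df,
    )
    return matrix, truth


def _arm_assignment(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    r_pl, r_tr = config.randomization_ratio
    n = config.n_patients
    n_pl = int(round(n * r_pl / (r_pl + r_tr)))
    n_tr = n - n_pl
    if n_pl < 2 or n_tr < 2:
        raise ConfigurationError(
            "randomization leaves fewer than 2 patients in an arm"
        )
    arms = np.array(["placebo"] * n_pl + ["treatment"] * n_tr, dtype=object)
    return arms[rng.permutation(n)]


def simulate_trial(config: SimConfig) -> tuple[BulkStudy, GroundTruth]:
    """Simulate the paired two-visit, two-location randomized trial.

    Each patient contributes a screening and a week-14 biopsy from the
    same bowel segment.  Bulk expected counts are library_size x mixture
    of cell-type programs; the target type's proportion is multiplied by
    ``effect_size`` at week 14 in the treatment arm only.  Activity
    labels derive from SES-CD-like segment scores (colon >= 7, ileum
    >= 4) computed from a latent severity that is coupled to the
    target-type proportion and likewise suppressed by treatment; the
    planted inflammation program is up-regulated by
    ``activity_fold_change`` in samples labeled active, so resolving
    segments lose it at week 14.
    """
    gene_ids, _, profile_df, true_markers, activity_genes, activity_idx = (
        _shared_programs(config)
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    names = config.type_names
    profiles = profile_df.to_numpy()
    t_idx = names.index(config.target_cell_type)

    n = config.n_patients
    arms = _arm_assignment(rng, config)
    patients = [f"P{i + 1:04d}" for i in range(n)]
    locations = np.array(
        ["colon"] * (n // 2) + ["ileum"] * (n - n // 2), dtype=object
    )[rng.permutation(n)]
    anti_tnf = np.array(
        ["yes" if u < 0.5 else "no" for u in rng.uniform(size=n)], dtype=object
    )

    base_props = np.full(config.n_cell_types, 0.75 / max(config.n_cell_types - 1, 1))
    base_props[t_idx] = 0.25
    if config.n_cell_types == 1:
        base_props = np.array([1.0])
    patient_props = rng.dirichlet(base_props * 60.0, size=n)

    pi_t = base_props[t_idx]
    severity_scr = np.clip(
        patient_props[:, t_idx] / (2.0 * pi_t) + rng.normal(0.0, 0.08, size=n),
        0.02,
        0.98,
    )

    sample_ids, meta_rows = [], []
    prop_rows, severities, scores = [], [], []
    rate_cols = []
    for i in range(n):
        treated = arms[i] == "treatment"
        w14 = float(
            np.clip(
                severity_scr[i] * (config.effect_size if treated else 1.0)
                + rng.normal(0.0, 0.03),
                0.02,
                0.98,
            )
        )
        for visit, sev in (("screening", float(severity_scr[i])), ("week14", w14)):
            props = patient_props[i].copy()
            if visit == "week14" and treated:
                props[t_idx] *= config.effect_size
                props /= props.sum()
            rate = profiles @ props
            score = segment_score(sev, locations[i])
            active = activity_from_score(score, locations[i]) == "active"
            if active:
                rate[activity_idx] *= config.activity_fold_change
            rate /= rate.sum()
            sid = f"{patients[i]}_{'scr' if visit == 'screening' else 'wk14'}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "patient_id": patients[i],
                    "arm": arms[i],
                    "visit": visit,
                    "location": locations[i],
                    "activity": "active" if active else "inactive",
                    "anti_tnf": anti_tnf[i],
                }
            )
            prop_rows.append(props)
            severities.append(sev)
            scores.append(score)
            rate_cols.append(rate)

    lib = np.exp(
        rng.normal(
            config.library_size_log_mean,
            config.library_size_log_sd,
            size=len(sample_ids),
        )
    )
    mu = np.stack(rate_cols, axis=1) * lib[None, :]
    counts = _nb_counts(rng, mu, config.nb_dispersion)

    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    study = BulkStudy(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids), meta=meta
    )
    props_df = pd.DataFrame(prop_rows, index=sample_ids, columns=names)
    treated_delta = pd.Series(
        {
            patients[i]: float(
                props_df.iloc[2 * i + 1, t_idx] - props_df.iloc[2 * i, t_idx]
            )
            for i in range(n)
        }
    )
    truth = GroundTruth(
        true_markers=true_markers,
        activity_genes=activity_genes,
        sample_proportions=props_df,
        treated_delta=treated_delta,
        type_profiles=profile_df,
        severity=pd.Series(severities, index=sample_ids),
        segment_scores=pd.Series(scores, index=sample_ids),
    )
    return study, truth


def write_fixture(dataset, directory) -> list[Path]:
    """Write a simulated dataset (or (dataset, truth) tuple) to disk.

    Delegates to :mod:`sigtrace.io`; single-cell data become MTX +
    barcodes/features TSVs, bulk data counts + metadata TSVs, ground
    truth a JSON file.
    """
    from . import io as _io

    return _io.write_fixture(dataset, directory)
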