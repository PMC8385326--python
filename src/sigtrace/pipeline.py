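"""End-to-end driver: configuration, metadata validation, stage
orchestration and machine-readable run reports."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import bulkstats, concordance, io, markers, scqc, sigscore
from .containers import (
    ACTIVITY_LEVELS,
    ARM_LEVELS,
    ANTI_TNF_LEVELS,
    LOCATION_LEVELS,
    META_COLUMNS,
    MetadataError,
    VISIT_LEVELS,
    build_pairs,
)
from .simdata import (
    SimConfig,
    activity_from_score,
    simulate_single_cell,
    simulate_trial,
)

__all__ = ["PipelineConfig", "PipelineError", "run_all", "validate_metadata"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """All thresholds, seeds and stage parameters of a pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    min_umi: int = 2000
    max_mito: float = 0.08
    k_neighbors: int = 15
    resolution: float = 0.3
    n_pcs: int = 30
    cluster_method: str = "leiden"
    min_markers: int = 30
    min_merge_fold: float = 1.5
    marker_fdr: float = 0.01
    max_signature_genes: int = 50
    min_reads: int = 10
    min_samples: int = 31
    fc_cut: float = 1.5
    de_fdr: float = 0.05
    nominal_cut: float = 0.05
    restrict_to_active_screening: bool = False
    voom_span: float = 0.5
    t_test: str = "welch"
    concordance_mode: str = "all"  # or "significant"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            sim = dict(self.sim)
            if "randomization_ratio" in sim:
                sim["randomization_ratio"] = tuple(sim["randomization_ratio"])
            self.sim = SimConfig(**sim)
        for name in ("min_umi", "k_neighbors", "min_markers", "min_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("max_mito", "marker_fdr", "de_fdr", "nominal_cut"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.fc_cut < 1 or self.min_merge_fold < 1:
            raise ValueError("fold-change cuts must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def validate_metadata(
    meta: pd.DataFrame, segment_scores: pd.Series | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize and validate trial metadata; returns (meta, pairs).

    Categorical levels are lower-cased and checked; when SES-CD-like
    segment scores are provided (argument or a ``ses_cd`` column),
    activity is recomputed from the endoscopic rule (colonic score >= 7,
    ileal score >= 4) and contradictions with provided labels raise an
    error listing the offending samples.
    """
    meta = meta.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    required = [c for c in META_COLUMNS if c != "sample_id"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise MetadataError(f"metadata is missing columns: {missing}")
    for col in ("arm", "visit", "location", "activity", "anti_tnf"):
        meta[col] = meta[col].astype(str).str.strip().str.lower()
    levels = {
        "arm": ARM_LEVELS,
        "visit": VISIT_LEVELS,
        "location": LOCATION_LEVELS,
        "activity": ACTIVITY_LEVELS,
        "anti_tnf": ANTI_TNF_LEVELS,
    }
    for col, lv in levels.items():
        bad = set(meta[col]) - set(lv)
        if bad:
            raise MetadataError(f"column '{col}' has invalid levels: {sorted(bad)}")
    if segment_scores is None and "ses_cd" in meta.columns:
        segment_scores = meta["ses_cd"].astype(float)
        meta = meta.drop(columns="ses_cd")
    if segment_scores is not None:
        derived = pd.Series(
            [
                activity_from_score(float(segment_scores[s]), meta.loc[s, "location"])
                for s in meta.index
            ],
            index=meta.index,
        )
        clash = meta.index[meta["activity"] != derived]
        if len(clash):
            raise MetadataError(
                "provided activity contradicts the segment-score rule for "
                f"samples: {list(clash)}"
            )
        meta["activity"] = derived
    pairs, _ = build_pairs(meta)
    return meta, pairs


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run the full chain on simulated data and write all artifacts.

    Emits fixtures, cluster labels, marker tables, GMT signatures, DE
    tables for every stratum, the three-clause treatment call, signature
    score and arm-comparison tables, concordance summaries and a JSON
    run report with all thresholds, seeds and exclusion logs.  Outputs
    are deterministic for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": json.loads(config.to_json()),
        "exclusions": {},
        "stages": {},
    }

    sim = config.sim

    @_stage("simulate")
    def do_simulate():
        cells, sc_truth = simulate_single_cell(sim)
        study, trial_truth = simulate_trial(sim)
        io.write_fixture((cells, sc_truth), outdir / "sc")
        io.write_fixture((study, trial_truth), outdir / "bulk")
        return cells, sc_truth, study, trial_truth

    cells, sc_truth, study, trial_truth = do_simulate()

    @_stage("scqc")
    def do_scqc():
        filtered, qc = scqc.qc_filter_barcodes(cells, config.min_umi, config.max_mito)
        norm = scqc.normalize_cells(filtered)
        labels = scqc.cluster_cells(
            norm,
            k_neighbors=config.k_neighbors,
            resolution=config.resolution,
            seed=config.seed,
            donors=filtered.donor,
            n_pcs=config.n_pcs,
            method=config.cluster_method,
        )
        labels = scqc.merge_small_clusters(
            norm, labels, config.min_markers, config.min_merge_fold
        )
        pd.DataFrame(
            {"barcode": filtered.barcode_ids, "cluster": labels}
        ).to_csv(outdir / "labels.tsv", sep="\t", index=False)
        report["stages"]["scqc"] = {
            "n_input_barcodes": qc.n_input,
            "n_kept_barcodes": qc.n_kept,
            "n_low_umi": qc.n_low_umi,
            "n_high_mito": qc.n_high_mito,
            "n_clusters": int(np.unique(labels).size),
        }
        report["exclusions"]["barcodes_failed_qc"] = {
            "reason": "low_umi_or_high_mito",
            "count": qc.n_removed,
        }
        return filtered, norm, labels

    filtered, norm, labels = do_scqc()

    @_stage("markers")
    def do_markers():
        table = markers.marker_table(norm, labels, filtered.gene_ids)
        table.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sigs = markers.build_all_signatures(
                table, config.max_signature_genes, config.marker_fdr
            )
        io.write_gmt(sigs, outdir / "signatures.gmt")
        report["stages"]["markers"] = {
            "n_signatures": len(sigs),
            "signature_sizes": {n: len(sigs.genes(n)) for n in sigs},
        }
        return sigs

    sigs = do_markers()

    @_stage("de")
    def do_de():
        results = {}
        for stratum in ("combined", "colon_only", "ileum_only"):
            model = bulkstats.DifferentialExpressionModel.from_study(
                study,
                stratum=stratum,
                min_reads=config.min_reads,
                min_samples=config.min_samples,
                restrict_to_active_screening=config.restrict_to_active_screening,
                span=config.voom_span,
            )
            res = model.fit("arm_visit")
            res.table.rename_axis("gene").to_csv(
                outdir / f"de_{stratum}.tsv", sep="\t"
            )
            results[stratum] = res
        activity = bulkstats.de_active_vs_inactive(
            study, config.min_reads, config.min_samples, span=config.voom_span
        )
        activity.table.rename_axis("gene").to_csv(
            outdir / "de_active_vs_inactive.tsv", sep="\t"
        )
        shared = results["combined"].table.index
        shared = shared.intersection(results["colon_only"].table.index)
        shared = shared.intersection(results["ileum_only"].table.index)
        trimmed = {
            k: bulkstats.DEResults(
                table=v.table.loc[shared],
                stratum=v.stratum,
                contrast=v.contrast,
                df_residual=v.df_residual,
                df_prior=v.df_prior,
                var_prior=v.var_prior,
                n_samples=v.n_samples,
            )
            for k, v in results.items()
        }
        called = bulkstats.call_treatment_modulated(
            trimmed["combined"],
            trimmed["colon_only"],
            trimmed["ileum_only"],
            config.fc_cut,
            config.de_fdr,
            config.nominal_cut,
        )
        pd.Series(called, name="gene").to_csv(
            outdir / "treatment_modulated_genes.tsv", sep="\t", index=False
        )
        report["stages"]["de"] = {
            "n_genes_combined": int(len(results["combined"].table)),
            "n_treatment_modulated": int(len(called)),
        }
        return results, activity, called

    de_results, activity_res, called = do_de()

    @_stage("score")
    def do_score():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, comp = sigscore.score_all_signatures(study, sigs, kind=config.t_test)
        table.scores.rename_axis("sample_id").to_csv(outdir / "scores.tsv", sep="\t")
        comp.table.to_csv(outdir / "arm_comparison.tsv", sep="\t", index=False)
        report["stages"]["score"] = {
            "n_signatures": int(len(comp.table)),
            "min_fdr": float(comp.table["fdr"].min()),
        }
        report["exclusions"]["unpaired_samples"] = {
            "reason": "missing_visit_partner",
            "samples": table.excluded,
        }
        return table, comp

    score_table, arm_comp = do_score()

    @_stage("concordance")
    def do_concord():
        out = {}
        for arm in ("treatment", "placebo"):
            fc = concordance.build_fold_change_pairs(
                study,
                arm=arm,
                activity=activity_res,
                min_reads=config.min_reads,
                min_samples=config.min_samples,
            )
            fc.rename_axis("gene").to_csv(
                outdir / f"concordance_{arm}.tsv", sep="\t"
            )
            subset = None
            if config.concordance_mode == "significant":
                subset = called
            r, p, n = concordance.correlate_changes(fc, gene_subset=subset)
            out[arm] = {"r": r, "p": p, "n": n}
        (outdir / "concordance.json").write_text(
            json.dumps(out, indent=2, sort_keys=True)
        )
        report["stages"]["concordance"] = out
        return out

    do_concord()

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
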