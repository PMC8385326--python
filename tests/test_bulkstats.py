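"""Bulk differential-expression tests: transforms, filters, weights,
moderated fits, the three-clause call, and an independent R/limma oracle."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from sigtrace import SimConfig, simulate_trial
from sigtrace.bulkstats import (
    DEResults,
    DifferentialExpressionModel,
    adjust_bh,
    call_treatment_modulated,
    cpm,
    de_active_vs_inactive,
    filter_genes,
    fit_and_moderate,
    log2cpm,
    voom_weights,
)

from conftest import small_sim_config


class TestCPM:
    def test_definition(self):
        out = cpm(np.array([[10.0]]), np.array([1e6]))
        assert out[0, 0] == 10.0

    def test_scale_invariance(self, rng):
        counts = rng.poisson(50.0, size=(20, 4)).astype(float)
        lib = counts.sum(axis=0)
        np.testing.assert_allclose(
            cpm(counts, lib), cpm(counts * 2, lib * 2), atol=1e-9
        )

    def test_zero_count_zero_cpm(self):
        assert cpm(np.array([[0.0]]), np.array([100.0]))[0, 0] == 0.0

    def test_zero_library_raises(self):
        with pytest.raises(ValueError, match="positive"):
            cpm(np.array([[1.0]]), np.array([0.0]))

    def test_log2cpm_pseudocounts(self):
        counts = np.array([[4.0], [6.0]])
        out = log2cpm(counts)
        assert out[0, 0] == pytest.approx(np.log2(4.5 / 11.0 * 1e6))


class TestFilterGenes:
    def test_boundaries(self):
        n = 100
        counts = np.zeros((3, n))
        counts[0, :32] = 11   # 11 reads in 32 samples -> kept
        counts[1, :] = 10     # 10 reads everywhere -> dropped (strict > 10)
        counts[2, :31] = 11   # 11 reads in exactly 31 samples -> dropped
        kept = filter_genes(counts, min_reads=10, min_samples=31)
        np.testing.assert_array_equal(kept, [0])

    def test_dataframe_returns_index(self):
        df = pd.DataFrame(np.full((2, 40), 20.0), index=["a", "b"])
        assert list(filter_genes(df)) == ["a", "b"]


class TestAdjustBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)


def _design(n):
    half = n // 2
    return pd.DataFrame(
        {"intercept": 1.0, "group": [0.0] * half + [1.0] * (n - half)},
        index=range(n),
    )


class TestVoomWeights:
    def test_flat_trend_gives_near_unit_weight_ratio(self, rng):
        """Homoskedastic log-scale data: all genes share one mean, so the
        fitted trend is flat and weights become nearly constant."""
        n, g = 40, 500
        y = rng.normal(10.0, 0.2, size=(g, n))
        counts = np.rint(2.0**y)
        _, w = voom_weights(counts, _design(n))
        assert w.max() / w.min() < 1.5

    def test_decreasing_sd_trend_weights_increase_with_abundance(self, rng):
        """NB counts: log-CPM sd falls with abundance, so high-count genes
        earn larger precision weights."""
        n, g = 40, 400
        mu = np.geomspace(5, 5000, g)
        counts = rng.poisson(
            rng.gamma(1 / 0.2, mu[:, None] * 0.2, size=(g, n))
        )
        _, w = voom_weights(counts, _design(n))
        mean_w = w.mean(axis=1)
        r = np.corrcoef(np.log(mu), mean_w)[0, 1]
        assert r > 0.5

    def test_single_gene_unit_weights_with_warning(self):
        counts = np.full((1, 10), 50.0)
        with pytest.warns(UserWarning, match="degenerate"):
            y, w = voom_weights(counts, _design(10))
        np.testing.assert_array_equal(w, 1.0)

    def test_rank_deficient_design_names_aliased_column(self):
        design = _design(10)
        design["dup"] = design["group"]
        with pytest.raises(ValueError, match="dup"):
            voom_weights(np.full((5, 10), 20.0), design)


class TestFitAndModerate:
    def test_unit_weights_match_ols(self, rng):
        """With unit weights the per-gene fit equals ordinary least
        squares (closed form) and df_prior=0 gives the ordinary t."""
        n, g = 16, 30
        design = _design(n)
        x = design.to_numpy()
        y = rng.normal(size=(g, n)) + rng.normal(size=(g, 1))
        res = fit_and_moderate(y, np.ones_like(y), design, "group", df_prior=0)
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = y @ x @ xtx_inv.T
        resid = y - beta @ x.T
        s2 = (resid**2).sum(axis=1) / (n - 2)
        t_manual = beta[:, 1] / np.sqrt(s2 * xtx_inv[1, 1])
        np.testing.assert_allclose(res.table["log2fc"], beta[:, 1], atol=1e-10)
        np.testing.assert_allclose(res.table["t"], t_manual, atol=1e-10)

    def test_moderated_variance_is_convex_combination(self, rng):
        """Each posterior variance lies between the raw per-gene variance
        and the fitted prior, so the moderated |t| brackets the raw |t|
        accordingly."""
        n, g = 10, 200
        design = _design(n)
        x = design.to_numpy()
        y = rng.normal(size=(g, n)) * rng.uniform(0.5, 2.0, size=(g, 1))
        plain = fit_and_moderate(y, np.ones_like(y), design, "group", df_prior=0)
        mod = fit_and_moderate(y, np.ones_like(y), design, "group")
        assert 0 < mod.df_prior < np.inf
        # recover raw and posterior variances from the t statistics
        xtx_inv = np.linalg.inv(x.T @ x)
        coef = plain.table["log2fc"].to_numpy()
        s2_raw = (coef / plain.table["t"].to_numpy()) ** 2 / xtx_inv[1, 1]
        s2_post = (coef / mod.table["t"].to_numpy()) ** 2 / xtx_inv[1, 1]
        lo = np.minimum(s2_raw, mod.var_prior) - 1e-10
        hi = np.maximum(s2_raw, mod.var_prior) + 1e-10
        assert np.all((s2_post >= lo) & (s2_post <= hi))

    def test_null_p_values_roughly_uniform(self, rng):
        n, g = 40, 2000
        design = _design(n)
        y = rng.normal(size=(g, n))
        res = fit_and_moderate(y, np.ones_like(y), design, "group")
        frac = (res.table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_interaction_recovered(self):
        """log2FC=1 planted in 5% of genes on the arm-by-visit interaction
        is recovered at >=80% sensitivity at FDR < 0.05."""
        cfg = SimConfig(seed=3, effect_size=1.0)
        study, _ = simulate_trial(cfg)
        rng = np.random.default_rng(0)
        planted = rng.choice(study.counts.index, size=100, replace=False)
        boost = study.meta.index[
            (study.meta["arm"] == "treatment") & (study.meta["visit"] == "week14")
        ]
        counts = study.counts.copy()
        counts.loc[planted, boost] = (counts.loc[planted, boost] * 2).astype(int)
        study2 = type(study)(counts=counts, meta=study.meta)
        res = DifferentialExpressionModel.from_study(study2).fit("arm_visit")
        hits = res.table.loc[planted, "fdr"] < 0.05
        assert hits.mean() >= 0.8
        assert res.table.loc[planted, "log2fc"].median() == pytest.approx(1.0, abs=0.15)

    def test_bad_contrast_raises(self, rng):
        design = _design(8)
        y = rng.normal(size=(5, 8))
        with pytest.raises(ValueError, match="contrast"):
            fit_and_moderate(y, np.ones_like(y), design, "nope")


class TestTreatmentCall:
    @staticmethod
    def result_with(log2fc, fdr, p, genes=("g1",)):
        table = pd.DataFrame(
            {"log2fc": log2fc, "t": 1.0, "p": p, "fdr": fdr},
            index=list(genes),
        )
        return DEResults(table, "combined", "arm_visit", 10, 2, 1.0, 20)

    def test_three_clauses(self):
        combined = self.result_with([np.log2(1.6)], [0.03], [0.001])
        colon = self.result_with([0.5], [0.2], [0.01])
        ileum = self.result_with([0.5], [0.2], [0.04])
        assert list(call_treatment_modulated(combined, colon, ileum)) == ["g1"]

    def test_fold_change_clause(self):
        combined = self.result_with([np.log2(1.4)], [0.03], [0.001])
        colon = self.result_with([0.5], [0.2], [0.01])
        ileum = self.result_with([0.5], [0.2], [0.04])
        assert len(call_treatment_modulated(combined, colon, ileum)) == 0

    def test_nominal_clause_in_both_locations(self):
        combined = self.result_with([np.log2(1.6)], [0.03], [0.001])
        colon = self.result_with([0.5], [0.2], [0.01])
        ileum = self.result_with([0.5], [0.2], [0.06])
        assert len(call_treatment_modulated(combined, colon, ileum)) == 0

    def test_negative_fold_change_counts_as_absolute(self):
        combined = self.result_with([-np.log2(1.6)], [0.03], [0.001])
        colon = self.result_with([0.5], [0.2], [0.01])
        ileum = self.result_with([0.5], [0.2], [0.04])
        assert list(call_treatment_modulated(combined, colon, ileum)) == ["g1"]

    def test_differing_universes_raise(self):
        combined = self.result_with([1.0], [0.01], [0.001], genes=("g1",))
        other = self.result_with([1.0], [0.01], [0.001], genes=("g2",))
        with pytest.raises(ValueError, match="universes"):
            call_treatment_modulated(combined, other, other)


class TestActiveVsInactive:
    def test_week14_content_cannot_influence_result(self):
        cfg = small_sim_config()
        study, _ = simulate_trial(cfg)
        res = de_active_vs_inactive(study, min_samples=10)
        poisoned = study.counts.copy()
        wk14 = study.meta.index[study.meta["visit"] == "week14"]
        poisoned[wk14] = 999999
        study2 = type(study)(counts=poisoned, meta=study.meta)
        res2 = de_active_vs_inactive(study2, min_samples=10)
        pd.testing.assert_frame_equal(res.table, res2.table)

    def test_planted_activity_genes_recovered(self):
        cfg = small_sim_config(
            n_patients=60, activity_fold_change=2.0, effect_size=1.0, seed=4
        )
        study, truth = simulate_trial(cfg)
        res = de_active_vs_inactive(study, min_samples=20)
        sub = res.table.loc[res.table.index.intersection(truth.activity_genes)]
        assert (sub["log2fc"] > 0).mean() > 0.9
        assert (sub["fdr"] < 0.05).mean() > 0.5

    def test_confounded_activity_location_raises(self):
        cfg = small_sim_config()
        study, _ = simulate_trial(cfg)
        meta = study.meta.copy()
        scr = meta["visit"] == "screening"
        meta.loc[scr, "activity"] = np.where(
            meta.loc[scr, "location"] == "colon", "active", "inactive"
        )
        study2 = type(study)(counts=study.counts, meta=meta)
        with pytest.raises(ValueError, match="aliased|rank"):
            de_active_vs_inactive(study2, min_samples=10)

    def test_requires_both_activity_levels(self):
        cfg = small_sim_config()
        study, _ = simulate_trial(cfg)
        meta = study.meta.copy()
        meta["activity"] = "active"
        study2 = type(study)(counts=study.counts, meta=meta)
        with pytest.raises(ValueError, match="active"):
            de_active_vs_inactive(study2, min_samples=10)


def test_matches_r_limma_voom(tmp_path, rng):
    """Independent oracle: the full voom + moderated-fit chain agrees with
    R limma's voom/lmFit/eBayes on an NB dataset."""
    n_genes, n = 300, 24
    mu = rng.lognormal(4, 1.5, n_genes)
    design = _design(n)
    x = design.to_numpy()
    beta = np.zeros(n_genes)
    beta[:30] = rng.normal(0, 1, 30)
    mean = mu[:, None] * 2 ** (beta[:, None] * x[:, 1][None, :])
    counts = rng.poisson(rng.gamma(1 / 0.15, mean * 0.15))
    pd.DataFrame(counts).to_csv(tmp_path / "counts.csv", index=False)
    design.to_csv(tmp_path / "design.csv", index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(limma))\n'
        'counts <- as.matrix(read.csv("counts.csv"))\n'
        'design <- as.matrix(read.csv("design.csv"))\n'
        'v <- voom(counts, design)\n'
        'fit <- eBayes(lmFit(v, design))\n'
        'out <- data.frame(logFC=fit$coefficients[,"group"],'
        ' t=fit$t[,"group"], dfprior=rep(fit$df.prior, nrow(counts)),'
        ' s2prior=rep(fit$s2.prior, nrow(counts)))\n'
        'write.csv(out, "limma.csv", row.names=FALSE)\n'
    )
    subprocess.run(
        ["Rscript", "oracle.R"], cwd=tmp_path, check=True, capture_output=True
    )
    ref = pd.read_csv(tmp_path / "limma.csv")
    y, w = voom_weights(pd.DataFrame(counts), design)
    res = fit_and_moderate(y, w, design, "group")
    np.testing.assert_allclose(res.table["log2fc"], ref["logFC"], atol=0.01)
    assert np.corrcoef(res.table["t"], ref["t"])[0, 1] > 0.999
    np.testing.assert_allclose(res.table["t"], ref["t"], atol=0.05)
    assert res.df_prior == pytest.approx(ref["dfprior"][0], rel=0.1)
    assert res.var_prior == pytest.approx(ref["s2prior"][0], rel=0.05)
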