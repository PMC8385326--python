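"""Eigengene scoring, paired changes and arm-comparison tests."""

import warnings

import numpy as np
import pandas as pd
import pytest

from sigtrace.containers import MetadataError, SignatureSet
from sigtrace.sigscore import (
    compare_arms,
    eigengene_score,
    paired_change,
    score_all_signatures,
)

from conftest import small_sim_config


def expr_frame(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestEigengeneScore:
    def test_rank_one_case_returns_zscored_profile(self, rng):
        profile = rng.normal(size=8)
        rows = [2.0 * profile + 1.0, -0.5 * profile, profile + 3.0]
        # note: affine maps of one shared profile
        expr = expr_frame(np.vstack(rows))
        score = eigengene_score(expr, list(expr.index))
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(score.to_numpy(), z, atol=1e-8)

    def test_affine_invariance(self, rng):
        expr = expr_frame(rng.normal(size=(6, 10)))
        base = eigengene_score(expr, list(expr.index))
        shifted = expr * 3.7 - 11.0
        np.testing.assert_allclose(
            eigengene_score(shifted, list(expr.index)).to_numpy(),
            base.to_numpy(),
            atol=1e-8,
        )

    def test_gene_order_invariance_including_sign(self, rng):
        expr = expr_frame(rng.normal(size=(7, 9)))
        genes = list(expr.index)
        fwd = eigengene_score(expr, genes)
        rev = eigengene_score(expr, genes[::-1])
        np.testing.assert_allclose(fwd.to_numpy(), rev.to_numpy(), atol=1e-10)

    def test_score_is_standardized(self, rng):
        expr = expr_frame(rng.normal(size=(10, 14)))
        s = eigengene_score(expr, list(expr.index))
        assert s.mean() == pytest.approx(0.0, abs=1e-10)
        assert s.std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_missing_genes_warn_or_raise(self, rng):
        expr = expr_frame(rng.normal(size=(4, 6)))
        with pytest.warns(UserWarning, match="absent"):
            eigengene_score(expr, list(expr.index) + ["nope"])
        with pytest.raises(ValueError, match="missing"):
            eigengene_score(expr, ["a", "b", "c", "nope1", "nope2", "nope3"])

    def test_zero_variance_gene_dropped_with_warning(self, rng):
        values = rng.normal(size=(4, 6))
        values[0] = 5.0
        expr = expr_frame(values)
        with pytest.warns(UserWarning, match="zero-variance"):
            s = eigengene_score(expr, list(expr.index))
        assert np.isfinite(s).all()

    def test_too_few_samples(self, rng):
        expr = expr_frame(rng.normal(size=(4, 2)))
        with pytest.raises(ValueError, match="3 samples"):
            eigengene_score(expr, list(expr.index))

    def test_score_tracks_true_proportion(self, default_trial):
        """Eigengene score of the planted target markers recovers the true
        mixing proportion (r >= 0.9)."""
        from sigtrace.bulkstats import log2cpm

        study, truth = default_trial
        expr = log2cpm(study.counts)
        score = eigengene_score(expr, truth.true_markers["CD8_IEL"])
        prop = truth.sample_proportions["CD8_IEL"].loc[score.index]
        assert np.corrcoef(score, prop)[0, 1] >= 0.9


def simple_meta():
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2", "p2", "p3"],
            "arm": ["treatment"] * 2 + ["placebo"] * 2 + ["placebo"],
            "visit": ["screening", "week14"] * 2 + ["screening"],
            "location": ["colon"] * 5,
            "activity": ["active"] * 5,
            "anti_tnf": ["no"] * 5,
        },
        index=pd.Index(["s1", "s2", "s3", "s4", "s5"], name="sample_id"),
    )


class TestPairedChange:
    def test_delta_definition_and_exclusion(self):
        scores = pd.Series([1.0, 2.0, 3.0, 3.0, 9.0], index=simple_meta().index)
        deltas, unpaired = paired_change(scores, simple_meta())
        assert unpaired == ["s5"]
        by_patient = deltas.set_index("patient_id")["delta"]
        assert by_patient["p1"] == pytest.approx(1.0)
        assert by_patient["p2"] == pytest.approx(0.0)

    def test_duplicate_pair_raises(self):
        meta = simple_meta()
        meta.loc["s5", ["patient_id", "visit"]] = ["p2", "screening"]
        scores = pd.Series(np.arange(5.0), index=meta.index)
        with pytest.raises(MetadataError, match="duplicate"):
            paired_change(scores, meta)


class TestCompareArms:
    def test_welch_worked_example(self):
        """Deltas {-1.1,-0.9,-1.0,-1.2} vs {0.1,-0.1,0.0,0.05}: the mean
        difference is -1.0625 and Welch's test is highly significant."""
        deltas = pd.DataFrame(
            {
                "arm": ["treatment"] * 4 + ["placebo"] * 4,
                "delta": [-1.1, -0.9, -1.0, -1.2, 0.1, -0.1, 0.0, 0.05],
            }
        )
        diff, t, p = compare_arms(deltas)
        assert diff == pytest.approx(-1.0625, abs=1e-12)
        # closed-form Welch oracle
        a = np.array([-1.1, -0.9, -1.0, -1.2])
        b = np.array([0.1, -0.1, 0.0, 0.05])
        se = np.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        assert t == pytest.approx((a.mean() - b.mean()) / se, abs=1e-9)
        assert p < 0.01

    def test_constant_equal_arms_degenerate(self):
        deltas = pd.DataFrame(
            {"arm": ["treatment"] * 2 + ["placebo"] * 2, "delta": [0.5] * 4}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            diff, t, p = compare_arms(deltas)
        assert diff == 0.0 and p == 1.0

    def test_too_few_per_arm(self):
        deltas = pd.DataFrame(
            {"arm": ["treatment", "placebo", "placebo"], "delta": [1.0, 0.0, 0.1]}
        )
        with pytest.raises(ValueError, match="at least 2"):
            compare_arms(deltas)


class TestScoreAllSignatures:
    def test_single_signature_fdr_equals_p(self, default_trial):
        study, truth = default_trial
        sigs = SignatureSet()
        sigs.add("CD8_IEL", truth.true_markers["CD8_IEL"][:50])
        _, comp = score_all_signatures(study, sigs)
        assert comp.table.loc[0, "fdr"] == pytest.approx(comp.table.loc[0, "p"])

    def test_target_signature_most_negative_delta(self, default_trial):
        """Only the CD8-IEL proportion is reduced, so its signature shows
        the most negative treatment-arm paired delta."""
        study, truth = default_trial
        sigs = SignatureSet()
        for name, genes in truth.true_markers.items():
            sigs.add(name, genes[:50])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, comp = score_all_signatures(study, sigs)
        table = comp.table.set_index("signature")
        assert table["delta_treatment"].idxmin() == "CD8_IEL"
        assert table.loc["CD8_IEL", "delta_treatment"] < 0

    def test_empty_signature_set_raises(self, default_trial):
        study, _ = default_trial
        with pytest.raises(ValueError, match="empty"):
            score_all_signatures(study, SignatureSet())
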