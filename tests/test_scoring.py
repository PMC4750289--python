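"""Variant scoring, dominant-negative remapping and cohort matrices."""

import numpy as np
import pandas as pd
import pytest

import fuzzyact as fa

from conftest import make_cohort


def _variant(cls, recurrent=False, gene="G1", sample="S0", pos=100):
    return fa.VariantRecord(sample, gene, cls, protein_position=pos, recurrent=recurrent)


class TestScoreVariant:
    def test_recurrent_missense_high_expr_amplified(self, rb, sep_expr_fit, sep_expr_var):
        s = fa.score_variant(
            rb, _variant("Missense_Mutation", recurrent=True),
            expr_value=sep_expr_fit.m_high + 2.0, cn_value=1.0, expr_var=sep_expr_var,
        )
        assert s > 0.8

    def test_frameshift_low_expr_deleted(self, rb, sep_expr_fit, sep_expr_var):
        s = fa.score_variant(
            rb, _variant("Frame_Shift_Del"),
            expr_value=sep_expr_fit.m_low - 2.0, cn_value=-1.0, expr_var=sep_expr_var,
        )
        assert s < -0.8

    def test_no_mutation_neutral_is_zero(self, rb, sep_expr_fit, sep_expr_var):
        s = fa.score_variant(
            rb, _variant("No_Mutation", pos=None),
            expr_value=sep_expr_fit.m_med, cn_value=0.0, expr_var=sep_expr_var,
        )
        assert s == pytest.approx(0.0, abs=1e-6)

    def test_unknown_class_rejected(self, rb, sep_expr_var):
        with pytest.raises(fa.InputError, match="Weird"):
            fa.score_variant(rb, _variant("Weird_Class"), 8.0, 0.0, sep_expr_var)

    # Between category anchors the aggregated curve can thin out and the
    # centroid of a clipped consequent drifts with the clip level, so the
    # score traces the consequent ordering with a small ripple. The ripple is
    # bounded by the centroid travel of a single clipped output category
    # (< 0.05, well under the 1/3 spacing between output categories).
    RIPPLE = 0.05

    @pytest.mark.parametrize("cn", [-1.0, 0.0, 1.0])
    @pytest.mark.parametrize("cls,recurrent", [("Missense_Mutation", True), ("Nonsense_Mutation", False)])
    def test_score_non_decreasing_in_expression(self, rb, cn, cls, recurrent):
        # activating context walks no_effect -> high_GoF; inactivating walks
        # high_LoF -> low_LoF: both rise with expression
        rng = np.random.default_rng(12)
        values = rng.normal(8.0, 1.2, 300)
        var = fa.fit_expression_memberships(values, gene="G")
        fit = fa.fit_expression(values, gene="G")
        xs = np.linspace(values.min(), values.max(), 60)
        scores = [
            fa.score_variant(rb, _variant(cls, recurrent=recurrent), x, cn, var)
            for x in xs
        ]
        assert np.all(np.diff(scores) >= -self.RIPPLE)
        anchors = [
            fa.score_variant(rb, _variant(cls, recurrent=recurrent), x, cn, var)
            for x in (fit.m_low, fit.m_med, fit.m_high)
        ]
        assert np.all(np.diff(anchors) >= -self.RIPPLE)
        assert scores[-1] >= scores[0] - 1e-9

    def test_recurrent_dominates_non_recurrent(self, rb, sep_expr_fit, sep_expr_var):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.uniform(sep_expr_fit.m_low - 2, sep_expr_fit.m_high + 2)
            cn = rng.uniform(-1.5, 1.5)
            rec = fa.score_variant(rb, _variant("Missense_Mutation", recurrent=True), x, cn, sep_expr_var)
            non = fa.score_variant(rb, _variant("Missense_Mutation", recurrent=False), x, cn, sep_expr_var)
            assert rec >= non - 1e-9


class TestSpecialRules:
    def test_special_missense_mirrors_to_lof(self, rb, sep_expr_fit, sep_expr_var):
        rulemap = fa.apply_special_rules(rb)
        s = fa.score_variant(
            rulemap.for_gene("TP53"), _variant("Missense_Mutation", recurrent=True, gene="TP53"),
            sep_expr_fit.m_high + 2.0, 1.0, sep_expr_var,
        )
        assert s < -0.8

    def test_special_truncating_rules_unchanged(self, rb, sep_expr_fit, sep_expr_var):
        rulemap = fa.apply_special_rules(rb)
        s = fa.score_variant(
            rulemap.for_gene("TP53"), _variant("Nonsense_Mutation", gene="TP53"),
            sep_expr_fit.m_low - 2.0, -1.0, sep_expr_var,
        )
        assert s < -0.8

    def test_non_special_gene_untouched(self, rb):
        rulemap = fa.apply_special_rules(rb)
        assert rulemap.for_gene("KRAS") is rb

    def test_mirror_symmetry_in_activating_context(self, rb, sep_expr_fit, sep_expr_var):
        # with the symmetric shipped output categories, the special-gene score
        # is exactly the negative of the default score for activating variants
        rulemap = fa.apply_special_rules(rb)
        rng = np.random.default_rng(21)
        for _ in range(20):
            x = float(rng.uniform(sep_expr_fit.m_low - 2, sep_expr_fit.m_high + 2))
            cn = float(rng.uniform(-1.5, 1.5))
            v = _variant("Missense_Mutation", recurrent=bool(rng.integers(2)))
            plain = fa.score_variant(rb, v, x, cn, sep_expr_var)
            special = fa.score_variant(rulemap.for_gene("TP53"), v, x, cn, sep_expr_var)
            assert special == pytest.approx(-plain, abs=1e-9)

    def test_full_mirror_negates_everything(self, rb, sep_expr_fit, sep_expr_var):
        mirrored = fa.mirror_consequents(rb)
        rng = np.random.default_rng(33)
        for cls in ("Missense_Mutation", "Splice_Site", "No_Mutation"):
            x = float(rng.uniform(sep_expr_fit.m_low - 2, sep_expr_fit.m_high + 2))
            cn = float(rng.uniform(-1.5, 1.5))
            v = _variant(cls, recurrent=True)
            assert fa.score_variant(mirrored, v, x, cn, sep_expr_var) == pytest.approx(
                -fa.score_variant(rb, v, x, cn, sep_expr_var), abs=1e-9
            )


class TestScoreGeneSample:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([0.9, -0.7], (0.9, -0.7)),
            ([0.3, 0.8], (0.8, 0.0)),
            ([-0.2, -0.5], (0.0, -0.5)),
        ],
    )
    def test_sign_split_max_min(self, scores, expected):
        assert fa.score_gene_sample(scores) == pytest.approx(expected)

    def test_unmutated_uses_no_mutation_score(self):
        assert fa.score_gene_sample([], no_mutation_score=-0.4) == pytest.approx((0.0, -0.4))
        assert fa.score_gene_sample([], no_mutation_score=0.25) == pytest.approx((0.25, 0.0))

    def test_empty_without_fallback_raises(self):
        with pytest.raises(fa.InputError):
            fa.score_gene_sample([])


class TestScoreCohort:
    def test_zero_variant_cohort_neutral_sample_scores_zero(self, rb):
        cohort = make_cohort(n_samples=60, genes=("G1", "G2"), sep_gene="G1", seed=4)
        gof, lof = fa.score_cohort(cohort, rb)
        fit = fa.fit_expression(cohort.expression.loc["G1"].to_numpy(), gene="G1")
        # the sample closest to the middle-tertile mean with near-zero CN
        expr = cohort.expression.loc["G1"]
        med_sample = (expr - fit.m_med).abs().idxmin()
        assert gof.loc["G1", med_sample] == pytest.approx(0.0, abs=1e-6)
        assert lof.loc["G1", med_sample] == pytest.approx(0.0, abs=1e-6)

    def test_matrix_bounds_and_shape(self, rb):
        sim = fa.generate_cohort(fa.SynthConfig(n_samples=60, n_genes=10, seed=5))
        gof, lof = fa.score_cohort(sim.cohort, rb)
        assert gof.shape == lof.shape == sim.cohort.expression.shape
        assert np.nanmin(gof.to_numpy()) >= 0.0 and np.nanmax(gof.to_numpy()) <= 1.0
        assert np.nanmin(lof.to_numpy()) >= -1.0 and np.nanmax(lof.to_numpy()) <= 0.0

    def test_planted_oncogene_mutants_score_higher(self, rb):
        sim = fa.generate_cohort(fa.SynthConfig(n_samples=120, n_genes=10, seed=6))
        gof, _ = fa.score_cohort(sim.cohort, rb)
        gene = sim.truth.loc[sim.truth.role == "oncogene", "gene"].iloc[0]
        mutants = {v.sample_id for v in sim.cohort.variants if v.gene == gene}
        wt = [s for s in gof.columns if s not in mutants]
        assert gof.loc[gene, sorted(mutants)].mean() > gof.loc[gene, wt].mean()

    def test_sample_permutation_equivariance(self, rb):
        sim = fa.generate_cohort(fa.SynthConfig(n_samples=40, n_genes=6, n_oncogenes=2, n_tsgs=1, seed=7))
        gof, lof = fa.score_cohort(sim.cohort, rb)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(sim.cohort.samples))
        shuffled = fa.OmicsCohort(
            sim.cohort.expression[perm], sim.cohort.copy_number[perm], sim.cohort.variants
        )
        gof_p, lof_p = fa.score_cohort(shuffled, rb)
        pd.testing.assert_frame_equal(gof_p, gof[perm])
        pd.testing.assert_frame_equal(lof_p, lof[perm])

    def test_constant_expression_gene_skipped_as_nan(self, rb):
        cohort = make_cohort(n_samples=30, genes=("G1", "G2"), seed=8)
        flat = cohort.expression.copy()
        flat.loc["G2"] = 5.0
        cohort = fa.OmicsCohort(flat, cohort.copy_number, [])
        gof, lof = fa.score_cohort(cohort, rb)
        assert gof.loc["G2"].isna().all() and lof.loc["G2"].isna().all()
        assert gof.loc["G1"].notna().all()

    def test_duplicate_variant_rows_do_not_change_scores(self, rb):
        v = _variant("Missense_Mutation", gene="G1", sample="S1")
        c1 = make_cohort(n_samples=30, variants=[v], seed=9)
        c2 = make_cohort(n_samples=30, variants=[v, v], seed=9)
        gof1, lof1 = fa.score_cohort(c1, rb)
        gof2, lof2 = fa.score_cohort(c2, rb)
        pd.testing.assert_frame_equal(gof1, gof2)
        pd.testing.assert_frame_equal(lof1, lof2)
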