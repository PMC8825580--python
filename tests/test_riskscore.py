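"""Risk-score construction: selection, scoring, cutoff, transfer, correlation."""

import numpy as np
import pandas as pd
import pytest

from episcore.errors import ArgumentError
from episcore.riskscore import (
    RiskGene,
    RiskScoreModel,
    correlate_score_response,
    diff_expression,
    fit_score_cutoff,
    score_patients,
    select_prognostic,
    strongly_expressed,
    transfer_cutpoint,
    transfer_model,
)
from episcore.survival import SurvivalCohort, logrank_test, maxstat_cutpoint


def model_of(*genes):
    return RiskScoreModel([RiskGene(g, b, c, p, 0.01) for g, b, c, p in genes])


class TestScoreArithmetic:
    M = model_of(("g1", 0.5, 10.0, 0.5), ("g2", -0.3, 20.0, 0.5))

    @pytest.mark.parametrize(
        "e1, e2, expected",
        [
            (11.0, 21.0, 0.2),  # above both
            (9.0, 19.0, -0.2),  # below both
            (11.0, 19.0, 0.8),  # above g1 only
            (10.0, 21.0, -0.8),  # equality codes as below
        ],
    )
    def test_weighted_sum(self, e1, e2, expected):
        expr = pd.DataFrame({"p": [e1, e2]}, index=["g1", "g2"])
        assert score_patients(self.M, expr)["p"] == pytest.approx(expected)

    def test_equality_convention_flag(self):
        expr = pd.DataFrame({"p": [10.0, 21.0]}, index=["g1", "g2"])
        assert score_patients(self.M, expr, equality="above")["p"] == pytest.approx(0.2)

    def test_gene_order_invariance_and_zero_beta(self, rng):
        expr = pd.DataFrame(
            rng.normal(10, 3, (2, 20)), index=["g1", "g2"],
            columns=[f"p{i}" for i in range(20)],
        )
        rev = RiskScoreModel(list(reversed(self.M.genes)))
        assert np.allclose(score_patients(self.M, expr), score_patients(rev, expr))
        withzero = RiskScoreModel(
            self.M.genes + [RiskGene("g1", 0.0, 5.0, 0.5, 1.0)]
        )
        assert np.allclose(score_patients(self.M, expr), score_patients(withzero, expr))

    def test_crossing_one_cutpoint_moves_score_by_two_beta(self):
        expr = pd.DataFrame({"p": [9.0, 19.0]}, index=["g1", "g2"])
        lo = score_patients(self.M, expr)["p"]
        expr.loc["g1", "p"] = 11.0
        hi = score_patients(self.M, expr)["p"]
        assert hi - lo == pytest.approx(2 * 0.5)

    def test_missing_gene_listed(self):
        expr = pd.DataFrame({"p": [1.0]}, index=["g1"])
        with pytest.raises(ArgumentError, match="g2"):
            score_patients(self.M, expr)

    def test_score_bounded_by_total_abs_beta(self, rng):
        expr = pd.DataFrame(
            rng.normal(10, 8, (2, 50)), index=["g1", "g2"],
            columns=[f"p{i}" for i in range(50)],
        )
        s = score_patients(self.M, expr)
        assert (s.abs() <= self.M.max_abs_score() + 1e-12).all()

    def test_model_tsv_roundtrip(self, tmp_path):
        m = model_of(("g1", 0.512345, 10.1, 0.45), ("g2", -0.3, 20.0, 0.55))
        m.score_cutoff = -0.123456789
        m.training_meta = {"cohort": "train", "n": "600"}
        path = tmp_path / "model.tsv"
        m.to_tsv(path)
        back = RiskScoreModel.from_tsv(path)
        assert back.score_cutoff == m.score_cutoff
        assert [(g.gene_id, g.beta, g.cutpoint) for g in back.genes] == [
            (g.gene_id, g.beta, g.cutpoint) for g in m.genes
        ]
        assert back.training_meta["cohort"] == "train"


class TestDiffExpression:
    def test_identical_groups_not_significant(self, rng):
        a = pd.DataFrame(rng.normal(size=(30, 5)), index=[f"g{i}" for i in range(30)])
        res = diff_expression(a, a.copy(), alternative="over")
        assert (res["p"] >= 0.5).all()

    def test_swapping_groups_flips_calls(self, rng):
        genes = [f"g{i}" for i in range(100)]
        a = pd.DataFrame(rng.normal(size=(100, 10)), index=genes)
        b = pd.DataFrame(rng.normal(size=(100, 10)), index=genes)
        a.iloc[:10] += 3
        over = diff_expression(a, b, "over")
        under = diff_expression(b, a, "under")
        assert np.allclose(over["p"], under["p"])

    def test_planted_shift_recovered(self):
        from episcore.synthetic_data import SimConfig, make_group_expression

        cfg = SimConfig(seed=9, n_planted_de=50, planted_log2fc=2.0)
        genes = [f"g{i}" for i in range(500)]
        a, b, up = make_group_expression(cfg, genes, 20, 20)
        res = diff_expression(a, b, "over")
        called = set(res.index[res["q"] <= 0.05])
        assert len(called & set(up)) >= 45
        assert len(called - set(up)) <= 5

    def test_small_group_rejected(self, rng):
        a = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ArgumentError):
            diff_expression(a, a, "over")


class TestSelectPrognostic:
    def _planted_cohort(self, seed):
        from episcore.synthetic_data import SimConfig, make_expression, make_survival_cohort

        cfg = SimConfig(seed=seed, n_patients=600)
        genes = [f"G{i:04d}" for i in range(200)]
        expr = make_expression(cfg, genes, 600)
        return make_survival_cohort(cfg, expr)

    def test_planted_genes_recovered(self):
        cohort, truth = self._planted_cohort(0)
        sel = {g.gene_id for g in select_prognostic(list(cohort.expression.index), cohort)}
        assert len(sel & set(truth.gene_id)) >= 8

    def test_direction_filter(self):
        cohort, truth = self._planted_cohort(1)
        high = select_prognostic(list(cohort.expression.index), cohort,
                                 direction="adverse_high")
        assert all(g.beta > 0 for g in high)
        low = select_prognostic(list(cohort.expression.index), cohort,
                                direction="adverse_low")
        assert all(g.beta < 0 for g in low)

    def test_null_cohort_selects_nothing(self):
        from episcore.synthetic_data import SimConfig, make_expression, make_survival_cohort

        zero = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed + 100, n_patients=600, planted_betas=())
            expr = make_expression(cfg, [f"g{i}" for i in range(100)], 600)
            cohort, _ = make_survival_cohort(cfg, expr)
            sel = select_prognostic(list(expr.index), cohort)
            zero += len(sel) == 0
        assert zero >= 9

    def test_perfect_separator_flagged(self):
        r = np.random.default_rng(0)
        x = np.sort(r.normal(size=40))
        t = np.where(x > x[19], 100.0 + r.random(40), 1.0 + r.random(40))
        e = (x <= x[19]).astype(int)
        expr = pd.DataFrame([x], index=["sep"], columns=[f"p{i}" for i in range(40)])
        cohort = SurvivalCohort([f"p{i}" for i in range(40)], t, e, expr)
        sel = select_prognostic(["sep"], cohort)
        assert len(sel) == 1 and sel[0].separation

    def test_empty_candidates_rejected(self):
        cohort, _ = self._planted_cohort(2)
        with pytest.raises(ArgumentError):
            select_prognostic([], cohort)


class TestScoreCutoffAndTransfer:
    def test_cutoff_equals_bruteforce_argmax(self, rng):
        t = rng.exponential(40, 80)
        e = (rng.random(80) < 0.7).astype(int)
        s = rng.normal(size=80)
        cohort = SurvivalCohort(
            [f"p{i}" for i in range(80)], t, e,
            pd.DataFrame(np.zeros((1, 80)), index=["g"],
                         columns=[f"p{i}" for i in range(80)]),
        )
        split = fit_score_cutoff(s, cohort)
        res = maxstat_cutpoint(t, e, s)
        assert split.cutoff == res.cutpoint
        assert split.n_high + split.n_low == 80

    def test_patient_permutation_invariance(self, rng):
        t = rng.exponential(40, 60)
        e = (rng.random(60) < 0.7).astype(int)
        s = rng.normal(size=60)
        ids = [f"p{i}" for i in range(60)]
        expr = pd.DataFrame(np.zeros((1, 60)), index=["g"], columns=ids)
        c1 = SurvivalCohort(ids, t, e, expr)
        perm = rng.permutation(60)
        ids_p = [ids[i] for i in perm]
        c2 = SurvivalCohort(ids_p, t[perm], e[perm],
                            expr[ids_p])
        assert fit_score_cutoff(s, c1).cutoff == fit_score_cutoff(s[perm], c2).cutoff

    def test_bimodal_scores_split_recovers_planted_modes(self):
        r = np.random.default_rng(1)
        s = np.concatenate([r.normal(-3, 0.3, 50), r.normal(3, 0.3, 50)])
        t = np.where(s > 0, r.exponential(3, 100), 50 + r.exponential(3, 100))
        ids = [f"p{i}" for i in range(100)]
        cohort = SurvivalCohort(
            ids, np.maximum(t, 1e-3), np.ones(100, dtype=int),
            pd.DataFrame(np.zeros((1, 100)), index=["g"], columns=ids),
        )
        split = fit_score_cutoff(s, cohort)
        # the dichotomy at the cutoff matches the planted mode membership
        # up to at most two boundary patients
        assert (((s > split.cutoff) != (s > 0)).sum()) <= 2

    def test_transfer_quantile_matching(self):
        assert transfer_cutpoint(np.arange(1.0, 11.0), 0.4) == 6.0

    def test_transfer_identity_reproduces_dichotomies(self, rng):
        expr = pd.DataFrame(
            rng.normal(10, 3, (3, 50)),
            index=["g1", "g2", "g3"],
            columns=[f"p{i}" for i in range(50)],
        )
        genes = []
        for g in expr.index:
            cut = float(np.quantile(expr.loc[g], 0.6))
            genes.append(
                RiskGene(g, 0.5, cut, float((expr.loc[g] > cut).mean()), 0.01)
            )
        model = RiskScoreModel(genes, score_cutoff=0.0)
        back = transfer_model(model, expr)
        for g0, g1 in zip(model.genes, back.genes):
            assert np.array_equal(
                expr.loc[g0.gene_id] > g0.cutpoint, expr.loc[g1.gene_id] > g1.cutpoint
            )

    def test_transfer_preserves_proportions(self, rng):
        vals = rng.normal(size=500)
        expr = pd.DataFrame([vals], index=["g"],
                            columns=[f"p{i}" for i in range(500)])
        model = RiskScoreModel([RiskGene("g", 0.4, 0.0, 0.37, 0.01)])
        back = transfer_model(model, expr)
        achieved = (vals > back.genes[0].cutpoint).mean()
        assert abs(achieved - 0.37) <= 1 / 500 + 1e-9

    def test_transfer_keeps_betas_and_score_cutoff(self, rng):
        expr = pd.DataFrame([rng.normal(size=30)], index=["g"],
                            columns=[f"p{i}" for i in range(30)])
        model = RiskScoreModel([RiskGene("g", -0.7, 0.2, 0.5, 0.01)], score_cutoff=-1.2)
        back = transfer_model(model, expr)
        assert back.score_cutoff == -1.2
        assert back.genes[0].beta == -0.7


class TestCorrelation:
    def test_exact_linear_r2_one(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = correlate_score_response(s, 2.5 - 0.5 * s)
        assert res.r_squared == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(-1.0)

    def test_hand_formula_small_vectors(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r_hand = (((s - s.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((s - s.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        res = correlate_score_response(s, y)
        assert res.pearson_r == pytest.approx(r_hand)

    def test_missing_pairs_dropped_with_warning(self):
        s = np.arange(6.0)
        y = np.array([1.0, 2.0, np.nan, 3.0, 5.0, 4.0])
        with pytest.warns(UserWarning):
            res = correlate_score_response(s, y)
        assert res.n == 5

    def test_type_i_error_near_nominal(self):
        hits = 0
        for seed in range(500):
            r = np.random.default_rng(seed)
            if correlate_score_response(r.normal(size=8), r.normal(size=8)).p_value < 0.05:
                hits += 1
        assert abs(hits / 500 - 0.05) <= 0.03

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ArgumentError):
            correlate_score_response([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        with pytest.raises(ArgumentError):
            correlate_score_response(np.ones(5), np.arange(5.0))


class TestExpressionFilter:
    def test_strongly_expressed_median_rule(self):
        expr = pd.DataFrame(
            [[10, 10, 10], [0, 0, 0], [5, 0, 5]],
            index=["hi", "lo", "mid"], dtype=float,
        )
        got = strongly_expressed(expr)  # global median of all values is 5
        assert "hi" in got and "lo" not in got and "mid" not in got
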