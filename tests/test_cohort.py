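"""Cohort assembly, outcome labels, genotype encoding, and statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from riskpipe import (
    GeneratorSpec,
    assemble_cohort,
    encode_genotype,
    fev1_criterion,
    fisher_exact,
    generate_registry,
    label_decline,
    label_outcome,
    logistic_recalibration,
    mann_whitney_u,
    recalibrate_in_large,
    single_variable_importance,
)
from riskpipe.cohort import FlowCounts, GENOTYPE_FEATURES


def _record(**kw):
    base = {"age": 30.0, "prior_lt": 0, "lost_fu": 0, "death_3y": 0,
            "lt_3y": 0, "fev1pp_y0": 60.0, "fev1pp_y3": 55.0}
    base.update(kw)
    return base


class TestFlow:
    def test_counts_identity_enforced(self):
        with pytest.raises(ValueError, match="add up"):
            FlowCounts(100, 10, 10, 90, 5)

    def test_empty_input_all_zero(self):
        _, counts = assemble_cohort(pd.DataFrame())
        assert (counts.n_initial, counts.n_final, counts.n_events) == (0, 0, 0)

    def test_handcrafted_records_filtered_in_order(self):
        records = pd.DataFrame([
            _record(age=10.0),                       # pediatric: out first
            _record(prior_lt=1),                     # prior transplant
            _record(lost_fu=1),                      # lost to follow-up
            _record(death_3y=1),                     # event
            _record(lt_3y=1),                        # event
            _record(),                               # survivor
        ])
        dataset, counts = assemble_cohort(records)
        assert counts.n_initial == 5          # adults
        assert counts.n_prior_transplant_excluded == 1
        assert counts.n_lost_excluded == 1
        assert counts.n_final == 3
        assert counts.n_events == 2
        assert dataset.n == 3

    def test_age_comparator_configurable(self):
        records = pd.DataFrame([_record(age=18.0)])
        _, ge = assemble_cohort(records, age_comparator=">=")
        _, gt = assemble_cohort(records, age_comparator=">")
        assert ge.n_final == 1
        assert gt.n_final == 0
        assert gt.n_age_excluded == 1

    def test_printed_flow_reproduced(self):
        spec = GeneratorSpec(n=4064, prevalence=0.094, seed=7,
                             n_prior_transplant=114, n_lost_followup=354,
                             n_pediatric=300, exact_prevalence=True)
        dataset, counts = assemble_cohort(generate_registry(spec))
        assert counts.n_initial == 4532
        assert counts.n_final == 4064
        assert counts.n_events == 382
        assert round(100 * counts.prevalence, 1) == 9.4
        assert "4064" in counts.report()


class TestLabels:
    @pytest.mark.parametrize("death,lt,expect", [
        (1, 0, 1), (0, 1, 1), (1, 1, 1), (0, 0, 0),
    ])
    def test_composite_endpoint_counts_once(self, death, lt, expect):
        assert label_outcome(_record(death_3y=death, lt_3y=lt)) == expect

    @pytest.mark.parametrize("base,horizon,lt,expect", [
        (35.0, 25.0, 0, True),    # crossed below 30 without transplant
        (28.0, 25.0, 0, False),   # already below 30 at baseline
        (35.0, 25.0, 1, False),   # transplant disqualifies
        (35.0, 32.0, 0, False),   # never crossed
    ])
    def test_pulmonary_decline(self, base, horizon, lt, expect):
        rec = _record(fev1pp_y0=base, fev1pp_y3=horizon, lt_3y=lt)
        assert label_decline(rec) is expect

    def test_missing_horizon_fev1_is_undefined(self):
        assert label_decline(_record(fev1pp_y3=np.nan)) is None

    def test_missing_baseline_is_an_error(self):
        with pytest.raises(ValueError):
            label_decline(_record(fev1pp_y0=np.nan))


class TestGenotype:
    def test_f508del_homozygote(self):
        g = encode_genotype("F508del", "F508del")
        assert g["geno_homozygous"] == 1
        assert g["geno_f508del"] == 1
        assert g["geno_g551d"] == 0
        assert (g["geno_class_ii"], g["geno_class_iii"], g["geno_class_vi"]) \
            == (1, 1, 1)
        assert (g["geno_class_i"], g["geno_class_iv"], g["geno_class_v"]) \
            == (0, 0, 0)

    def test_g551d_g542x_compound_heterozygote(self):
        g = encode_genotype("G551D", "G542X")
        assert g["geno_homozygous"] == 0
        assert g["geno_f508del"] == 0
        assert g["geno_g551d"] == 1
        assert g["geno_class_i"] == 1   # G542X
        assert g["geno_class_iii"] == 1  # G551D

    def test_unknown_mutations_set_no_class_flags(self):
        with pytest.warns(UserWarning, match="unknown CFTR"):
            g = encode_genotype("novel1", "novel1")
        assert g["geno_homozygous"] == 1
        assert sum(v for k, v in g.items() if k != "geno_homozygous") == 0

    def test_symmetric_in_allele_order(self):
        pool = ["F508del", "G551D", "R117H", "G542X", "621+1G->T"]
        for a in pool:
            for b in pool:
                assert encode_genotype(a, b) == encode_genotype(b, a)

    def test_nine_features(self):
        assert len(GENOTYPE_FEATURES) == 9


def _fisher_oracle(table):
    """Brute-force two-sided Fisher by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    rv = hypergeom(n, r1, c1)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(k) for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
               if rv.pmf(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    @pytest.mark.parametrize("table,expect", [
        ([[2027, 1655], [192, 190]], 0.075),   # gender
        ([[48, 3634], [11, 371]], 0.022),      # hemoptysis
        ([[123, 3559], [4, 378]], 0.012),      # nasal polyps
    ])
    def test_printed_cohort_table_pvalues(self, table, expect):
        assert round(fisher_exact(table), 3) == expect

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact([[0, 5], [0, 3]]) == 1.0

    def test_small_table_full_enumeration(self):
        # 4 admissible tables; two-sided mass = 34/70
        assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(34 / 70)
        assert round(fisher_exact([[3, 1], [1, 3]]), 3) == 0.486

    @settings(max_examples=60, deadline=None)
    @given(st.tuples(st.integers(0, 10), st.integers(0, 10),
                     st.integers(0, 10), st.integers(0, 10)))
    def test_matches_hypergeometric_enumeration(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            assert fisher_exact(table) == 1.0
        else:
            assert fisher_exact(table) == pytest.approx(_fisher_oracle(table),
                                                        abs=1e-9)


class TestMannWhitney:
    def test_identical_multisets_give_one(self):
        assert mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3]) == pytest.approx(1.0)

    def test_all_identical_values_give_one(self):
        assert mann_whitney_u([5, 5], [5, 5, 5]) == 1.0

    def test_extreme_separation_matches_exact_enumeration(self):
        # 20 arrangements of ranks; the observed split is one of the two
        # extremes, two-sided p = 2/20
        assert mann_whitney_u([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_exact_agrees_with_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 18)
        y = rng.normal(0.5, 1, 20)  # 18*20 = 360 <= 400 -> exact path
        from scipy.stats import mannwhitneyu

        p_exact = mann_whitney_u(x, y)
        p_norm = mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic").pvalue
        assert abs(p_exact - p_norm) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestFEV1Criterion:
    def test_strict_inequality_at_thirty(self):
        assert fev1_criterion(29.9) == 1
        assert fev1_criterion(30.0) == 0

    def test_other_thresholds(self):
        assert fev1_criterion(35.0, threshold=40.0) == 1

    def test_vectorized_referral_count(self):
        vals = np.array([10.0, 29.9, 30.0, 45.0, 25.0])
        flags = fev1_criterion(vals)
        assert flags.sum() == int((vals < 30).sum()) == 3


class TestRecalibration:
    def test_matched_mean_is_identity(self):
        s = np.array([0.05, 0.1, 0.15])
        out = recalibrate_in_large(s, float(s.mean()))
        np.testing.assert_allclose(out, s, atol=1e-12)

    def test_constant_scores_map_to_target(self):
        out = recalibrate_in_large(np.full(50, 0.2), 0.094)
        np.testing.assert_allclose(out, 0.094, atol=1e-9)

    def test_heterogeneous_scores_hit_target_mean(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0.01, 0.9, 500)
        out = recalibrate_in_large(s, 0.094)
        assert out.mean() == pytest.approx(0.094, abs=1e-8)

    def test_rank_order_preserved_exactly(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0.01, 0.99, 200)
        out = recalibrate_in_large(s, 0.3)
        np.testing.assert_array_equal(np.argsort(s), np.argsort(out))

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            recalibrate_in_large(np.array([0.2, 0.3]), 1.5)

    def test_logistic_recalibration_recovers_identity(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0.02, 0.98, 10_000)
        y = (rng.uniform(size=s.size) < s).astype(int)
        res = logistic_recalibration(s, y)
        assert res.slope == pytest.approx(1.0, abs=0.1)
        assert res.intercept == pytest.approx(0.0, abs=0.1)
        assert not res.separated

    def test_constant_scores_intercept_only(self):
        y = np.r_[np.ones(20, int), np.zeros(80, int)]
        res = logistic_recalibration(np.full(100, 0.5), y)
        assert res.slope == 0.0
        np.testing.assert_allclose(res.adjusted, 0.2)

    def test_adjusted_scores_monotone_in_input(self):
        rng = np.random.default_rng(4)
        s = np.sort(rng.uniform(0.01, 0.99, 300))
        y = (rng.uniform(size=300) < s).astype(int)
        res = logistic_recalibration(s, y)
        assert (np.diff(res.adjusted) >= -1e-12).all()

    def test_perfect_separation_flagged_and_capped(self):
        s = np.r_[np.full(20, 0.9), np.full(20, 0.1)]
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        res = logistic_recalibration(s, y)
        assert res.separated
        assert abs(res.slope) <= 25.0


class TestVariableImportance:
    def test_outcome_copy_is_perfectly_predictive(self, toy_cohort):
        dataset, _ = toy_cohort
        leaky = dataset.X.copy()
        leaky["leak"] = dataset.y.astype(float)
        from riskpipe import LabeledDataset

        ds = LabeledDataset(leaky, dataset.y)
        score = single_variable_importance(ds, "leak", "auc_roc", seed=0,
                                           budget=4)
        assert score > 0.95

    def test_independent_variable_near_chance(self, toy_cohort):
        dataset, _ = toy_cohort
        rng = np.random.default_rng(5)
        X = dataset.X.copy()
        X["junk"] = rng.normal(size=len(X))
        from riskpipe import LabeledDataset

        ds = LabeledDataset(X, dataset.y)
        roc = single_variable_importance(ds, "junk", "auc_roc", seed=0,
                                         budget=4)
        assert roc == pytest.approx(0.5, abs=0.12)

    def test_constant_variable_scores_at_chance_level(self, toy_cohort):
        dataset, _ = toy_cohort
        X = dataset.X.copy()
        X["const"] = 1.0
        from riskpipe import LabeledDataset

        ds = LabeledDataset(X, dataset.y)
        assert single_variable_importance(ds, "const", "auc_roc") == 0.5
        assert single_variable_importance(ds, "const", "auc_pr") \
            == pytest.approx(ds.prevalence)

    def test_precision_and_sensitivity_rankings_can_disagree(self):
        # variable A: diffuse signal, best AUC-ROC; variable B: flags a small
        # very-high-precision subset, best AUC-PR — the ranking flips with
        # the metric
        from riskpipe import LabeledDataset

        rng = np.random.default_rng(6)
        n = 3000
        y = (rng.uniform(size=n) < 0.1).astype(int)
        a = 1.4 * y + rng.normal(0, 1.0, n)
        b = np.where(y == 1, rng.uniform(size=n) < 0.4,
                     rng.uniform(size=n) < 0.002).astype(float)
        ds = LabeledDataset(pd.DataFrame({"a": a, "b": b}), y)
        roc_a = single_variable_importance(ds, "a", "auc_roc", seed=1, budget=4)
        roc_b = single_variable_importance(ds, "b", "auc_roc", seed=1, budget=4)
        pr_a = single_variable_importance(ds, "a", "auc_pr", seed=1, budget=4)
        pr_b = single_variable_importance(ds, "b", "auc_pr", seed=1, budget=4)
        assert roc_a > roc_b
        assert pr_b > pr_a
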