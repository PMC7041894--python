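import itertools
import math

import numpy as np
import pytest
from scipy import stats

from dptrialsynth.cohort import Cohort, DEFAULT_SCHEMA
from dptrialsynth.evaluation import (
    EvaluationReport,
    coefficient_concordance,
    evaluate_cohorts,
    med_addition_rate,
    pairwise_pearson,
    score_comparison,
    structure_similarity,
    summary_stats,
    transfer_learning_eval,
)
from dptrialsynth.fixtures import TrialSimParams, simulate_trial

from conftest import make_record


class TestPairwisePearson:
    def test_dbp_equal_to_sbp_gives_unit_cross_block(self, trial_cohort):
        vals = trial_cohort.values().copy()
        vals[:, :, 1] = vals[:, :, 0]  # DBP := SBP
        cohort_eq = Cohort(
            tuple(
                type(r)(r.id, r.arm, vals[i], r.visit_labels)
                for i, r in enumerate(trial_cohort.records)
            ),
            trial_cohort.schema,
        )
        mat = pairwise_pearson(cohort_eq)
        n_v = DEFAULT_SCHEMA.n_visits
        # corr(SBP_t, DBP_t) = 1 on the cross-block diagonal
        for t in range(n_v):
            assert mat[t, n_v + t] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self, trial_cohort):
        mat = pairwise_pearson(trial_cohort)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert np.abs(mat).max() <= 1.0 + 1e-12

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(0)
        n = 10_000
        vals = rng.normal(size=(n, 12, 3)) * [15, 10, 1] + [140, 80, 2]
        recs = tuple(
            make_record(f"r{i}", "standard", vals[i, :, 0], vals[i, :, 1], vals[i, :, 2])
            for i in range(n)
        )
        mat = pairwise_pearson(Cohort(recs))
        off = mat[~np.eye(36, dtype=bool)]
        assert np.abs(off).max() < 0.05  # null correlations ~ 1/sqrt(n)

    def test_zero_variance_column_warns_and_zeroes(self):
        recs = tuple(make_record(f"c{i}", "standard", np.full(12, 140.0),
                                 med=np.full(12, 2.0)) for i in range(5))
        with pytest.warns(UserWarning, match="zero-variance"):
            mat = pairwise_pearson(Cohort(recs))
        assert (np.diag(mat) == 1).all()
        assert mat[0, 1] == 0.0


class TestStructureSimilarity:
    def test_identical_matrices(self, trial_cohort):
        mat = pairwise_pearson(trial_cohort)
        rho, p = structure_similarity(mat, mat)
        assert rho == pytest.approx(1.0)
        assert p < 1e-4

    def test_reversed_rank_order(self):
        a = np.array([[1.0, 0, 0], [0.1, 1.0, 0], [0.2, 0.3, 1.0]])
        b = np.array([[1.0, 0, 0], [0.3, 1.0, 0], [0.2, 0.1, 1.0]])
        rho, _ = structure_similarity(a, b)
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_toy(self):
        # lower triangles (0.5, 0.1, 0.3) vs (0.2, 0.4, 0.6):
        # ranks (3,1,2) vs (1,2,3) -> Spearman rho = -0.5
        a, b = np.eye(3), np.eye(3)
        a[1, 0], a[2, 0], a[2, 1] = 0.5, 0.1, 0.3
        b[1, 0], b[2, 0], b[2, 1] = 0.2, 0.4, 0.6
        rho, _ = structure_similarity(a, b)
        assert rho == pytest.approx(-0.5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            structure_similarity(np.eye(3), np.eye(4))


class TestSummaryStats:
    def test_constant_cohort_zero_sd(self):
        recs = tuple(make_record(f"k{i}", "intensive", np.full(12, 120.0))
                     for i in range(4))
        with pytest.warns(UserWarning):  # standard arm empty
            table = summary_stats(Cohort(recs))
        assert (table["sd"] == 0.0).all()
        assert set(table.index.get_level_values("arm")) == {"intensive"}

    def test_hand_computed_four_records(self, toy_cohort):
        table = summary_stats(toy_cohort)
        # standard arm, RZ visit, SBP: values 150 and 145
        row = table.loc[("standard", "RZ", "SBP")]
        assert row["mean"] == pytest.approx(147.5)
        assert row["sd"] == pytest.approx(np.std([150, 145], ddof=1))

    def test_pooled_mean_is_weighted_average_of_arms(self, trial_cohort):
        table = summary_stats(trial_cohort)
        arms = trial_cohort.arms
        n_std, n_int = (arms == 0).sum(), (arms == 1).sum()
        m_std = table.loc[("standard", "RZ", "SBP"), "mean"]
        m_int = table.loc[("intensive", "RZ", "SBP"), "mean"]
        pooled = trial_cohort.values()[:, 0, 0].mean()
        weighted = (n_std * m_std + n_int * m_int) / (n_std + n_int)
        assert pooled == pytest.approx(weighted)


class TestMedAdditionRate:
    def test_hand_enumerated_toy(self):
        # P1 standard: SBP (150,145,130), meds (1,2,2); P2 standard:
        # SBP (135,150,150), meds (0,0,1). Above-goal transitions: P1 150->,
        # P1 145->, P2 150->; additions on 2 of the 3 -> rate 2/3
        sched = DEFAULT_SCHEMA.schedule[:3]
        import dataclasses
        schema3 = dataclasses.replace(DEFAULT_SCHEMA, schedule=sched)
        recs = (
            make_record("P1", "standard", [150, 145, 130], med=[1, 2, 2], schema=schema3),
            make_record("P2", "standard", [135, 150, 150], med=[0, 0, 1], schema=schema3),
        )
        rates = med_addition_rate(Cohort(recs, schema3))
        assert rates["overall"] == pytest.approx(2 / 3)
        assert rates["standard"] == pytest.approx(2 / 3)
        assert rates["intensive"] is None

    def test_always_below_goal_undefined(self):
        recs = (make_record("low", "standard", np.full(12, 110.0)),)
        rates = med_addition_rate(Cohort(recs))
        assert rates["overall"] is None

    def test_constant_meds_rate_zero(self):
        recs = (make_record("hi", "standard", np.full(12, 160.0), med=np.full(12, 2.0)),)
        assert med_addition_rate(Cohort(recs))["overall"] == 0.0


class TestTransferLearning:
    def test_separable_arms_perfect_auroc(self):
        rng = np.random.default_rng(1)
        recs = []
        for i in range(60):
            arm = "intensive" if i < 30 else "standard"
            base = 110.0 if arm == "intensive" else 160.0
            recs.append(make_record(f"s{i}", arm, np.full(12, base)
                                    + rng.normal(0, 0.5, 12)))
        cohort = Cohort(tuple(recs))
        res = transfer_learning_eval(cohort, cohort, seed=0)
        for name, out in res.items():
            assert out["auroc"] == pytest.approx(1.0), name

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(2)
        n = 2000
        vals = rng.normal(size=(n, 12, 3)) * [15, 10, 1] + [140, 80, 2]
        arms = ["standard" if rng.random() < 0.5 else "intensive" for _ in range(n)]
        recs = tuple(make_record(f"n{i}", arms[i], vals[i, :, 0], vals[i, :, 1],
                                 np.clip(vals[i, :, 2], 0, 10)) for i in range(n))
        cohort = Cohort(recs)
        train = cohort.subset(range(1500))
        test = cohort.subset(range(1500, 2000))
        res = transfer_learning_eval(train, test,
                                     model_names=("logistic_regression",), seed=0)
        assert res["logistic_regression"]["auroc"] == pytest.approx(0.5, abs=0.07)

    def test_deterministic_repeat(self, trial_cohort):
        train = trial_cohort.subset(range(300))
        test = trial_cohort.subset(range(300, 400))
        a = transfer_learning_eval(train, test, seed=3)
        b = transfer_learning_eval(train, test, seed=3)
        for name in a:
            assert a[name]["auroc"] == b[name]["auroc"]

    def test_single_class_rejected(self):
        recs = tuple(make_record(f"x{i}", "standard", np.full(12, 140.0))
                     for i in range(10))
        cohort = Cohort(recs)
        with pytest.raises(ValueError, match="single class"):
            transfer_learning_eval(cohort, cohort)


class TestCoefficientConcordance:
    def test_identical_and_negated(self):
        v = [0.2, -0.5, 1.0, 0.1, 0.4]
        same = coefficient_concordance(v, v)
        assert same["pearson_r"] == pytest.approx(1.0)
        assert same["spearman_rho"] == pytest.approx(1.0)
        neg = coefficient_concordance(v, [-x for x in v])
        assert neg["pearson_r"] == pytest.approx(-1.0)
        assert neg["spearman_rho"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 1.0, 4.0, 3.0, 5.0]
        r_hand = np.cov(a, b, ddof=1)[0, 1] / (np.std(a, ddof=1) * np.std(b, ddof=1))
        out = coefficient_concordance(a, b)
        assert out["pearson_r"] == pytest.approx(r_hand)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            coefficient_concordance([1, 2], [1, 2, 3])


class TestScoreComparison:
    def test_identical_lists_no_shift(self):
        u, p = score_comparison([3, 5, 7, 9], [3, 5, 7, 9])
        assert p > 0.9

    def test_complete_separation_u_zero(self):
        u, _ = score_comparison([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_brute_force_pair_enumeration(self):
        a, b = [1, 2, 3], [2, 3, 4]
        u_brute = sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x, y in itertools.product(a, b)
        )
        u, _ = score_comparison(a, b)
        assert u == pytest.approx(u_brute)  # 2.0 by hand

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score_comparison([], [1.0])


class TestPrivacyUtilityTrend:
    def test_nonprivate_tstr_beats_private_on_average(self):
        # gradient noise costs signal: averaged over seeds, classifiers
        # trained on nonprivate synthetic data outperform private-trained
        # ones on the same real held-out split (a trend, not per-run)
        from dptrialsynth.acgan import TrainConfig, generate, train
        from dptrialsynth.cohort import split_train_test

        cohort = simulate_trial(TrialSimParams(n_participants=600, seed=10))
        train_c, test_c = split_train_test(cohort, 500, seed=11)
        nonprivate, private = [], []
        for seed in range(5):
            for is_private, store in ((False, nonprivate), (True, private)):
                cfg = TrainConfig(epochs=60, lot_size=50, private=is_private,
                                  noise_multiplier=7.0, clip_norm=1.0, seed=seed)
                ckpts, _ = train(train_c, cfg)
                syn = generate(ckpts[-1].generator, 500, seed=21)
                auroc = transfer_learning_eval(
                    syn, test_c, model_names=("logistic_regression",), seed=0
                )["logistic_regression"]["auroc"]
                store.append(auroc)
        assert np.mean(nonprivate) >= np.mean(private)


class TestReport:
    def test_full_report_round_trips(self, trial_cohort):
        train = trial_cohort.subset(range(400))
        test = trial_cohort.subset(range(400, 500))
        synthetic = simulate_trial(TrialSimParams(n_participants=300, seed=77))
        report = evaluate_cohorts(train, test, synthetic, seed=0)
        back = EvaluationReport.from_json(report.to_json())
        assert back == report
        assert -1.0 <= report.structure_spearman_rho <= 1.0
        for res in report.transfer_real.values():
            assert 0.0 <= res["auroc"] <= 1.0
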