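"""Ranking-SVM, preference scores, clinical matching and the IR Score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irscore import (
    ClinicalRecord,
    IRScoreModel,
    fit_ir_score_model,
    match_similar_patients,
    predict_ir_score,
    preference_from_ranks,
    preference_score,
    rank_samples,
    train_ranking_svm,
)
from irscore.ranking import RankingModel


def identity_model(k=1):
    w = np.zeros(k)
    w[0] = 1.0
    return RankingModel(w, [f"f{i}" for i in range(k)], np.zeros(k), np.ones(k),
                        1.0, 1.0)


class TestTrainRankingSVM:
    def test_separable_1d_perfect_training_accuracy(self):
        cases = np.array([[2.0], [3.0], [2.5]])
        ctrls = np.array([[0.0], [0.5], [1.0]])
        model = train_ranking_svm(cases, ctrls)
        assert model.training_pairwise_accuracy == 1.0
        assert model.weights[0] > 0

    def test_rank_order_invariant_to_feature_rescaling(self, rng):
        cases = rng.normal(1, 1, size=(10, 3))
        ctrls = rng.normal(0, 1, size=(10, 3))
        samples = rng.normal(0.5, 1, size=(8, 3))
        m1 = train_ranking_svm(cases, ctrls, seed=0)
        m2 = train_ranking_svm(cases * 10, ctrls * 10, seed=0)
        assert np.array_equal(rank_samples(m1, samples), rank_samples(m2, samples * 10))

    def test_degenerate_identical_features_rejected(self):
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="degenerate"):
            train_ranking_svm(X, X)

    def test_shuffled_labels_near_chance_held_out(self, rng):
        # no class signal: held-out pairwise ordering accuracy ~ 0.5
        train_a, train_b = rng.normal(size=(40, 4)), rng.normal(size=(40, 4))
        model = train_ranking_svm(train_a, train_b, seed=0)
        test_a, test_b = rng.normal(size=(300, 4)), rng.normal(size=(300, 4))
        acc = np.mean(model.score(test_a) > model.score(test_b))
        assert 0.40 <= acc <= 0.60

    def test_pairing_restricts_constraints(self, rng):
        cases = rng.normal(1, 1, size=(4, 2))
        ctrls = rng.normal(0, 1, size=(4, 2))
        model = train_ranking_svm(
            cases, ctrls,
            case_patients=np.array(["a", "a", "b", "b"]),
            control_patients=np.array(["ax", "ax", "bx", "bx"]),
            pairing=[("a", "ax"), ("b", "bx")],
        )
        assert model.weights.shape == (2,)


class TestRankSamples:
    def test_ranks_follow_scores(self):
        model = identity_model()
        ranks = rank_samples(model, np.array([[0.2], [0.9], [0.5]]))
        assert ranks.tolist() == [1, 3, 2]

    def test_ranks_are_permutation(self, rng):
        model = identity_model()
        ranks = rank_samples(model, rng.normal(size=(17, 1)))
        assert sorted(ranks.tolist()) == list(range(1, 18))

    def test_ties_stable_input_order(self):
        model = identity_model()
        ranks = rank_samples(model, np.array([[0.5], [0.5], [0.1]]))
        assert ranks.tolist() == [2, 3, 1]


class TestPreference:
    def test_top_ranks_give_npreference_one(self):
        r = preference_from_ranks(np.array([3, 4]), n2=2)
        assert (r.preference, r.preference_min, r.preference_max) == (7, 3, 7)
        assert r.npreference == 1.0

    def test_bottom_ranks_give_zero(self):
        r = preference_from_ranks(np.array([1, 2]), n2=2)
        assert r.npreference == 0.0

    def test_d_below_one_rejected(self):
        with pytest.raises(ValueError):
            preference_from_ranks(np.array([1, 2]), n2=2, d=0.5)

    def test_empty_set_rejected(self):
        model = identity_model()
        with pytest.raises(ValueError):
            preference_score(model, np.empty((0, 1)), np.array([[1.0]]))

    def test_equals_normalized_mannwhitney_u_at_d1(self, rng):
        for _ in range(50):
            n1, n2 = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            s1 = rng.normal(size=(n1, 1))
            s2 = rng.normal(size=(n2, 1))
            r = preference_score(identity_model(), s1, s2, d=1)
            u = sum(float(a) > float(b) for a in s1[:, 0] for b in s2[:, 0])
            assert r.npreference == pytest.approx(u / (n1 * n2))

    def test_symmetry_sums_to_one_without_ties(self, rng):
        for _ in range(20):
            s1 = rng.normal(size=(int(rng.integers(1, 6)), 1))
            s2 = rng.normal(size=(int(rng.integers(1, 6)), 1))
            a = preference_score(identity_model(), s1, s2).npreference
            b = preference_score(identity_model(), s2, s1).npreference
            assert a + b == pytest.approx(1.0)

    def test_fully_tied_sets_give_half(self):
        s = np.ones((3, 1))
        r = preference_score(identity_model(), s, s.copy())
        assert r.npreference == 0.5

    def test_d2_weights_high_ranks_more(self):
        # S1 at ranks {1, 4}, S2 at {2, 3}: U = 2 of 4 so d=1 gives 0.5,
        # but squared ranks reward holding the top rank
        r1 = preference_from_ranks(np.array([1, 4]), n2=2, d=1)
        r2 = preference_from_ranks(np.array([1, 4]), n2=2, d=2)
        assert r1.npreference == 0.5
        assert r2.npreference > 0.5


def record(pid, age, gsum, stage, recurrence, psa=8.0):
    return ClinicalRecord(pid, age, "white", None, None, gsum, stage, psa,
                          recurrence=recurrence)


class TestMatching:
    training = [
        record("c1", 60, 7, "T2b", True),
        record("c2", 70, 8, "T3a", True),
        record("n1", 60, 7, "T2b", False),
        record("n2", 55, 6, "T2a", False),
    ]

    def test_exact_match_returned(self):
        q = record("q", 60, 7, "T2b", None)
        case, ctrl = match_similar_patients(q, self.training)
        assert case.patient_id == "c1" and ctrl.patient_id == "n1"

    def test_equidistant_tie_lower_id(self):
        training = [record("cb", 62, 7, "T2b", True), record("ca", 58, 7, "T2b", True),
                    record("n1", 60, 7, "T2b", False)]
        q = record("q", 60, 7, "T2b", None)
        case, _ = match_similar_patients(q, training)
        assert case.patient_id == "ca"

    def test_invariant_to_age_rescaling(self):
        q = record("q", 63, 7, "T3a", None)
        base = match_similar_patients(q, self.training)
        doubled = [record(r.patient_id, r.age * 2, r.gleason_sum, r.stage,
                          r.recurrence) for r in self.training]
        q2 = record("q", 126, 7, "T3a", None)
        rescaled = match_similar_patients(q2, doubled)
        assert [m.patient_id for m in base] == [m.patient_id for m in rescaled]

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            match_similar_patients(record("q", 60, 7, "T2b", None),
                                   [record("c", 60, 7, "T2b", True)])


class TestIRScoreModel:
    @staticmethod
    def toy_training(rng, shift):
        """Patients with 1-D core features; cases shifted upward by `shift`."""
        records, cores = [], {}
        for i in range(12):
            rec = record(f"c{i}", 55 + i, 7, "T2b", True)
            records.append(rec)
            cores[rec.patient_id] = rng.normal(shift, 1, size=(3, 1))
        for i in range(12):
            rec = record(f"n{i}", 55 + i, 7, "T2b", False)
            records.append(rec)
            cores[rec.patient_id] = rng.normal(0, 1, size=(3, 1))
        return records, cores

    def test_probabilities_in_unit_interval(self, rng):
        records, cores = self.toy_training(rng, shift=1.5)
        model = fit_ir_score_model(records, cores, identity_model())
        for rec in records:
            s = predict_ir_score(rec, cores[rec.patient_id],
                                 [r for r in records if r.patient_id != rec.patient_id],
                                 cores, identity_model(), model)
            assert 0.0 < s < 1.0

    def test_degenerate_covariates_give_prevalence(self):
        records = [record(f"c{i}", 60, 7, "T2b", True) for i in range(3)] + \
                  [record(f"n{i}", 60, 7, "T2b", False) for i in range(5)]
        cores = {r.patient_id: np.ones((2, 1)) for r in records}
        model = fit_ir_score_model(records, cores, identity_model())
        assert model.predict(0.5, 0.5) == pytest.approx(3 / 8)

    def test_separable_cohort_orders_classes(self, rng):
        records, cores = self.toy_training(rng, shift=3.0)
        model = fit_ir_score_model(records, cores, identity_model())
        scores = {}
        for rec in records:
            scores[rec.patient_id] = predict_ir_score(
                rec, cores[rec.patient_id],
                [r for r in records if r.patient_id != rec.patient_id],
                cores, identity_model(), model)
        case_scores = [s for p, s in scores.items() if p.startswith("c")]
        ctrl_scores = [s for p, s in scores.items() if p.startswith("n")]
        assert np.mean(case_scores) > np.mean(ctrl_scores) + 0.2

    def test_repeatable(self, rng):
        records, cores = self.toy_training(rng, shift=1.0)
        model = fit_ir_score_model(records, cores, identity_model())
        q = records[0]
        rest = records[1:]
        s1 = predict_ir_score(q, cores[q.patient_id], rest, cores,
                              identity_model(), model)
        s2 = predict_ir_score(q, cores[q.patient_id], rest, cores,
                              identity_model(), model)
        assert s1 == s2
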