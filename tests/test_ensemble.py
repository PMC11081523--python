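import numpy as np
import pandas as pd
import pytest

from fragfocus.ensemble import (
    EnsembleModel,
    EvaluationMetrics,
    MemberSpec,
    TuningConfig,
    consensus_classify,
    default_member_specs,
    evaluate,
    load_model,
    negative_pool_fpr,
    save_model,
    split_train_test,
    tune_and_fit_member,
)
from helpers import FakeMember


def separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, 5)) + y[:, None] * 8.0
    return X, y


class TestSplit:
    def test_90_10_sizes(self):
        X = np.zeros((1000, 3))
        y = np.array([0] * 900 + [1] * 100)
        X_tr, X_te, y_tr, y_te = split_train_test(X, y, seed=0)
        assert len(X_tr) == 900 and len(X_te) == 100

    def test_same_seed_same_split(self):
        X, y = separable_data(100)
        a = split_train_test(X, y, seed=3)
        b = split_train_test(X, y, seed=3)
        assert np.array_equal(a[1], b[1]) and np.array_equal(a[3], b[3])

    def test_stratification(self):
        X = np.zeros((1000, 2))
        y = np.array([1] * 100 + [0] * 900)
        _, _, _, y_te = split_train_test(X, y, seed=1)
        assert abs(int(y_te.sum()) - 10) <= 1

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            split_train_test(np.zeros((20, 2)), np.zeros(20, dtype=int))


class TestTuning:
    def test_single_trial_is_selected(self):
        X, y = separable_data()
        spec = MemberSpec("logistic_linear", {"C": [0.37]}, preprocessing="standardize")
        _, best, log = tune_and_fit_member(spec, X, y, TuningConfig(n_trials=1, cv_folds=3))
        assert best == {"C": 0.37}
        assert len(log) == 1

    def test_separable_data_reaches_cv_precision_one(self):
        X, y = separable_data()
        spec = [s for s in default_member_specs() if s.algorithm == "logistic_linear"][0]
        _, _, log = tune_and_fit_member(spec, X, y, TuningConfig(n_trials=3, cv_folds=3, seed=1))
        assert max(e["objective"] for e in log) == 1.0

    def test_seeded_search_is_reproducible(self):
        X, y = separable_data()
        spec = [s for s in default_member_specs() if s.algorithm == "random_forest"][0]
        cfg = TuningConfig(n_trials=4, cv_folds=3, seed=5)
        _, best1, log1 = tune_and_fit_member(spec, X, y, cfg)
        _, best2, log2 = tune_and_fit_member(spec, X, y, cfg)
        assert best1 == best2
        assert [e["params"] for e in log1] == [e["params"] for e in log2]

    def test_empty_space_is_an_error(self):
        with pytest.raises(ValueError):
            tune_and_fit_member(MemberSpec("logistic_linear", {}), *separable_data(), TuningConfig())


class TestConsensus:
    @pytest.mark.parametrize("votes,threshold,expected", [(6, 6, True), (4, 4, True), (5, 6, False), (0, 1, False)])
    def test_threshold_rule(self, votes, threshold, expected):
        assert consensus_classify(votes, threshold) is expected

    def test_vector_form_and_monotonicity(self):
        votes = np.array([0, 2, 4, 6, 5, 3])
        sizes = [int(consensus_classify(votes, t).sum()) for t in range(1, 7)]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            consensus_classify(3, 0)


def fake_ensemble(prob_matrix, threshold=6):
    """An EnsembleModel whose members return fixed per-row probabilities."""
    members = {f"m{j}": FakeMember(probs=prob_matrix[:, j]) for j in range(prob_matrix.shape[1])}
    return EnsembleModel(members, {}, vote_threshold=threshold)


class TestVotesAndEvaluate:
    def test_vote_extremes(self):
        n = 4
        all_pos = fake_ensemble(np.ones((n, 6)))
        none_pos = fake_ensemble(np.zeros((n, 6)))
        X = np.zeros((n, 2))
        assert np.array_equal(all_pos.predict_votes(X), np.full(n, 6))
        assert np.array_equal(none_pos.predict_votes(X), np.zeros(n))

    def test_worked_confusion_example(self):
        # 3 true positives, 1 false positive -> precision 0.75
        probs = np.array([[0.9], [0.9], [0.9], [0.9], [0.1]] )
        model = fake_ensemble(np.repeat(probs, 6, axis=1), threshold=6)
        y = np.array([1, 1, 1, 0, 0])
        m, _ = evaluate(model, np.zeros((5, 2)), y)
        assert (m.tp, m.fp) == (3, 1)
        assert m.precision == 0.75

    def test_perfect_predictor_metrics(self):
        y = np.array([0, 0, 1, 1])
        member = FakeMember(probs=np.array([0.1, 0.2, 0.8, 0.9]))
        m, curves = evaluate(member, np.zeros((4, 2)), y)
        assert m.roc_auc == 1.0 and m.average_precision == 1.0
        assert "roc" in curves and "pr" in curves

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(42)
        n = 10_000
        y = np.array([0, 1] * (n // 2))
        member = FakeMember(probs=rng.random(n))
        m, _ = evaluate(member, np.zeros((n, 1)), y)
        assert m.roc_auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_auc_undefined(self):
        member = FakeMember(constant=0.9)
        m, curves = evaluate(member, np.zeros((5, 1)), np.ones(5, dtype=int))
        assert np.isnan(m.roc_auc)
        assert m.accuracy == 1.0
        assert curves == {}

    def test_metric_identities(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 500)
        member = FakeMember(probs=rng.random(500))
        m, _ = evaluate(member, np.zeros((500, 1)), y)
        assert abs(m.precision - m.tp / (m.tp + m.fp)) < 1e-12
        assert abs(m.recall - m.tp / (m.tp + m.fn)) < 1e-12
        assert abs(m.accuracy - (m.tp + m.tn) / 500) < 1e-12
        assert abs(m.fpr - m.fp / (m.fp + m.tn)) < 1e-12


class TestNegativePool:
    def test_fpr_table_non_increasing(self):
        rng = np.random.default_rng(2)
        probs = rng.random((200, 6))
        model = fake_ensemble(probs)
        table = negative_pool_fpr(model, np.zeros((200, 1)))
        vals = [table[t] for t in range(1, 7)]
        assert vals == sorted(vals, reverse=True)

    def test_unanimous_fpr_bounded_by_members(self):
        rng = np.random.default_rng(3)
        probs = rng.random((300, 6))
        model = fake_ensemble(probs)
        table = negative_pool_fpr(model, np.zeros((300, 1)))
        member_fprs = (probs >= 0.5).mean(axis=0)
        assert table[6] <= member_fprs.min() + 1e-12

    def test_empty_pool_error(self):
        with pytest.raises(ValueError):
            negative_pool_fpr(fake_ensemble(np.ones((1, 6))), np.zeros((0, 1)))


class TestTrainedEnsemble:
    def test_unanimous_dominance_on_test_split(self, trained):
        model, X_test, y_test = trained["model"], trained["X_test"], trained["y_test"]
        em, _ = evaluate(model, X_test, y_test)
        for est in model.members.values():
            mm, _ = evaluate(est, X_test, y_test)
            assert em.fp <= mm.fp

    def test_votes_in_range(self, trained):
        votes = trained["model"].predict_votes(trained["X_test"])
        assert votes.min() >= 0 and votes.max() <= 6

    def test_schema_mismatch_names_first_bad_column(self, trained):
        X = trained["X_test"].copy()
        X = X.rename(columns={"bit_0": "wrong_name"})
        with pytest.raises(ValueError, match="wrong_name"):
            trained["model"].predict_votes(X)

    def test_save_load_roundtrip_predictions(self, trained, tmp_path):
        path = tmp_path / "model.ffx"
        save_model(trained["model"], path)
        back = load_model(path)
        assert np.array_equal(
            back.predict_votes(trained["X_test"]), trained["model"].predict_votes(trained["X_test"])
        )
        assert back.feature_schema == trained["model"].feature_schema


def test_member_spec_validation():
    with pytest.raises(ValueError):
        MemberSpec("deep_dream", {})
    with pytest.raises(ValueError):
        TuningConfig(n_trials=0)
    with pytest.raises(ValueError):
        TuningConfig(cv_folds=1)
    with pytest.raises(ValueError):
        EnsembleModel({"a": None}, {}, vote_threshold=3)
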