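"""Metric learning to rank: scores, partial-order features, oracle, training."""

import itertools

import numpy as np
import pytest

import beatset as bs
from beatset.features import FeatureTable
from beatset.metric import Ranking, RankingInstance


def random_instance(rng, P=None, N=None, d=3):
    P = P or int(rng.integers(1, 4))
    N = N or int(rng.integers(1, 4))
    return RankingInstance(
        query=rng.normal(size=d),
        relevant=rng.normal(size=(P, d)),
        irrelevant=rng.normal(size=(N, d)),
    )


def random_metric(rng, d=3):
    a = rng.normal(size=(d, d))
    return a + a.T  # symmetric, not necessarily PSD: fine for oracle algebra


def brute_psi(instance, ranking):
    """Direct pair-sum evaluation of the partial-order feature."""
    P, N = instance.n_relevant, instance.n_irrelevant
    pos = {item: p for p, item in enumerate(ranking.order.tolist())}
    q = instance.query
    psi = np.zeros((len(q), len(q)))
    for i in range(P):
        phi_i = -np.outer(q - instance.relevant[i], q - instance.relevant[i])
        for j in range(N):
            phi_j = -np.outer(q - instance.irrelevant[j], q - instance.irrelevant[j])
            sign = 1.0 if pos[i] < pos[P + j] else -1.0
            psi += sign * (phi_i - phi_j)
    return psi / (P * N)


def ground_truth(instance):
    return Ranking(order=np.arange(instance.n_relevant + instance.n_irrelevant))


class TestMahalScore:
    def test_zero_for_identical_points(self):
        rng = np.random.default_rng(0)
        w = random_metric(rng, 4)
        q = rng.normal(size=4)
        assert bs.mahal_score(w, q, q) == 0.0

    def test_identity_metric_is_negative_squared_euclidean(self):
        assert bs.mahal_score(np.eye(2), np.zeros(2), np.ones(2)) == -2.0

    def test_diagonal_metric_hand_value(self):
        w = np.diag([2.0, 1.0])
        assert bs.mahal_score(w, np.array([1.0, 0.0]), np.zeros(2)) == -2.0

    def test_dimension_mismatch_errors(self):
        with pytest.raises(ValueError):
            bs.mahal_score(np.eye(2), np.zeros(2), np.zeros(3))


class TestPartialOrderFeature:
    def test_matches_direct_pair_summation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            inst = random_instance(rng)
            n = inst.n_relevant + inst.n_irrelevant
            ranking = Ranking(order=rng.permutation(n))
            psi = bs.partial_order_feature(inst, ranking)
            assert np.allclose(psi, brute_psi(inst, ranking), atol=1e-12)
            assert np.allclose(psi, psi.T)

    def test_within_block_permutation_leaves_psi_unchanged(self):
        rng = np.random.default_rng(2)
        inst = random_instance(rng, P=3, N=3)
        base = bs.partial_order_feature(inst, ground_truth(inst))
        shuffled = Ranking(order=np.array([2, 0, 1, 5, 3, 4]))
        assert np.allclose(bs.partial_order_feature(inst, shuffled), base)

    def test_full_reversal_negates_ground_truth(self):
        rng = np.random.default_rng(3)
        inst = random_instance(rng, P=2, N=3)
        gt = bs.partial_order_feature(inst, ground_truth(inst))
        reversed_psi = bs.partial_order_feature(
            inst, Ranking(order=np.array([2, 3, 4, 0, 1]))
        )
        assert np.allclose(reversed_psi, -gt)

    def test_item_mismatch_errors(self):
        rng = np.random.default_rng(4)
        inst = random_instance(rng, P=2, N=2)
        with pytest.raises(ValueError):
            bs.partial_order_feature(inst, Ranking(order=np.array([0, 1, 2])))


class TestRankingScoreSort:
    def test_separated_clusters_rank_relevant_first(self):
        inst = RankingInstance(
            query=np.zeros(2),
            relevant=np.array([[0.1, 0.0], [0.0, 0.2]]),
            irrelevant=np.array([[5.0, 5.0], [6.0, 5.0]]),
        )
        order = bs.ranking_score_sort(np.eye(2), inst).order
        assert set(order[:2].tolist()) == {0, 1}

    def test_maximizes_inner_product_over_all_rankings(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            inst = random_instance(rng)
            w = random_metric(rng)
            best = bs.ranking_score_sort(w, inst)
            got = np.sum(w * bs.partial_order_feature(inst, best))
            n = inst.n_relevant + inst.n_irrelevant
            enum = max(
                np.sum(w * bs.partial_order_feature(inst, Ranking(np.array(p))))
                for p in itertools.permutations(range(n))
            )
            assert got == pytest.approx(enum, abs=1e-9)

    def test_zero_metric_keeps_input_order(self):
        rng = np.random.default_rng(6)
        inst = random_instance(rng, P=2, N=2)
        assert bs.ranking_score_sort(np.zeros((3, 3)), inst).order.tolist() == [0, 1, 2, 3]


class TestQueryLoss:
    @pytest.mark.parametrize(
        "order,k,expected",
        [
            ([0, 1, 2, 3], 3, 0.0),           # first relevant on top
            ([2, 3, 0, 1], 3, 1.0 - 1.0 / 3),  # r = 3 within k
            ([2, 3, 4, 0, 1], 3, 1.0),         # r = 4 beyond k -> S = 0
        ],
    )
    def test_truncated_reciprocal_rank(self, order, k, expected):
        rng = np.random.default_rng(7)
        inst = random_instance(rng, P=2, N=len(order) - 2)
        assert bs.query_loss(inst, Ranking(np.array(order)), k) == pytest.approx(expected)

    def test_invalid_k(self):
        rng = np.random.default_rng(8)
        inst = random_instance(rng, P=1, N=1)
        with pytest.raises(ValueError):
            bs.query_loss(inst, ground_truth(inst), k=0)


class TestSeparationOracle:
    def test_margin_dominant_limit_returns_zero_loss(self):
        inst = RankingInstance(
            query=np.zeros(2),
            relevant=np.array([[0.1, 0.0], [0.0, 0.1]]),
            irrelevant=np.array([[10.0, 0.0], [0.0, 11.0]]),
        )
        ranking, violation = bs.separation_oracle(100.0 * np.eye(2), inst, k=3)
        assert bs.query_loss(inst, ranking, 3) == 0.0
        assert violation <= 0.0

    def test_tied_pair_prefers_half_loss(self):
        inst = RankingInstance(
            query=np.zeros(1), relevant=np.array([[1.0]]), irrelevant=np.array([[-1.0]])
        )
        ranking, violation = bs.separation_oracle(np.zeros((1, 1)), inst, k=3)
        assert ranking.order.tolist() == [1, 0]  # irrelevant first
        assert violation == pytest.approx(0.5)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            inst = random_instance(rng)
            w = random_metric(rng)
            k = int(rng.integers(1, 5))
            ranking, violation = bs.separation_oracle(w, inst, k)
            objective = bs.query_loss(inst, ranking, k) + np.sum(
                w * bs.partial_order_feature(inst, ranking)
            )
            n = inst.n_relevant + inst.n_irrelevant
            enum = max(
                bs.query_loss(inst, Ranking(np.array(p)), k)
                + np.sum(w * bs.partial_order_feature(inst, Ranking(np.array(p))))
                for p in itertools.permutations(range(n))
            )
            assert objective == pytest.approx(enum, abs=1e-9)
            gt_inner = np.sum(w * bs.partial_order_feature(inst, ground_truth(inst)))
            assert violation == pytest.approx(objective - gt_inner, abs=1e-9)


class TestFactorize:
    def test_distance_identity_on_random_psd(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(5, 5))
        w = a @ a.T
        l = bs.factorize(w)
        for _ in range(10):
            u, v = rng.normal(size=5), rng.normal(size=5)
            quad = (u - v) @ w @ (u - v)
            proj = np.sum((l @ u - l @ v) ** 2)
            assert proj == pytest.approx(quad, rel=1e-6)

    def test_identity_metric_preserves_distances(self):
        l = bs.factorize(np.eye(3))
        u, v = np.array([1.0, 2.0, 3.0]), np.zeros(3)
        assert np.sum((l @ u - l @ v) ** 2) == pytest.approx(np.sum((u - v) ** 2))

    def test_rank_deficient_metric_drops_rows(self):
        l = bs.factorize(np.diag([4.0, 0.0]), rank_tol=1e-8)
        assert l.shape == (1, 2)
        assert abs(l[0, 0]) == pytest.approx(2.0)

    def test_indefinite_matrix_rejected(self):
        with pytest.raises(ValueError, match="not PSD"):
            bs.factorize(np.diag([1.0, -0.5]))


class TestTrain:
    def test_separable_two_class_converges_with_zero_training_loss(self):
        X = np.array([[0.0], [0.2], [0.4], [5.0], [5.2], [5.4]])
        labels = np.array(list("aaabbb"), dtype=object)
        model = bs.train(FeatureTable(matrix=X, labels=labels))
        assert model.converged
        assert model.final_violation <= 1e-4
        # every leave-one-out query ranks its own class on top
        for q in range(len(X)):
            corpus = np.delete(X, q, axis=0)
            rel = np.delete(labels == labels[q], q)
            inst = RankingInstance(X[q], corpus[rel], corpus[~rel])
            ranking = bs.ranking_score_sort(model.w, inst)
            assert bs.query_loss(inst, ranking, model.k) == 0.0

    def test_history_is_monotone_and_metric_psd(self, study_model):
        h = np.asarray(study_model.history)
        assert len(h) >= 1
        assert np.all(np.diff(h) >= -1e-7 * (1.0 + np.abs(h[:-1])))
        assert np.linalg.eigvalsh(study_model.w).min() >= -1e-9
        recon = study_model.l.T @ study_model.l
        denom = max(np.linalg.norm(study_model.w), 1e-30)
        assert np.linalg.norm(recon - study_model.w) / denom < 1e-6

    def test_learned_metric_improves_distorted_clusters(self, study):
        """Mean Rank-1 with the learned metric >= Euclidean, single and set-based."""
        assert study["mlr_single"].mean() >= study["baseline"].mean()
        assert study["mlr_mbd"].mean() >= study["mbd"].mean()

    def test_regularizers_agree_on_rank1(self):
        # Compared in the C-regime where both programs are non-degenerate:
        # the trace penalty charges linearly at w = 0, so on unit-scale
        # features it needs a larger trade-off C than the Frobenius
        # penalty before any metric is worth learning.
        from dataclasses import replace

        from beatset.evaluation import ExperimentConfig, evaluate

        features = bs.simulate_feature_clusters(
            bs.default_cluster_spec(), [40] * 4, seed=11
        )
        base = ExperimentConfig(
            n_trials=3, set_size=10, small_class_set_size={}, seed=4, metric="mlr"
        )
        r_frob = evaluate(
            features,
            replace(base, mlr_params={"C": 100.0, "regularizer": "frobenius", "max_iter": 60}),
        )
        r_trace = evaluate(
            features,
            replace(base, mlr_params={"C": 100.0, "regularizer": "trace", "max_iter": 60}),
        )
        assert abs(r_frob.rank1 - r_trace.rank1) < 2.0

    def test_insufficient_classes_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="2 classes"):
            bs.train(FeatureTable(matrix=X, labels=np.array(list("aaaa"), dtype=object)))

    def test_hitting_max_iter_warns_not_raises(self, study_training_table):
        with pytest.warns(RuntimeWarning, match="max_iter"):
            model = bs.train(study_training_table, max_iter=1)
        assert not model.converged

    def test_model_json_round_trip(self, tmp_path, study_model):
        path = str(tmp_path / "metric.json")
        study_model.to_json(path)
        loaded = type(study_model).from_json(path)
        assert np.allclose(loaded.w, study_model.w)
        assert np.allclose(loaded.l, study_model.l)
        assert loaded.history == list(study_model.history)
        assert loaded.converged == study_model.converged
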