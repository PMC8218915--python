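import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from frl import (ExpressionMatrix, FRLConfig, TrainConfig, choose_pace,
                 fit_logistic, kfold_split, logistic_cost, logistic_gradient,
                 rfe, run_frl, sigmoid)
from frl.synthetic_data import SimConfig, simulate
from oracles import cross_entropy_oracle, greedy_backward_elimination


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid(0.0) == 0.5

    @given(st.floats(-500, 500))
    def test_antisymmetry(self, j):
        assert sigmoid(j) + sigmoid(-j) == pytest.approx(1.0, abs=1e-12)

    def test_no_overflow_far_in_the_tails(self):
        hi = sigmoid(710.0)
        lo = sigmoid(-710.0)
        assert np.isfinite(hi) and hi < 1.0
        assert np.isfinite(lo) and lo > 0.0


class TestLogisticCost:
    def test_perfect_prediction_limit(self):
        y = np.array([1, 0, 1])
        assert logistic_cost(y.astype(float), y) == pytest.approx(0.0, abs=1e-10)

    def test_uninformative_half_probabilities(self):
        assert logistic_cost([0.5, 0.5], [1, 0]) == pytest.approx(np.log(2))

    def test_frozen_oracle_value(self):
        # frozen from the term-by-term oracle:
        # mean(-ln 0.8, -ln 0.7) = 0.2899092476...
        a, y = [0.8, 0.3], [1, 0]
        assert cross_entropy_oracle(a, y) == pytest.approx(0.2899092476, abs=1e-9)
        assert logistic_cost(a, y) == pytest.approx(0.2899092476, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            logistic_cost([0.5], [1, 0])


class TestGradient:
    def test_matches_central_differences(self, rng):
        for _ in range(30):
            m, p = rng.integers(4, 20), rng.integers(1, 8)
            X = rng.normal(size=(m, p))
            y = rng.integers(0, 2, size=m).astype(float)
            w = rng.normal(size=p)
            b = float(rng.normal())
            l2 = float(rng.uniform(0, 0.5))
            gw, gb = logistic_gradient(X, y, w, b, l2)

            def cost(wv, bv):
                a = 1 / (1 + np.exp(-(X @ wv + bv)))
                return (np.mean(-(y * np.log(a) + (1 - y) * np.log(1 - a)))
                        + l2 * (wv @ wv) / 2)

            eps = 1e-6
            for i in range(p):
                e = np.zeros(p)
                e[i] = eps
                fd = (cost(w + e, b) - cost(w - e, b)) / (2 * eps)
                assert gw[i] == pytest.approx(fd, rel=1e-6, abs=1e-9)
            fdb = (cost(w, b + eps) - cost(w, b - eps)) / (2 * eps)
            assert gb == pytest.approx(fdb, rel=1e-6, abs=1e-9)


class TestFitLogistic:
    def test_separable_data_fits_perfectly_with_monotone_cost(self):
        X = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_logistic(X, y)
        trace = np.asarray(model.training_trace)
        assert np.all(np.diff(trace) <= 1e-9)
        assert np.array_equal(model.predict(X), y)

    def test_uninformative_features_stay_near_prior(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.integers(0, 2, size=60)
        model = fit_logistic(X, y, TrainConfig(l2=1.0))
        prior = max(y.mean(), 1 - y.mean())
        acc = np.mean(model.predict(X) == y)
        assert np.all(np.abs(model.weights) < 1.0)
        assert acc <= prior + 0.25

    def test_duplicating_all_samples_leaves_optimum_unchanged(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, size=20)
        hp = TrainConfig(tol=1e-12, max_iter=10000, l2=0.5)
        m1 = fit_logistic(X, y, hp)
        m2 = fit_logistic(np.vstack([X, X]), np.r_[y, y], hp)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.ones((4, 2)), np.ones(4))


class TestChoosePace:
    @pytest.mark.parametrize("d1,expected", [
        (2500, 5), (1500, 3), (800, 2),
        (2001, 5), (2000, 3), (1001, 3), (1000, 2), (1, 2),
    ])
    def test_dimensional_bands(self, d1, expected):
        assert choose_pace(d1) == expected

    @given(st.integers(1, 10000))
    def test_band_property(self, d1):
        pace = choose_pace(d1)
        if d1 > 2000:
            assert pace == 5
        elif d1 > 1000:
            assert pace == 3
        else:
            assert pace == 2


class TestKfoldSplit:
    def test_balanced_eight_samples_four_folds(self):
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        folds = kfold_split(8, labels, 4, seed=0)
        assert all(len(f) == 2 for f in folds)
        for f in folds:
            assert sorted(labels[f]) == [0, 1]

    def test_partition_property(self, rng):
        labels = rng.integers(0, 2, size=23)
        while len(np.unique(labels)) < 2 or min(np.bincount(labels)) < 3:
            labels = rng.integers(0, 2, size=23)
        folds = kfold_split(23, labels, 3, seed=5)
        joined = np.concatenate(folds)
        assert sorted(joined) == list(range(23))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_seed_reproducibility_and_variation(self):
        labels = np.array([0] * 10 + [1] * 10)
        a = kfold_split(20, labels, 4, seed=7)
        b = kfold_split(20, labels, 4, seed=7)
        c = kfold_split(20, labels, 4, seed=8)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_small_class_named_in_error(self):
        labels = np.array([0] * 10 + [1] * 2)
        with pytest.raises(ValueError, match="class 1"):
            kfold_split(12, labels, 4, seed=0)


def _random_feature_matrix(rng, n_samples=24, n_features=6):
    values = rng.normal(size=(n_features, n_samples))
    labels = np.r_[np.zeros(n_samples // 2, int), np.ones(n_samples // 2, int)]
    return ExpressionMatrix([f"F{i}" for i in range(n_features)],
                            [f"s{j}" for j in range(n_samples)],
                            values, labels=labels)


class TestRfe:
    def test_pace_one_matches_greedy_oracle(self, rng):
        """Elimination order of pace-1 RFE is step-for-step identical to an
        exhaustive greedy backward-elimination oracle (unrelated optimizer,
        same importance rule) on small instances."""
        from frl.embedded_layer import kfold_split as ks
        hp = TrainConfig(l2=1.0, tol=1e-13, max_iter=8000)
        for trial in range(5):
            mat = _random_feature_matrix(rng)
            path = rfe(mat, pace=1, K=3, floor=1, hp=hp, seed=trial)
            impl_order = []
            for a, b in zip(path.steps[:-1], path.steps[1:]):
                impl_order.extend(set(a.feature_ids) - set(b.feature_ids))
            folds = ks(mat.n_samples, mat.labels, 3, seed=trial)
            oracle_order, survivor = greedy_backward_elimination(
                mat.values.T, mat.labels.astype(float), mat.gene_ids, folds)
            assert impl_order == oracle_order
            assert path.steps[-1].feature_ids == survivor

    def test_sizes_decrease_by_pace_with_short_last_step(self, rng):
        mat = _random_feature_matrix(rng, n_features=11)
        path = rfe(mat, pace=3, K=3, floor=2, seed=0)
        sizes = [len(s.feature_ids) for s in path.steps]
        assert sizes == [11, 8, 5, 2]

    def test_already_at_floor_is_single_step(self, rng):
        mat = _random_feature_matrix(rng, n_features=4)
        path = rfe(mat, pace=2, K=3, floor=4, seed=0)
        assert len(path.steps) == 1
        assert path.selected_features == mat.gene_ids

    def test_planted_genes_survive_elimination(self):
        cfg = SimConfig(n_genes=200, n_samples_per_class=(20, 20),
                        n_informative=5, effect_size=3.0, seed=11)
        mat, planted = simulate(cfg)
        path = rfe(mat, pace=2, K=4, floor=10, seed=11, force_floor=True)
        assert set(planted) <= set(path.selected_features)

    def test_best_step_maximizes_cv_accuracy(self, rng):
        mat = _random_feature_matrix(rng, n_features=8)
        path = rfe(mat, pace=1, K=3, floor=1, seed=2)
        best_acc = path.steps[path.best_step].cv_accuracy
        assert best_acc == max(s.cv_accuracy for s in path.steps)
        # ties resolve to the smallest surviving set (the latest tied step)
        tied = [i for i, s in enumerate(path.steps)
                if s.cv_accuracy == best_acc]
        assert path.best_step == tied[-1]


class TestRunFrl:
    def test_pipeline_contract_on_synthetic_data(self):
        mat, planted = simulate(SimConfig(n_genes=800,
                                          n_samples_per_class=(20, 20),
                                          n_informative=10, effect_size=2.5,
                                          seed=3))
        cfg = FRLConfig(target_dim=30, seed=3)
        ranking, path, report = run_frl(mat, cfg)
        assert ranking.d1 < 800
        assert len(path.selected_features) == 30
        assert report.tp + report.tn + report.fp + report.fn == mat.n_samples
        assert report.distance_matrix.shape == (40, 40)

    def test_same_seed_reproduces_selection(self):
        mat, _ = simulate(SimConfig(n_genes=400, n_samples_per_class=(16, 16),
                                    n_informative=8, seed=9))
        cfg = FRLConfig(target_dim=20, seed=9)
        r1 = run_frl(mat, cfg)
        r2 = run_frl(mat, cfg)
        assert r1[1].selected_features == r2[1].selected_features
        assert r1[2].metrics_dict() == r2[2].metrics_dict()

    def test_cv_choice_mode_when_target_dim_unset(self):
        mat, _ = simulate(SimConfig(n_genes=300, n_samples_per_class=(15, 15),
                                    n_informative=6, seed=4))
        cfg = FRLConfig(target_dim=None, floor=5, seed=4)
        _, path, _ = run_frl(mat, cfg)
        best = path.steps[path.best_step]
        assert best.cv_accuracy == max(s.cv_accuracy for s in path.steps)
        assert len(path.selected_features) >= 5
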