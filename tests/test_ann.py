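"""Network predictor: forward pass, Levenberg--Marquardt training,
restarts, splits, deviations, architecture search and checkpoints."""

import numpy as np
import pytest

from jamqspr.ann import (
    DeviationReport,
    NetworkArchitecture,
    NetworkWeights,
    SplitSpec,
    TrainingConfig,
    architecture_search,
    deviation_report,
    forward,
    init_network,
    load_checkpoint,
    multi_restart_train,
    random_split,
    save_checkpoint,
    train_lm,
)

FAST = TrainingConfig(tolerance=1e-10, max_iterations=80, restarts=1, seed=0)


class TestArchitecture:
    def test_parameter_count(self):
        arch = NetworkArchitecture((10, 30, 10, 3))
        assert arch.n_parameters == 10 * 30 + 30 + 30 * 10 + 10 + 10 * 3 + 3

    def test_output_layer_fixed(self):
        with pytest.raises(ValueError):
            NetworkArchitecture((10, 5, 2))

    def test_layer_count_bounds(self):
        with pytest.raises(ValueError):
            NetworkArchitecture((10, 3))
        with pytest.raises(ValueError):
            NetworkArchitecture((10, 5, 5, 5, 3))


class TestInitNetwork:
    def test_reference_shapes(self):
        w = init_network(NetworkArchitecture((10, 30, 10, 3)), 0)
        assert w.w_input.shape == (30, 10)
        assert w.w_hidden.shape == (10, 30)
        assert w.w_output.shape == (3, 10)
        assert [b.shape for b in w.biases] == [(30,), (10,), (3,)]

    def test_seed_determinism(self):
        arch = NetworkArchitecture((4, 5, 3))
        a = init_network(arch, 7)
        b = init_network(arch, 7)
        c = init_network(arch, 8)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)
        assert any((wa != wc).any() for wa, wc in zip(a.weights, c.weights))

    def test_uniform_bounds_and_zero_biases(self):
        w = init_network(NetworkArchitecture((6, 20, 3)), 3)
        assert all(np.all(np.abs(m) <= 0.5) for m in w.weights)
        assert all(np.all(b == 0) for b in w.biases)


class TestForward:
    def test_zero_network_outputs_zero(self):
        w = init_network(NetworkArchitecture((4, 5, 3)), 0)
        for m in w.weights:
            m[:] = 0.0
        np.testing.assert_array_equal(forward(w, np.ones(4)), np.zeros(3))

    def test_output_bias_pass_through(self):
        w = init_network(NetworkArchitecture((4, 5, 3)), 0)
        for m in w.weights:
            m[:] = 0.0
        w.biases[-1][:] = [1.0, 2.0, 3.0]
        np.testing.assert_array_equal(forward(w, np.ones(4)), [1.0, 2.0, 3.0])

    def test_loop_based_oracle(self):
        arch = NetworkArchitecture((5, 7, 4, 3))
        w = init_network(arch, 9)
        rng = np.random.default_rng(0)
        for b in w.biases:
            b[:] = rng.normal(size=b.shape)
        x = rng.normal(size=5)

        h = x
        for W, b in zip(w.weights[:-1], w.biases[:-1]):
            h = np.array(
                [np.tanh(sum(W[j, i] * h[i] for i in range(len(h))) + b[j])
                 for j in range(W.shape[0])]
            )
        y_ref = np.array(
            [sum(w.weights[-1][k, j] * h[j] for j in range(len(h)))
             + w.biases[-1][k] for k in range(3)]
        )
        np.testing.assert_allclose(forward(w, x), y_ref, atol=1e-12)

    def test_hidden_activations_bounded(self):
        from jamqspr.ann import _forward_full

        w = init_network(NetworkArchitecture((3, 8, 3)), 2)
        X = np.random.default_rng(1).normal(scale=100, size=(20, 3))
        _, acts = _forward_full(w, X)
        # tanh saturates to exactly +/-1.0 in floating point
        assert np.all(np.abs(acts[1]) <= 1.0)

    def test_shape_mismatch_rejected(self):
        w = init_network(NetworkArchitecture((4, 5, 3)), 0)
        with pytest.raises(ValueError):
            forward(w, np.ones(7))


class TestTrainLM:
    def test_zero_residual_start_terminates(self):
        arch = NetworkArchitecture((2, 4, 3))
        w0 = init_network(arch, 5)
        X = np.random.default_rng(2).normal(size=(30, 2))
        Y = forward(w0, X)
        w, history, status = train_lm(w0, X, Y, FAST)
        assert history[0] == pytest.approx(0.0, abs=1e-20)
        assert len(history) <= 2
        for a, b in zip(w0.weights, w.weights):
            np.testing.assert_allclose(a, b, atol=1e-6)

    def test_linear_map_teacher_student(self):
        # 1-5-5-3 student fit to 50 points of a linear 3-output map
        X = np.linspace(-1, 1, 50)[:, None]
        Y = np.hstack([2 * X, -X + 0.5, 0.3 * X])
        cfg = TrainingConfig(tolerance=1e-12, max_iterations=300, restarts=1, seed=0)
        w, history, _ = train_lm(
            init_network(NetworkArchitecture((1, 5, 5, 3)), 3), X, Y, cfg
        )
        rmse = np.sqrt(((forward(w, X) - Y) ** 2).mean())
        assert rmse < 1e-3

    def test_accepted_loss_history_monotone(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        Y = rng.normal(size=(40, 3))
        _, history, _ = train_lm(
            init_network(NetworkArchitecture((3, 6, 3)), 1), X, Y, FAST
        )
        assert all(b <= a for a, b in zip(history, history[1:]))

    def test_non_finite_data_rejected(self):
        w0 = init_network(NetworkArchitecture((2, 3, 3)), 0)
        X = np.array([[1.0, np.inf]])
        with pytest.raises(ValueError):
            train_lm(w0, X, np.ones((1, 3)), FAST)


class TestDeviationReport:
    def test_zero_iff_exact(self):
        p = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        rep = deviation_report(p, p)
        np.testing.assert_array_equal(rep.average, 0.0)
        rep2 = deviation_report(p, p + 0.001)
        assert np.all(rep2.average > 0)

    def test_single_point_arithmetic(self):
        rep = deviation_report([[10.0, 10.0, 10.0]], [[9.0, 10.0, 10.0]])
        assert rep.average[0] == pytest.approx(10.0)  # 100*|10-9|/10

    def test_average_and_max(self):
        pred = np.array([[100.0, 1, 1], [100.0, 1, 1]])
        exp = np.array([[99.0, 1, 1], [97.0, 1, 1]])
        rep = deviation_report(pred, exp)
        assert rep.average[0] == pytest.approx(2.0)
        assert rep.maximum[0] == pytest.approx(3.0)
        assert rep.overall_max >= rep.overall_average

    def test_experimental_denominator_option(self):
        rep = deviation_report([[10.0, 1, 1]], [[8.0, 1, 1]],
                               denominator="experimental")
        assert rep.average[0] == pytest.approx(25.0)

    def test_zero_predicted_rejected(self):
        with pytest.raises(ZeroDivisionError):
            deviation_report([[0.0, 1, 1]], [[1.0, 1, 1]])


class TestRandomSplit:
    def test_reference_counts(self):
        learn, test, pred = random_split(680, SplitSpec(585, 55, 40, seed=1))
        assert (len(learn), len(test), len(pred)) == (585, 55, 40)

    def test_partition_properties(self):
        learn, test, pred = random_split(100, SplitSpec(70, 20, 10, seed=3))
        parts = [set(learn), set(test), set(pred)]
        assert parts[0] | parts[1] | parts[2] == set(range(100))
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_seed_reproducibility_and_variation(self):
        a = random_split(50, SplitSpec(30, 10, 10, seed=5))
        b = random_split(50, SplitSpec(30, 10, 10, seed=5))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        others = [random_split(50, SplitSpec(30, 10, 10, seed=s))[0] for s in range(10)]
        assert any(not np.array_equal(a[0], o) for o in others)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            random_split(99, SplitSpec(70, 20, 10))


def _toy_teacher_data(n=120, seed=0):
    # inputs live on a 3-D subspace of the 10-D feature space, like the
    # strongly collinear jam covariates, so modest n suffices to generalise
    rng = np.random.default_rng(seed)
    Z = rng.uniform(-1, 1, size=(n, 3))
    X = Z @ (rng.normal(size=(3, 10)) / np.sqrt(3))
    teacher = init_network(NetworkArchitecture((10, 30, 10, 3)), seed + 1)
    teacher.biases[-1][:] = 5.0  # keep outputs away from zero
    Y = forward(teacher, X) + rng.normal(0, 0.01, size=(n, 3))
    i, j = n - 60, n - 30
    return X[:i], Y[:i], X[i:j], Y[i:j], X[j:], Y[j:]


class TestMultiRestart:
    def test_single_restart_equals_train_lm(self):
        Xl, Yl, Xt, Yt, *_ = _toy_teacher_data()
        cfg = TrainingConfig(tolerance=1e-6, max_iterations=30, restarts=1, seed=4)
        best, idx, reports = multi_restart_train(
            NetworkArchitecture((10, 30, 10, 3)), Xl, Yl, Xt, Yt, cfg
        )
        seed0 = int(np.random.default_rng(4).integers(0, 2**31 - 1, 1)[0])
        w_direct, _, _ = train_lm(
            init_network(NetworkArchitecture((10, 30, 10, 3)), seed0), Xl, Yl, cfg
        )
        assert idx == 0 and len(reports) == 1
        for a, b in zip(best.weights, w_direct.weights):
            np.testing.assert_array_equal(a, b)

    def test_winner_has_lowest_max_deviation(self):
        Xl, Yl, Xt, Yt, *_ = _toy_teacher_data(seed=2)
        cfg = TrainingConfig(tolerance=1e-6, max_iterations=15, restarts=3, seed=9)
        _, idx, reports = multi_restart_train(
            NetworkArchitecture((10, 10, 3)), Xl, Yl, Xt, Yt, cfg
        )
        assert reports[idx].overall_max == min(r.overall_max for r in reports)

    def test_fixed_master_seed_reproducible_winner(self):
        Xl, Yl, Xt, Yt, *_ = _toy_teacher_data(seed=3)
        cfg = TrainingConfig(tolerance=1e-6, max_iterations=10, restarts=3, seed=21)
        arch = NetworkArchitecture((10, 10, 3))
        _, idx1, _ = multi_restart_train(arch, Xl, Yl, Xt, Yt, cfg)
        _, idx2, _ = multi_restart_train(arch, Xl, Yl, Xt, Yt, cfg)
        assert idx1 == idx2


class TestArchitectureSearch:
    def test_single_candidate_rank_one(self):
        Xl, Yl, Xt, Yt, Xp, Yp = _toy_teacher_data(seed=5)
        cfg = TrainingConfig(tolerance=1e-6, max_iterations=10, restarts=1, seed=0)
        res = architecture_search([(10, 10, 3)], Xl, Yl, Xt, Yt, Xp, Yp, cfg)
        assert len(res) == 1 and res[0]["rank"] == 1

    def test_teacher_architecture_beats_tiny_student(self):
        Xl, Yl, Xt, Yt, Xp, Yp = _toy_teacher_data(n=200, seed=6)
        cfg = TrainingConfig(tolerance=1e-8, max_iterations=80, restarts=2, seed=1)
        res = architecture_search(
            [(10, 2, 3), (10, 30, 10, 3)], Xl, Yl, Xt, Yt, Xp, Yp, cfg
        )
        assert str(res[0]["architecture"]) == "10-30-10-3"

    def test_ranking_is_permutation(self):
        Xl, Yl, Xt, Yt, Xp, Yp = _toy_teacher_data(seed=7)
        cfg = TrainingConfig(tolerance=1e-6, max_iterations=8, restarts=1, seed=2)
        cands = [(10, 5, 3), (10, 8, 3), (10, 4, 4, 3)]
        res = architecture_search(cands, Xl, Yl, Xt, Yt, Xp, Yp, cfg)
        assert sorted(str(r["architecture"]) for r in res) == sorted(
            "-".join(map(str, c)) for c in cands
        )
        assert [r["rank"] for r in res] == [1, 2, 3]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            architecture_search([], *[np.ones((2, 2))] * 6,
                                TrainingConfig(restarts=1))


class TestCheckpoint:
    def test_round_trip_exact(self, tmp_path):
        w = init_network(NetworkArchitecture((10, 30, 10, 3)), 13)
        rng = np.random.default_rng(0)
        for b in w.biases:
            b[:] = rng.normal(size=b.shape)
        path = tmp_path / "net.txt"
        save_checkpoint(w, path)
        w2 = load_checkpoint(path)
        assert w2.architecture.layers == (10, 30, 10, 3)
        for a, b in zip(w.weights + w.biases, w2.weights + w2.biases):
            np.testing.assert_array_equal(a, b)

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "junk.txt"
        path.write_text("not a checkpoint\n")
        with pytest.raises(ValueError):
            load_checkpoint(path)
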