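from dataclasses import replace

import numpy as np
import pytest

from fedglioma.federated import (CLConfig, ClientState, FLConfig,
                                 CentralClassifier, FederatedClassifier,
                                 ServerState, _client_rng, _sgd_epochs,
                                 convergence_round, local_update_etfeddyn,
                                 local_update_fedavg, run_central,
                                 run_federated, server_update_etfeddyn,
                                 server_update_fedavg)
from fedglioma.network import PRESETS
from fedglioma.params import ParameterSet
from fedglioma.preprocess import SliceDataset


def scalar(v) -> ParameterSet:
    return ParameterSet({"w": np.array([float(v)])})


def toy_dataset(n=1) -> SliceDataset:
    return SliceDataset(images=np.zeros((n, 2, 2, 2)),
                        labels=np.zeros(n, dtype=int),
                        patient_ids=np.array(["p"] * n, dtype=object),
                        views=np.array(["axial"] * n, dtype=object),
                        slice_indices=np.zeros(n, dtype=int))


def quadratic(b):
    """L = 0.5 (w - b)^2 as a pluggable objective."""
    def fn(w, images, labels):
        val = 0.5 * float((w["w"][0] - b) ** 2)
        return val, ParameterSet({"w": w["w"] - b})
    return fn


class TestLocalUpdateToy:
    def test_single_gradient_step_closed_form(self):
        """One full-batch step on L=0.5(w-b)^2 from w=0 gives w = eta*b."""
        w, _ = _sgd_epochs(scalar(0.0), toy_dataset(), None, epochs=1,
                           batch_size=8, lr=0.1, weight_decay=0.0,
                           loss_params=None, rng=_client_rng(0, 0),
                           grad_fn=quadratic(1.0))
        assert w["w"][0] == pytest.approx(0.1)

    def test_proximal_term_pulls_toward_center(self):
        """With alpha=10, b=1, w_c=0 the fixed point of the update direction
        is w = b / (1 + alpha)."""
        alpha, b = 10.0, 1.0
        w = scalar(0.0)
        anchor = scalar(0.0)
        for _ in range(400):
            w, _ = _sgd_epochs(w, toy_dataset(), None, epochs=1,
                               batch_size=8, lr=0.05, weight_decay=0.0,
                               loss_params=None, rng=_client_rng(0, 0),
                               correction=anchor.zeros_like(), anchor=anchor,
                               alpha=alpha, grad_fn=quadratic(b))
        assert w["w"][0] == pytest.approx(b / (1 + alpha), abs=1e-6)

    def test_alpha_zero_with_zero_correction_is_plain_sgd(self):
        kw = dict(epochs=2, batch_size=4, lr=0.07, weight_decay=0.01,
                  loss_params=None, grad_fn=quadratic(0.5))
        plain, _ = _sgd_epochs(scalar(0.2), toy_dataset(6), None,
                               rng=_client_rng(1, 0), **kw)
        feddyn, _ = _sgd_epochs(scalar(0.2), toy_dataset(6), None,
                                rng=_client_rng(1, 0),
                                correction=scalar(0.0).zeros_like(),
                                anchor=scalar(0.0), alpha=0.0, **kw)
        assert plain.equal(feddyn)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            _sgd_epochs(scalar(0.0), toy_dataset(0), None, epochs=1,
                        batch_size=4, lr=0.1, weight_decay=0.0,
                        loss_params=None, rng=_client_rng(0, 0),
                        grad_fn=quadratic(1.0))


class TestServerUpdates:
    def test_fixed_point_of_central_update(self):
        """If every client returns w_c exactly, (w_c, h_c) never move."""
        server = ServerState(weights=scalar(1.5),
                             accumulator=scalar(0.0).zeros_like())
        for _ in range(5):
            server = server_update_etfeddyn(server, [scalar(1.5),
                                                     scalar(1.5)])
        assert server.weights["w"][0] == pytest.approx(1.5)
        assert server.accumulator["w"][0] == pytest.approx(0.0)
        assert server.round == 5

    def test_scalar_hand_evaluation(self):
        """h=0, w_c=1.0, mean local = 1.5, N=1 -> h'=-0.5, w_c'=2.0."""
        server = ServerState(weights=scalar(1.0),
                             accumulator=scalar(0.0).zeros_like())
        server = server_update_etfeddyn(server, [scalar(1.5)])
        assert server.accumulator["w"][0] == pytest.approx(-0.5)
        assert server.weights["w"][0] == pytest.approx(2.0)

    def test_mean_of_identical_clients(self):
        server = ServerState(weights=scalar(0.0),
                             accumulator=scalar(0.0).zeros_like())
        server = server_update_etfeddyn(server, [scalar(2.0)] * 4)
        # w_bar = 2, h = (0-2)/4 = -0.5, w_c = 2.5
        assert server.weights["w"][0] == pytest.approx(2.5)

    def test_fedavg_weighted_mean(self):
        assert server_update_fedavg([scalar(0.0), scalar(4.0)],
                                    [1, 3])["w"][0] == pytest.approx(3.0)
        assert server_update_fedavg([scalar(7.0)], [5])["w"][0] == 7.0
        assert server_update_fedavg([scalar(1.0), scalar(3.0)],
                                    [2, 2])["w"][0] == pytest.approx(2.0)

    def test_empty_client_list_rejected(self):
        with pytest.raises(ValueError):
            server_update_fedavg([], [])


class TestOrchestration:
    def test_single_client_fedavg_bitwise_equals_central(self,
                                                         two_client_data):
        clients, _ = two_client_data
        ds = clients["a"]
        model_cfg = PRESETS["tiny"]
        fl_cfg = FLConfig(rounds=3, local_epochs=2, batch_size=16,
                          learning_rate=0.01, weight_decay=0.001,
                          algorithm="fedavg", seed=11)
        _, w_fl = run_federated({"a": ds}, fl_cfg, model_cfg)
        cl_cfg = CLConfig(batch_size=16, learning_rate=0.01,
                          weight_decay=0.001, iterations=6, seed=11)
        _, w_cl = run_central(ds, cl_cfg, model_cfg)
        assert w_fl.equal(w_cl)

    def test_zero_rounds_returns_initial_weights(self, two_client_data):
        clients, _ = two_client_data
        cfg = FLConfig(rounds=0, seed=1)
        from fedglioma.network import init_params
        hist, w = run_federated(clients, cfg, PRESETS["tiny"])
        assert len(hist) == 0
        assert w.equal(init_params(PRESETS["tiny"], seed=1,
                                   dtype=np.float32))

    def test_fedavg_k0_returns_broadcast_weights(self, two_client_data):
        clients, _ = two_client_data
        cfg = FLConfig(rounds=2, local_epochs=0, algorithm="fedavg", seed=1)
        from fedglioma.network import init_params
        _, w = run_federated(clients, cfg, PRESETS["tiny"])
        assert w.equal(init_params(PRESETS["tiny"], seed=1,
                                   dtype=np.float32))

    def test_history_length_and_determinism(self, two_client_data):
        clients, tests = two_client_data
        cfg = FLConfig(rounds=2, local_epochs=1, batch_size=16, seed=3)
        h1, w1 = run_federated(clients, cfg, PRESETS["tiny"], tests)
        h2, w2 = run_federated(clients, cfg, PRESETS["tiny"], tests)
        assert len(h1) == 2
        assert w1.equal(w2)
        assert h1.pooled_test_accuracy == h2.pooled_test_accuracy

    def test_client_order_invariance(self, two_client_data):
        clients, _ = two_client_data
        cfg = FLConfig(rounds=2, local_epochs=1, batch_size=16, seed=3)
        _, w_ab = run_federated(dict(clients), cfg, PRESETS["tiny"])
        reversed_clients = dict(reversed(list(clients.items())))
        _, w_ba = run_federated(reversed_clients, cfg, PRESETS["tiny"])
        assert w_ab.equal(w_ba)

    def test_central_loss_decreases_on_separable_data(self,
                                                      two_client_data):
        clients, _ = two_client_data
        from fedglioma.losses import CE
        finals, initials = [], []
        for seed in range(5):
            cfg = CLConfig(batch_size=16, learning_rate=0.01,
                           iterations=10, loss=CE, seed=seed)
            hist, _ = run_central(clients["a"], cfg, PRESETS["tiny"])
            losses = [r["train_loss"]["pooled"] for r in hist.records]
            initials.append(losses[0])
            finals.append(losses[-1])
        assert np.median(finals) < np.median(initials)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            run_central(SliceDataset(np.zeros((0, 2, 2, 2)),
                                     np.zeros(0, int),
                                     np.array([], object),
                                     np.array([], object),
                                     np.zeros(0, int)),
                        CLConfig(), PRESETS["tiny"])


class TestConvergenceRound:
    def test_constant_history(self):
        assert convergence_round([0.8] * 6) == 1

    def test_worked_example(self):
        assert convergence_round([0.5, 0.6, 0.9, 0.91, 0.9],
                                 delta=0.02) == 3

    def test_never_stable_returns_t(self):
        acc = list(np.linspace(0.1, 0.9, 9))
        assert convergence_round(acc, delta=0.01) == 9


class TestModelObjects:
    def test_fit_returns_results_with_summary(self, two_client_data):
        clients, tests = two_client_data
        cfg = FLConfig(rounds=1, local_epochs=1, batch_size=16, seed=0)
        model = FederatedClassifier(clients, cfg, test_sets=tests)
        results = model.fit()
        text = results.summary()
        assert "etfeddyn" in text and "rounds completed" in text
        rep = results.evaluate_slices(tests["a"])
        assert rep.accuracy is not None
        probs = results.predict(tests["a"].images[:4])
        assert probs.shape == (4, 2)

    def test_checkpoint_roundtrip(self, tmp_path, two_client_data):
        clients, _ = two_client_data
        cfg = FLConfig(rounds=1, local_epochs=1, batch_size=16, seed=0)
        results = FederatedClassifier(clients, cfg).fit()
        path = tmp_path / "ckpt.h5"
        results.save(path)
        loaded, header = ParameterSet.from_hdf5(path)
        assert loaded.equal(results.params)
        assert header["conv_layers_per_stream"] == 7
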