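"""Federated training: dynamically regularized local/central updates
(EtFedDyn), the FedAvg baseline, and the pooled central-learning reference.

The federation minimizes the average of the clients' focal-loss objectives
without pooling data.  Each communication round broadcasts the central
weights w_c, every client runs K local epochs of minibatch SGD, and the
server aggregates.  For the dynamic-regularization algorithm the local update
direction is

    g = grad(L(w)) + weight_decay * w - c_i + alpha * (w - w_c)

where c_i is the client's gradient-correction state (initialized to zero and
updated after each round as c_i <- c_i - alpha * (w_i - w_c)) and alpha the
regularization strength; the proximal term pulls local iterates toward the
central model, countering client drift on heterogeneous data.  The server
keeps an accumulator h and sets

    h <- h + (1/N) (w_c - mean_i w_i),      w_c <- mean_i w_i - h.

A sign-flipped "as printed" variant of the local direction
(-grad(L) - c_i - alpha * (w_c - w)) is retained behind
``FLConfig.eq4_as_printed`` for auditability; it ascends the loss at alpha=0
and is off by default.  FedAvg runs plain local SGD and aggregates by
sample-size-weighted averaging.  All clients participate every round;
"parallel" clients are simulated sequentially with independent per-client
generators, so results do not depend on execution order.

The module also provides the statsmodels-style front door:
:class:`FederatedClassifier` / :class:`CentralClassifier` objects built from
client slice datasets, whose ``fit()`` returns a :class:`FitResults` carrying
the final weights, the round-by-round history, ``summary()`` and evaluation
helpers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import network as net
from .evaluate import (confusion, evaluate_patient_level, evaluate_slice_level,
                       metrics, predict_slices)
from .losses import CE, FocalParams, focal_loss, focal_loss_grad
from .network import ModelConfig, PRESETS
from .params import ParameterSet
from .preprocess import SliceDataset, augment

__all__ = [
    "FLConfig", "CLConfig", "ClientState", "ServerState", "TrainingHistory",
    "loss_and_grads", "local_update_etfeddyn", "local_update_fedavg",
    "server_update_etfeddyn", "server_update_fedavg", "run_federated",
    "run_central", "convergence_round", "FederatedClassifier",
    "CentralClassifier", "FitResults",
]


@dataclass(frozen=True)
class FLConfig:
    """Federated training hyper-parameters (defaults follow the study setup:
    T=50 rounds, K=5 local epochs, batch 50, lr 0.01, alpha 0.01,
    weight decay 0.001, no learning-rate decay across rounds)."""

    rounds: int = 50
    local_epochs: int = 5
    batch_size: int = 50
    learning_rate: float = 0.01
    alpha: float = 0.01
    weight_decay: float = 0.001
    algorithm: str = "etfeddyn"
    loss: FocalParams = field(default_factory=FocalParams)
    seed: int = 0
    eq4_as_printed: bool = False
    use_augmentation: bool = False
    #: global gradient-norm clip on the data-loss gradient; tames the
    #: occasional exploding step through the quadratic (bilinear) head.
    clip_grad_norm: float | None = 1.0

    def __post_init__(self):
        if self.rounds < 0 or self.local_epochs < 0 or self.batch_size < 1:
            raise ValueError("rounds/local_epochs >= 0, batch_size >= 1")
        if self.learning_rate < 0 or self.alpha < 0 or self.weight_decay < 0:
            raise ValueError("rates must be nonnegative")
        if self.algorithm not in ("etfeddyn", "fedavg"):
            raise ValueError("algorithm must be 'etfeddyn' or 'fedavg'")


@dataclass(frozen=True)
class CLConfig:
    """Pooled central-learning hyper-parameters (batch 50, weight decay 1e-4,
    lr 1e-3, 50 epochs by default)."""

    batch_size: int = 50
    weight_decay: float = 0.0001
    learning_rate: float = 0.001
    iterations: int = 50
    loss: FocalParams = field(default_factory=FocalParams)
    seed: int = 0
    use_augmentation: bool = False
    clip_grad_norm: float | None = 1.0

    def __post_init__(self):
        if self.batch_size < 1 or self.iterations < 0 \
                or self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("invalid central-learning configuration")


@dataclass
class ClientState:
    client_id: str
    weights: ParameterSet
    correction: ParameterSet          # gradient-correction state c_i
    dataset: SliceDataset
    rng: np.random.Generator
    last_train_loss: float | None = None


@dataclass
class ServerState:
    weights: ParameterSet             # w_c
    accumulator: ParameterSet         # h_c, initialized to zeros
    round: int = 0


@dataclass
class TrainingHistory:
    records: list = field(default_factory=list)

    def append(self, rec: dict) -> None:
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def pooled_test_accuracy(self) -> list:
        return [r["test_accuracy"].get("pooled") for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"round": r["round"], "displacement": r["displacement"]}
            for cid, v in r["train_loss"].items():
                row[f"train_loss_{cid}"] = v
            for cid, v in r["test_accuracy"].items():
                row[f"test_acc_{cid}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as f:
            for r in self.records:
                f.write(json.dumps(r) + "\n")


# ---------------------------------------------------------------------------
# loss + gradients for one minibatch
# ---------------------------------------------------------------------------

def loss_and_grads(params: ParameterSet, config: ModelConfig,
                   images: np.ndarray, labels: np.ndarray,
                   loss_params: FocalParams):
    """Mean focal loss of a batch and its gradient w.r.t. every parameter."""
    probs, cache, _ = net.forward(params, config, images, return_cache=True)
    p1 = probs[:, 1]
    loss = focal_loss(p1, labels, loss_params)
    dp1 = focal_loss_grad(p1, labels, loss_params)
    dlogits = net.softmax_prob_grad_to_logits(probs, dp1)
    grads = net.backward(params, config, cache,
                         dlogits.astype(probs.dtype, copy=False))
    return loss, grads


def _client_rng(seed: int, index) -> np.random.Generator:
    """Independent per-client stream; index may be an int or a stable id."""
    if not isinstance(index, int):
        index = abs(hash(str(index))) % (2 ** 31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), index]))


def _sgd_epochs(weights: ParameterSet, dataset: SliceDataset,
                model_config: ModelConfig, *, epochs: int, batch_size: int,
                lr: float, weight_decay: float, loss_params: FocalParams,
                rng: np.random.Generator, use_augmentation: bool = False,
                correction: ParameterSet | None = None,
                anchor: ParameterSet | None = None, alpha: float = 0.0,
                eq4_as_printed: bool = False,
                clip_grad_norm: float | None = None,
                grad_fn=None):
    """K epochs of minibatch steps from ``weights``; returns (w, mean loss).

    ``grad_fn(w, images, labels)`` -> (loss, grads) defaults to the network
    objective; tests plug closed-form toy objectives through the same path.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("client dataset is empty")
    w = weights.copy()
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            images = dataset.images[idx]
            if use_augmentation:
                images = np.stack([augment(im, rng) for im in images])
            if grad_fn is not None:
                loss, grads = grad_fn(w, images, dataset.labels[idx])
            else:
                loss, grads = loss_and_grads(w, model_config, images,
                                             dataset.labels[idx], loss_params)
            losses.append(loss)
            if clip_grad_norm is not None:
                gnorm = grads.norm()
                if gnorm > clip_grad_norm:
                    grads = grads * (clip_grad_norm / gnorm)
            g = grads + weight_decay * w
            if alpha > 0 or correction is not None:
                c = correction if correction is not None else w.zeros_like()
                if eq4_as_printed:
                    # sign convention exactly as printed; ascends at alpha=0
                    g = -1.0 * g - c - alpha * (anchor - w)
                else:
                    g = g - c + alpha * (w - anchor)
            w = w - lr * g
    return w, float(np.mean(losses)) if losses else float("nan")


# ---------------------------------------------------------------------------
# local / server updates
# ---------------------------------------------------------------------------

def local_update_etfeddyn(client: ClientState, w_c: ParameterSet,
                          cfg: FLConfig,
                          model_config: ModelConfig) -> ClientState:
    """One round of dynamically-regularized local training from w_c."""
    w, mean_loss = _sgd_epochs(
        w_c, client.dataset, model_config, epochs=cfg.local_epochs,
        batch_size=cfg.batch_size, lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay, loss_params=cfg.loss, rng=client.rng,
        use_augmentation=cfg.use_augmentation, correction=client.correction,
        anchor=w_c, alpha=cfg.alpha, eq4_as_printed=cfg.eq4_as_printed,
        clip_grad_norm=cfg.clip_grad_norm)
    client.weights = w
    client.correction = client.correction - cfg.alpha * (w - w_c)
    client.last_train_loss = mean_loss
    return client


def local_update_fedavg(client: ClientState, w_c: ParameterSet,
                        cfg: FLConfig,
                        model_config: ModelConfig) -> ClientState:
    """Plain local SGD (with weight decay) from w_c; no correction/proximal."""
    if cfg.local_epochs == 0:
        client.weights = w_c.copy()
        client.last_train_loss = float("nan")
        return client
    w, mean_loss = _sgd_epochs(
        w_c, client.dataset, model_config, epochs=cfg.local_epochs,
        batch_size=cfg.batch_size, lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay, loss_params=cfg.loss, rng=client.rng,
        use_augmentation=cfg.use_augmentation,
        clip_grad_norm=cfg.clip_grad_norm)
    client.weights = w
    client.last_train_loss = mean_loss
    return client


def server_update_etfeddyn(server: ServerState,
                           local_weights: list[ParameterSet]) -> ServerState:
    """h <- h + (1/N)(w_c - mean w_i); w_c <- mean w_i - h; round += 1."""
    if not local_weights:
        raise ValueError("server update requires at least one client")
    w_bar = ParameterSet.mean(local_weights)
    server.accumulator = server.accumulator \
        + (1.0 / len(local_weights)) * (server.weights - w_bar)
    server.weights = w_bar - server.accumulator
    server.round += 1
    return server


def server_update_fedavg(local_weights: list[ParameterSet],
                         client_sizes: list[int]) -> ParameterSet:
    """Sample-size-weighted average of client weights."""
    if not local_weights:
        raise ValueError("server update requires at least one client")
    return ParameterSet.mean(local_weights, weights=[float(s) for s
                                                     in client_sizes])


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _make_clients(client_datasets: dict, init: ParameterSet,
                  cfg: FLConfig) -> list[ClientState]:
    # rng streams are keyed by the client's rank in sorted-id order, so
    # results are independent of the order clients are supplied in
    ranks = {cid: i for i, cid in enumerate(sorted(map(str,
                                                       client_datasets)))}
    clients = []
    for cid, ds in client_datasets.items():
        if len(ds) == 0:
            raise ValueError(f"client {cid!r} has an empty dataset")
        clients.append(ClientState(
            client_id=str(cid), weights=init.copy(),
            correction=init.zeros_like(), dataset=ds,
            rng=_client_rng(cfg.seed, ranks[str(cid)])))
    return clients


def _round_eval(params, model_config, test_sets) -> dict:
    accs = {}
    if not test_sets:
        return accs
    all_preds, all_labels = [], []
    for cid, ds in test_sets.items():
        preds, _ = predict_slices(params, model_config, ds.images)
        accs[cid] = metrics(confusion(preds, ds.labels)).accuracy
        all_preds.append(preds)
        all_labels.append(ds.labels)
    pooled = confusion(np.concatenate(all_preds), np.concatenate(all_labels))
    accs["pooled"] = metrics(pooled).accuracy
    return accs


def run_federated(client_datasets: dict, cfg: FLConfig,
                  model_config: ModelConfig,
                  test_sets: dict | None = None,
                  init: ParameterSet | None = None):
    """T communication rounds of broadcast -> local updates -> aggregation.

    ``client_datasets``: mapping client id -> SliceDataset.  Returns
    (TrainingHistory, final central ParameterSet).
    """
    if not client_datasets:
        raise ValueError("need at least one client")
    if init is None:
        init = net.init_params(model_config, seed=cfg.seed, dtype=np.float32)
    clients = _make_clients(client_datasets, init, cfg)
    server = ServerState(weights=init.copy(),
                         accumulator=init.zeros_like(), round=0)
    history = TrainingHistory()
    for t in range(1, cfg.rounds + 1):
        w_prev = server.weights.copy()
        for client in clients:
            if cfg.algorithm == "etfeddyn":
                local_update_etfeddyn(client, w_prev, cfg, model_config)
            else:
                local_update_fedavg(client, w_prev, cfg, model_config)
        local_weights = [c.weights for c in clients]
        if cfg.algorithm == "etfeddyn":
            server_update_etfeddyn(server, local_weights)
        else:
            server.weights = server_update_fedavg(
                local_weights, [len(c.dataset) for c in clients])
            server.round += 1
        history.append({
            "round": t,
            "train_loss": {c.client_id: c.last_train_loss for c in clients},
            "test_accuracy": _round_eval(server.weights, model_config,
                                         test_sets),
            "displacement": (server.weights - w_prev).norm(),
        })
    return history, server.weights


def run_central(pooled: SliceDataset, cfg: CLConfig,
                model_config: ModelConfig, test_sets: dict | None = None,
                init: ParameterSet | None = None):
    """Train the identical architecture on the pooled data (CL reference)."""
    if len(pooled) == 0:
        raise ValueError("pooled training set is empty")
    if init is None:
        init = net.init_params(model_config, seed=cfg.seed, dtype=np.float32)
    w = init.copy()
    rng = _client_rng(cfg.seed, 0)
    history = TrainingHistory()
    for it in range(1, cfg.iterations + 1):
        w, mean_loss = _sgd_epochs(
            w, pooled, model_config, epochs=1, batch_size=cfg.batch_size,
            lr=cfg.learning_rate, weight_decay=cfg.weight_decay,
            loss_params=cfg.loss, rng=rng,
            use_augmentation=cfg.use_augmentation,
            clip_grad_norm=cfg.clip_grad_norm)
        history.append({
            "round": it, "train_loss": {"pooled": mean_loss},
            "test_accuracy": _round_eval(w, model_config, test_sets),
            "displacement": float("nan"),
        })
    return history, w


def convergence_round(history, delta: float = 0.02) -> int:
    """Smallest round t whose test accuracy — and every later round's — lies
    within ``delta`` of the final-round accuracy; T if never stable earlier.
    """
    if isinstance(history, TrainingHistory):
        acc = history.pooled_test_accuracy
    else:
        acc = list(history)
    if not acc or any(a is None for a in acc):
        raise ValueError("history has no pooled test accuracy")
    acc = np.asarray(acc, dtype=float)
    final = acc[-1]
    for t in range(1, len(acc) + 1):
        if np.all(np.abs(acc[t - 1:] - final) <= delta):
            return t
    return len(acc)


# ---------------------------------------------------------------------------
# Model / Results front door
# ---------------------------------------------------------------------------

@dataclass
class FitResults:
    """Outcome of a federated or central fit: final weights, per-round
    history, and evaluation/summary helpers."""

    params: ParameterSet
    history: TrainingHistory
    model_config: ModelConfig
    train_config: object

    def evaluate_slices(self, dataset: SliceDataset):
        return evaluate_slice_level(self.params, self.model_config, dataset)

    def evaluate_patients(self, scans, n_per_view: int = 5):
        return evaluate_patient_level(self.params, self.model_config, scans,
                                      n_per_view=n_per_view)

    def predict(self, images: np.ndarray):
        return net.forward(self.params, self.model_config, images)

    def convergence_round(self, delta: float = 0.02) -> int:
        return convergence_round(self.history, delta)

    def save(self, path) -> None:
        desc, _ = net.build_model(self.model_config)
        self.params.to_hdf5(path, header=desc)

    def plot_history(self, ax=None):
        """Train-loss / test-accuracy curves over communication rounds."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        frame = self.history.to_frame()
        for col in frame.columns:
            if col.startswith("train_loss_"):
                ax.plot(frame["round"], frame[col], "--",
                        label=col.replace("train_loss_", "loss "))
        acc = self.history.pooled_test_accuracy
        if acc and acc[0] is not None:
            ax.plot(frame["round"], acc, label="pooled test accuracy")
        ax.set_xlabel("communication round")
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        cfg = self.train_config
        lines = ["Federated/central classifier fit",
                 "=" * 40,
                 f"architecture parameters : {self.params.n_parameters}",
                 f"rounds completed        : {len(self.history)}"]
        if isinstance(cfg, FLConfig):
            lines += [f"algorithm               : {cfg.algorithm}",
                      f"local epochs / round    : {cfg.local_epochs}",
                      f"alpha (dyn. reg.)       : {cfg.alpha}"]
        loss = cfg.loss
        lines.append(f"loss                    : focal(beta={loss.beta}, "
                     f"gamma={loss.gamma})")
        if self.history.records:
            last = self.history.records[-1]
            for cid, v in last["train_loss"].items():
                lines.append(f"final train loss [{cid:>8}]: {v:.4f}")
            for cid, v in last["test_accuracy"].items():
                lines.append(f"final test acc   [{cid:>8}]: {v:.4f}")
            acc = self.history.pooled_test_accuracy
            if acc and acc[0] is not None:
                lines.append(f"convergence round (2%)  : "
                             f"{convergence_round(self.history)}")
        return "\n".join(lines)


def _default_model_config(datasets) -> ModelConfig:
    size = next(iter(datasets.values())).images.shape[-1]
    for preset in PRESETS.values():
        if preset.input_size == size:
            return preset
    return replace(PRESETS["tiny"], input_size=size)


class FederatedClassifier:
    """Two-stream slice classifier trained across clients without data pooling.

    Parameters
    ----------
    client_datasets : dict
        Mapping client id -> training :class:`SliceDataset`.
    config : FLConfig
        Federated optimization settings (algorithm, rounds, alpha, loss...).
    model_config : ModelConfig, optional
        Architecture; inferred from the image size via presets if omitted.
    test_sets : dict, optional
        Per-client test slice datasets evaluated after every round.
    """

    def __init__(self, client_datasets: dict, config: FLConfig = FLConfig(),
                 model_config: ModelConfig | None = None,
                 test_sets: dict | None = None):
        if not client_datasets:
            raise ValueError("need at least one client dataset")
        self.client_datasets = client_datasets
        self.config = config
        self.model_config = (model_config if model_config is not None
                             else _default_model_config(client_datasets))
        self.test_sets = test_sets

    def fit(self, init: ParameterSet | None = None) -> FitResults:
        history, params = run_federated(self.client_datasets, self.config,
                                        self.model_config, self.test_sets,
                                        init=init)
        return FitResults(params=params, history=history,
                          model_config=self.model_config,
                          train_config=self.config)


class CentralClassifier:
    """The pooled central-learning reference on the identical architecture."""

    def __init__(self, pooled: SliceDataset, config: CLConfig = CLConfig(),
                 model_config: ModelConfig | None = None,
                 test_sets: dict | None = None):
        self.pooled = pooled
        self.config = config
        self.model_config = (model_config if model_config is not None
                             else _default_model_config({"pooled": pooled}))
        self.test_sets = test_sets

    def fit(self, init: ParameterSet | None = None) -> FitResults:
        history, params = run_central(self.pooled, self.config,
                                      self.model_config, self.test_sets,
                                      init=init)
        return FitResults(params=params, history=history,
                          model_config=self.model_config,
                          train_config=self.config)
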