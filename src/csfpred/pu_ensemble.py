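"""Positive-unlabeled bagging ensemble of small feed-forward classifiers.

The unlabeled pool U is shuffled and partitioned into T disjoint equal-size
subsets; each is paired with an equally sized random sample of the positive
pool P to form a balanced binary training set (positives labelled 1,
unlabeled 0). T identical feed-forward networks (ReLU hidden layers with
dropout, a 2-unit linear output, softmax probability of the positive unit)
are trained independently with mini-batch Adam on the mean binary
cross-entropy. A query protein's probability is the average over the models
whose training data exclude it (out-of-bag aggregation); for an unlabeled
training protein under disjoint partitioning that is exactly T-1 models.
Proteins unseen during training average all T models. A protein is called
positive when its probability strictly exceeds the decision threshold.

Default hyperparameters: T=16, three hidden layers of 128 units, dropout 0.1,
batch size 32, Adam learning rate 0.001, 20 epochs, threshold 0.5.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np

logger = logging.getLogger(__name__)

_CLIP = 1e-7  # probability clipping in the loss


@dataclass
class EnsembleConfig:
    input_dim: int
    T: int = 16
    hidden_layers: list = field(default_factory=lambda: [128, 128, 128])
    dropout: float = 0.1
    batch_size: int = 32
    learning_rate: float = 0.001
    epochs: int = 20
    seed: int = 0
    threshold: float = 0.5


# ---------------------------------------------------------------------------
# single network
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """Per-layer weights/biases; the last layer is the 2-unit linear output."""

    weights: list
    biases: list

    def shapes(self):
        return [w.shape for w in self.weights]


def init_parameters(input_dim: int, hidden_layers: list, rng: np.random.Generator) -> ModelParameters:
    """He-normal weights, zero biases; shapes chain input -> hidden -> 2."""
    dims = [input_dim] + list(hidden_layers) + [2]
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return ModelParameters(weights, biases)


def forward(params: ModelParameters, x: np.ndarray, train_mode: bool = False,
            dropout: float = 0.0, rng: np.random.Generator | None = None,
            return_cache: bool = False):
    """Probability of the positive class for a batch (or single vector).

    Hidden layers: h = max(0, W.h + b), with inverted dropout when
    ``train_mode``. Output: 2-unit linear layer, softmax with max-subtraction;
    the positive class is the second output unit.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.weights[0].shape[0]:
        raise ValueError(
            f"input dimension {x.shape[1]} != expected {params.weights[0].shape[0]}")
    h = x
    cache = {"acts": [x], "masks": []}
    for w, b in zip(params.weights[:-1], params.biases[:-1]):
        h = np.maximum(0.0, h @ w + b)
        if train_mode and dropout > 0:
            mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * mask
            cache["masks"].append(mask)
        else:
            cache["masks"].append(None)
        cache["acts"].append(h)
    o = h @ params.weights[-1] + params.biases[-1]
    o = o - o.max(axis=1, keepdims=True)
    e = np.exp(o)
    probs = e / e.sum(axis=1, keepdims=True)
    p_pos = probs[:, 1]
    if return_cache:
        cache["probs"] = probs
        return p_pos, cache
    return p_pos if p_pos.shape[0] > 1 else float(p_pos[0])


def loss(probabilities, labels) -> float:
    """Mean binary cross-entropy, probabilities clipped to [eps, 1-eps]."""
    p = np.clip(np.asarray(probabilities, dtype=float), _CLIP, 1.0 - _CLIP)
    y = np.asarray(labels, dtype=float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class _Adam:
    def __init__(self, params: ModelParameters, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(w) for w in params.weights + params.biases]
        self.v = [np.zeros_like(w) for w in params.weights + params.biases]

    def step(self, params: ModelParameters, grads: list):
        self.t += 1
        tensors = params.weights + params.biases
        for i, (p, g) in enumerate(zip(tensors, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _backward(params: ModelParameters, cache: dict, y: np.ndarray) -> list:
    """Gradients of mean softmax cross-entropy wrt weights then biases."""
    n = len(y)
    onehot = np.zeros((n, 2))
    onehot[np.arange(n), y.astype(int)] = 1.0
    delta = (cache["probs"] - onehot) / n
    grads_w = [None] * len(params.weights)
    grads_b = [None] * len(params.biases)
    for layer in range(len(params.weights) - 1, -1, -1):
        a = cache["acts"][layer]
        grads_w[layer] = a.T @ delta
        grads_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = delta @ params.weights[layer].T
            mask = cache["masks"][layer - 1]
            if mask is not None:
                delta = delta * mask
            delta = delta * (cache["acts"][layer] > 0)
    return grads_w + grads_b


def train_model(x: np.ndarray, y: np.ndarray, config: EnsembleConfig,
                seed: int) -> tuple[ModelParameters, list]:
    """Train one network with mini-batch Adam; returns parameters and the
    per-epoch training-loss trace."""
    rng = np.random.default_rng(seed)
    params = init_parameters(config.input_dim, config.hidden_layers, rng)
    opt = _Adam(params, config.learning_rate)
    n = len(y)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            _, cache = forward(params, x[idx], train_mode=True,
                               dropout=config.dropout, rng=rng, return_cache=True)
            grads = _backward(params, cache, y[idx])
            opt.step(params, grads)
        p = forward(params, x, train_mode=False)
        history.append(loss(np.atleast_1d(p), y))
    return params, history


class MLPClassifier:
    """Single-network convenience wrapper (fit / predict_proba), used as the
    fast surrogate model inside recursive feature elimination."""

    def __init__(self, hidden_layers=(128, 128, 128), dropout=0.1, batch_size=32,
                 learning_rate=0.001, epochs=20, seed=0):
        self.hidden_layers = list(hidden_layers)
        self.dropout = dropout
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.seed = seed
        self.params_: ModelParameters | None = None

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        cfg = EnsembleConfig(input_dim=x.shape[1], T=1, hidden_layers=self.hidden_layers,
                             dropout=self.dropout, batch_size=self.batch_size,
                             learning_rate=self.learning_rate, epochs=self.epochs,
                             seed=self.seed)
        self.params_, self.history_ = train_model(x, np.asarray(y), cfg, self.seed)
        return self

    def predict_proba(self, x):
        p = np.atleast_1d(forward(self.params_, x))
        return p


# ---------------------------------------------------------------------------
# bagging
# ---------------------------------------------------------------------------

@dataclass
class MembershipIndex:
    """Which positive / unlabeled protein ids each model was trained on."""

    positive: list  # list of T id lists
    unlabeled: list  # list of T id lists (pairwise disjoint)
    dropped: list  # unlabeled remainder ids excluded from all training

    def models_excluding(self, protein_id: str) -> list:
        return [t for t in range(len(self.unlabeled))
                if protein_id not in self._sets[t]]

    @property
    def _sets(self):
        if not hasattr(self, "_cached_sets"):
            self._cached_sets = [set(p) | set(u)
                                 for p, u in zip(self.positive, self.unlabeled)]
        return self._cached_sets


def partition_unlabeled(unlabeled_ids: list, T: int, seed: int) -> tuple[list, list]:
    """Shuffle and cut the unlabeled pool into T disjoint blocks of size
    floor(|U|/T); the remainder ids are dropped (returned separately, logged).
    """
    ids = list(unlabeled_ids)
    if len(ids) < T:
        raise ValueError(f"cannot partition {len(ids)} unlabeled ids into {T} subsets")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    size = len(ids) // T
    subsets = [[ids[j] for j in order[t * size:(t + 1) * size]] for t in range(T)]
    dropped = [ids[j] for j in order[T * size:]]
    if dropped:
        logger.info("dropping %d remainder unlabeled ids from training", len(dropped))
    return subsets, dropped


def sample_positive_subsets(positive_ids: list, T: int, size: int, seed: int) -> list:
    """T independent without-replacement samples of ``size`` positives each
    (a positive may appear in several subsets)."""
    ids = list(positive_ids)
    if len(ids) < size:
        raise ValueError(f"positive pool of {len(ids)} smaller than subset size {size}")
    rng = np.random.default_rng(seed)
    return [[ids[j] for j in rng.choice(len(ids), size=size, replace=False)]
            for _ in range(T)]


@dataclass
class TrainedEnsemble:
    config: EnsembleConfig
    membership: MembershipIndex
    models: list  # T ModelParameters
    loss_history: list  # per-model per-epoch training loss

    def predict(self, protein_id: str, features: np.ndarray) -> float:
        """Out-of-bag probability: mean of the models whose training data
        exclude ``protein_id`` (all T for unseen ids)."""
        models = self.membership.models_excluding(protein_id)
        if not models:
            logger.warning("protein %s in every training subset; averaging all models",
                           protein_id)
            models = list(range(len(self.models)))
        return float(np.mean([forward(self.models[t], features) for t in models]))

    def predict_many(self, protein_ids: list, features: np.ndarray) -> np.ndarray:
        """Vectorized out-of-bag probabilities for a batch of proteins."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        all_p = np.stack([np.atleast_1d(forward(m, x)) for m in self.models])
        include = np.ones((len(self.models), len(protein_ids)), dtype=bool)
        for t, s in enumerate(self.membership._sets):
            for i, pid in enumerate(protein_ids):
                if pid in s:
                    include[t, i] = False
        counts = include.sum(axis=0)
        full = counts == 0
        if full.any():
            logger.warning("%d proteins appear in every training subset; averaging all "
                           "models", int(full.sum()))
            include[:, full] = True
            counts = include.sum(axis=0)
        return (all_p * include).sum(axis=0) / counts

    def classify(self, probability) -> np.ndarray:
        return classify(probability, self.config.threshold)


def classify(probability, threshold: float = 0.5):
    """Positive iff probability strictly exceeds the threshold."""
    p = np.asarray(probability, dtype=float)
    out = (p > threshold).astype(int)
    return out if out.ndim else int(out)


def _model_seed(master: int, t: int) -> int:
    return int(np.random.SeedSequence([master, t]).generate_state(1)[0] % (2 ** 31))


def train(positive_ids: list, positive_x: np.ndarray,
          unlabeled_ids: list, unlabeled_x: np.ndarray,
          config: EnsembleConfig) -> TrainedEnsemble:
    """Train the T-model PU bagging ensemble on preprocessed features.

    ``positive_x`` / ``unlabeled_x`` are row-aligned with the id lists. Each
    model's training set is exactly class-balanced by construction.
    """
    if len(positive_ids) == 0 or len(unlabeled_ids) == 0:
        raise ValueError("positive and unlabeled pools must be non-empty")
    positive_x = np.asarray(positive_x, dtype=float)
    unlabeled_x = np.asarray(unlabeled_x, dtype=float)
    u_subsets, dropped = partition_unlabeled(unlabeled_ids, config.T, config.seed)
    size = len(u_subsets[0])
    p_subsets = sample_positive_subsets(positive_ids, config.T, size, config.seed + 1)
    membership = MembershipIndex(p_subsets, u_subsets, dropped)
    p_pos = {pid: i for i, pid in enumerate(positive_ids)}
    p_unl = {pid: i for i, pid in enumerate(unlabeled_ids)}
    models, histories = [], []
    for t in range(config.T):
        xp = positive_x[[p_pos[i] for i in p_subsets[t]]]
        xu = unlabeled_x[[p_unl[i] for i in u_subsets[t]]]
        x = np.vstack([xp, xu])
        y = np.concatenate([np.ones(len(xp)), np.zeros(len(xu))])
        params, history = train_model(x, y, config, _model_seed(config.seed, t))
        models.append(params)
        histories.append(history)
    return TrainedEnsemble(config, membership, models, histories)


# ---------------------------------------------------------------------------
# model bundle persistence
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: TrainedEnsemble, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "config.json"), "w") as fh:
        json.dump(asdict(ensemble.config), fh, indent=1)
    with open(os.path.join(directory, "membership.json"), "w") as fh:
        json.dump({"positive": ensemble.membership.positive,
                   "unlabeled": ensemble.membership.unlabeled,
                   "dropped": ensemble.membership.dropped}, fh)
    for t, m in enumerate(ensemble.models):
        arrays = {f"w{i}": w for i, w in enumerate(m.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(m.biases)})
        np.savez(os.path.join(directory, f"model_{t:02d}.npz"), **arrays)
    with open(os.path.join(directory, "loss_history.json"), "w") as fh:
        json.dump(ensemble.loss_history, fh)


def load_ensemble(directory: str) -> TrainedEnsemble:
    with open(os.path.join(directory, "config.json")) as fh:
        config = EnsembleConfig(**json.load(fh))
    with open(os.path.join(directory, "membership.json")) as fh:
        m = json.load(fh)
    membership = MembershipIndex(m["positive"], m["unlabeled"], m["dropped"])
    models = []
    for t in range(config.T):
        data = np.load(os.path.join(directory, f"model_{t:02d}.npz"))
        n_layers = len([k for k in data.files if k.startswith("w")])
        models.append(ModelParameters([data[f"w{i}"] for i in range(n_layers)],
                                      [data[f"b{i}"] for i in range(n_layers)]))
    with open(os.path.join(directory, "loss_history.json")) as fh:
        history = json.load(fh)
    return TrainedEnsemble(config, membership, models, history)
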