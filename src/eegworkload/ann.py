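"""Feedforward workload classifier.

A small fully-connected network (default: five hidden layers of 10 tanh units,
softmax output over the two workload states) trained by scaled conjugate
gradient (SCG; Moller 1993, Neural Networks 6:525-533) on cross-entropy with
early stopping: only a fraction (default 50%) of the training vectors in each
class is used directly for the weight updates, the remainder forms the
validation set that decides when to stop and which of the random restarts
(default 10) to keep.

The module exposes both a statsmodels-style model/results pair
(:class:`WorkloadClassifier` / :class:`WorkloadClassifierResults`) and flat
functions :func:`train` / :func:`predict` / :func:`accuracy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .features import FeatureSet, Normalizer, apply_normalizer, fit_normalizer

CLASSES = ("high", "low")  # output order; argmax ties resolve to "high"


@dataclass(frozen=True)
class NetConfig:
    """Architecture and training hyper-parameters."""

    hidden_layers: tuple[int, ...] = (10, 10, 10, 10, 10)
    max_iters: int = 300
    early_stop_patience: int = 8
    #: fraction of the training vectors used directly for weight updates;
    #: the remainder is the early-stopping validation set
    train_fraction: float = 0.5
    n_restarts: int = 10
    seed: int = 0

    def validate(self) -> None:
        if len(self.hidden_layers) < 1 or any(h < 1 for h in self.hidden_layers):
            raise ValidationError("hidden_layers",
                                  "need >= 1 hidden layer of >= 1 unit")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction",
                                  "train_fraction must be in (0, 1)")
        if self.n_restarts < 1:
            raise ValidationError("n_restarts", "n_restarts must be >= 1")


@dataclass
class WorkloadNet:
    """A trained network: layer weights, the normalizer fitted on its training
    vectors, and training metadata."""

    weights: list[np.ndarray]   # per layer, shape (fan_in, fan_out)
    biases: list[np.ndarray]
    normalizer: Normalizer
    config: NetConfig
    training_meta: dict = field(default_factory=dict)
    classes: tuple[str, str] = CLASSES

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    def forward(self, Z: np.ndarray) -> np.ndarray:
        """Output scores (logits) for already-normalized inputs."""
        a = Z
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ W + b)
        return a @ self.weights[-1] + self.biases[-1]


# ---------------------------------------------------------------- internals

def _layer_dims(n_in: int, hidden: tuple[int, ...], n_out: int) -> list[tuple[int, int]]:
    sizes = [n_in, *hidden, n_out]
    return list(zip(sizes[:-1], sizes[1:]))


def _init_params(rng: np.random.Generator, dims):
    Ws, bs = [], []
    for fan_in, fan_out in dims:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        Ws.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        bs.append(np.zeros(fan_out))
    return Ws, bs


def _pack(Ws, bs) -> np.ndarray:
    return np.concatenate([a.ravel() for a in Ws + bs])


def _unpack(w: np.ndarray, dims):
    Ws, bs, k = [], [], 0
    for fan_in, fan_out in dims:
        Ws.append(w[k : k + fan_in * fan_out].reshape(fan_in, fan_out))
        k += fan_in * fan_out
    for _, fan_out in dims:
        bs.append(w[k : k + fan_out])
        k += fan_out
    return Ws, bs


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _loss(w, dims, Z, Y) -> float:
    Ws, bs = _unpack(w, dims)
    a = Z
    for W, b in zip(Ws[:-1], bs[:-1]):
        a = np.tanh(a @ W + b)
    p = _softmax(a @ Ws[-1] + bs[-1])
    return float(-np.mean(np.sum(Y * np.log(p + 1e-300), axis=1)))


def _loss_grad(w, dims, Z, Y):
    """Mean cross-entropy and its gradient by backprop."""
    Ws, bs = _unpack(w, dims)
    acts = [Z]
    a = Z
    for W, b in zip(Ws[:-1], bs[:-1]):
        a = np.tanh(a @ W + b)
        acts.append(a)
    logits = a @ Ws[-1] + bs[-1]
    p = _softmax(logits)
    n = Z.shape[0]
    loss = float(-np.mean(np.sum(Y * np.log(p + 1e-300), axis=1)))
    delta = (p - Y) / n
    gWs = [None] * len(Ws)
    gbs = [None] * len(bs)
    for layer in range(len(Ws) - 1, -1, -1):
        gWs[layer] = acts[layer].T @ delta
        gbs[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ Ws[layer].T) * (1.0 - acts[layer] ** 2)
    return loss, _pack(gWs, gbs)


def scg_minimize(fun_grad, w0: np.ndarray, max_iters: int = 300,
                 callback=None, tol: float = 1e-10):
    """Scaled conjugate gradient minimisation (Moller 1993).

    ``fun_grad(w) -> (f, g)``. ``callback(w, f)`` is invoked after every
    accepted step and may return True to stop. Returns (w, f, n_iters).
    """
    w = w0.copy()
    f, g = fun_grad(w)
    r = -g
    p = r.copy()
    sigma0, lam, lam_bar = 1e-4, 1e-6, 0.0
    success = True
    n_params = w.size
    norm_p2 = delta = 0.0
    for k in range(1, max_iters + 1):
        if success:
            norm_p2 = float(p @ p)
            if norm_p2 < tol:
                break
            sigma = sigma0 / np.sqrt(norm_p2)
            _, g_plus = fun_grad(w + sigma * p)
            s = (g_plus - g) / sigma
            delta = float(p @ s)
        # scale: make the Hessian approximation positive definite
        delta += (lam - lam_bar) * norm_p2
        if delta <= 0:
            lam_bar = 2.0 * (lam - delta / norm_p2)
            delta = -delta + lam * norm_p2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, g_new = fun_grad(w + alpha * p)
        comparison = 2.0 * delta * (f - f_new) / mu**2
        if comparison >= 0:
            w = w + alpha * p
            f = f_new
            g = g_new
            r_new = -g
            lam_bar = 0.0
            success = True
            if k % n_params == 0:
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam *= 0.25
            if callback is not None and callback(w, f):
                return w, f, k
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam += delta * (1.0 - comparison) / norm_p2
        if lam > 1e15:
            break
    return w, f, k if max_iters > 0 else 0


def _encode_labels(labels) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    unknown = set(labels) - set(CLASSES)
    if unknown:
        raise ValidationError("known_state", f"unknown class labels {unknown}")
    y = (labels == CLASSES[1]).astype(int)  # high -> 0, low -> 1
    Y = np.zeros((len(labels), 2))
    Y[np.arange(len(labels)), y] = 1.0
    return Y


def train(features: FeatureSet, config: NetConfig = NetConfig()) -> WorkloadNet:
    """Train the workload network on a FeatureSet.

    Per restart: class-stratified random split of the training vectors by
    ``train_fraction``, SCG on cross-entropy, validation loss evaluated after
    every accepted step, stop after ``early_stop_patience`` evaluations without
    improvement; the restart with the best validation loss wins. Fully
    deterministic given ``config.seed``.
    """
    config.validate()
    X, labels = features.matrix, features.labels
    classes_present = set(labels)
    if len(classes_present) < 2:
        raise ValidationError("two_classes",
                              f"training data contains only {classes_present}")
    for c in CLASSES:
        if int(np.sum(labels == c)) < 10:
            raise ValidationError(
                "min_class_count",
                f"need >= 10 vectors per class, class {c!r} has "
                f"{int(np.sum(labels == c))}",
            )
    normalizer = fit_normalizer(features)
    Z = normalizer.transform(X)
    Y = _encode_labels(labels)
    dims = _layer_dims(Z.shape[1], tuple(config.hidden_layers), 2)

    master = np.random.SeedSequence(config.seed)
    restart_seqs = master.spawn(config.n_restarts)
    best = None
    for r in range(config.n_restarts):
        rng = np.random.default_rng(restart_seqs[r])
        # stratified split into direct-training and validation vectors
        tr_idx, va_idx = [], []
        for c in CLASSES:
            idx = np.flatnonzero(labels == c)
            idx = rng.permutation(idx)
            n_tr = max(1, min(len(idx) - 1, int(round(config.train_fraction * len(idx)))))
            tr_idx.extend(idx[:n_tr])
            va_idx.extend(idx[n_tr:])
        tr_idx, va_idx = np.sort(tr_idx), np.sort(va_idx)

        Ws, bs = _init_params(rng, dims)
        w0 = _pack(Ws, bs)
        state = {"best_f": np.inf, "best_w": w0.copy(), "stall": 0}

        def val_callback(w, f, state=state):
            fv = _loss(w, dims, Z[va_idx], Y[va_idx])
            if fv < state["best_f"] - 1e-12:
                state["best_f"] = fv
                state["best_w"] = w.copy()
                state["stall"] = 0
            else:
                state["stall"] += 1
            return state["stall"] >= config.early_stop_patience

        _, _, n_iter = scg_minimize(
            lambda w: _loss_grad(w, dims, Z[tr_idx], Y[tr_idx]),
            w0, max_iters=config.max_iters, callback=val_callback,
        )
        if state["best_f"] == np.inf:  # no accepted step improved validation
            state["best_f"] = _loss(w0, dims, Z[va_idx], Y[va_idx])
        if best is None or state["best_f"] < best["val_loss"]:
            best = {"val_loss": state["best_f"], "w": state["best_w"],
                    "restart": r, "iterations": n_iter}

    Ws, bs = _unpack(best["w"], dims)
    return WorkloadNet(
        weights=Ws,
        biases=bs,
        normalizer=normalizer,
        config=config,
        training_meta={
            "restart": best["restart"],
            "validation_loss": best["val_loss"],
            "iterations": best["iterations"],
            "n_training_vectors": int(X.shape[0]),
        },
    )


def predict(net: WorkloadNet, features) -> np.ndarray:
    """Per-epoch class labels. Exact output ties resolve to "high"."""
    X = features.matrix if isinstance(features, FeatureSet) else np.asarray(features, float)
    if X.ndim != 2 or X.shape[1] != net.n_inputs:
        raise ValidationError(
            "feature_width",
            f"features have {X.shape[-1]} columns, network expects {net.n_inputs}",
        )
    scores = net.forward(net.normalizer.transform(X))
    # np.argmax returns the first maximum: index 0 is "high", so ties -> high
    return np.asarray(CLASSES, dtype=object)[np.argmax(scores, axis=1)]


def accuracy(predicted, truth) -> float:
    """Fraction of epochs whose predicted state matches the known state."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.size == 0:
        raise ValidationError("nonempty", "accuracy of an empty sequence")
    if predicted.shape != truth.shape:
        raise ValidationError("equal_length",
                              f"{predicted.shape} predictions vs {truth.shape} truths")
    return float(np.mean(predicted == truth))


# ------------------------------------------------- model/results front-end

class WorkloadClassifier:
    """Workload classification model over a FeatureSet.

    Mirrors the statsmodels pattern: build the model from data, call
    :meth:`fit`, get a results object carrying the trained network and
    diagnostics.
    """

    def __init__(self, features: FeatureSet, config: NetConfig = NetConfig()):
        self.features = features
        self.config = config

    @classmethod
    def from_dataframe(cls, df, config: NetConfig = NetConfig()):
        return cls(FeatureSet.from_frame(df), config)

    def fit(self) -> "WorkloadClassifierResults":
        net = train(self.features, self.config)
        return WorkloadClassifierResults(self, net)


class WorkloadClassifierResults:
    """Results of fitting a :class:`WorkloadClassifier`."""

    def __init__(self, model: WorkloadClassifier, net: WorkloadNet):
        self.model = model
        self.net = net

    def predict(self, features) -> np.ndarray:
        return predict(self.net, features)

    def score(self, features: FeatureSet) -> float:
        return accuracy(self.predict(features), features.labels)

    @property
    def training_accuracy(self) -> float:
        return self.score(self.model.features)

    def summary(self) -> str:
        meta = self.net.training_meta
        arch = " -> ".join(
            str(d) for d in
            (self.net.n_inputs, *self.net.config.hidden_layers, 2)
        )
        lines = [
            "Workload ANN classification results",
            "=" * 43,
            f"architecture        {arch} (tanh / softmax)",
            f"training vectors    {meta.get('n_training_vectors')}",
            f"restarts            {self.net.config.n_restarts} "
            f"(chosen: {meta.get('restart')})",
            f"SCG iterations      {meta.get('iterations')}",
            f"validation loss     {meta.get('validation_loss'):.6f}",
            f"training accuracy   {self.training_accuracy:.3f}",
        ]
        return "\n".join(lines)
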