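"""Stacked (depth) autoencoder with a softmax head, and the raw-vs-fine
feature classification experiment.

The encoder maps an input x in [0,1]^M through successive layers
H = alpha(W x + d) (sigmoid activations by default); the decoder mirrors the
stack and ends in a sigmoid so the summed binary cross-entropy
reconstruction loss

    G(x, y) = - sum_i [ x_i log y_i + (1 - x_i) log(1 - y_i) ]

is well defined. Training is greedy layer-wise pretraining (each layer
trained as a one-hidden-layer autoencoder on the previous layer's codes)
followed by end-to-end fine-tuning, all with full-batch gradient descent and
a backtracking learning rate (halved whenever a step would increase the
loss), which makes the per-epoch loss history nonincreasing and every run
exactly reproducible from its seed. The encoder can additionally be tuned
jointly with the softmax classifier on labelled data — hidden weights
adjusted by the classification loss — which is how the "fine" features of
the comparison experiment are produced.

The SVM baselines come from scikit-learn; they are reference classifiers,
not part of the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "LayerParams",
    "AutoencoderModel",
    "SoftmaxClassifier",
    "encode",
    "decode",
    "reconstruction_loss",
    "train_autoencoder",
    "fine_features",
    "finetune_with_softmax",
    "train_softmax",
    "comparison_experiment",
]

EPS = 1e-12


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


@dataclass
class LayerParams:
    """One affine layer: out = activation(weights @ x + bias)."""

    weights: np.ndarray
    bias: np.ndarray
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a matrix (out_dim x in_dim)")
        if self.bias.shape != (self.weights.shape[0],):
            raise ValueError("bias length must equal out_dim")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.bias))):
            raise ValueError("layer parameters must be finite")
        if self.activation not in ("sigmoid", "identity"):
            raise ValueError("activation must be 'sigmoid' or 'identity'")

    @property
    def in_dim(self) -> int:
        return self.weights.shape[1]

    @property
    def out_dim(self) -> int:
        return self.weights.shape[0]

    def apply(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.weights.T + self.bias
        return _sigmoid(z) if self.activation == "sigmoid" else z


@dataclass
class AutoencoderModel:
    """Encoder/decoder layer stacks plus the training loss history."""

    encoder: list[LayerParams]
    decoder: list[LayerParams]
    input_dim: int
    history: list[float] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        enc_dims = [self.input_dim] + [l.out_dim for l in self.encoder]
        dec_dims = [l.out_dim for l in self.decoder]
        for layer, expect in zip(self.encoder, enc_dims[:-1]):
            if layer.in_dim != expect:
                raise ValueError("encoder layer dimensions do not chain")
        if self.decoder:
            if self.decoder[0].in_dim != enc_dims[-1]:
                raise ValueError("decoder must start at the code dimension")
            if dec_dims != enc_dims[-2::-1]:
                raise ValueError("decoder dimensions must mirror the encoder")
            if self.decoder[-1].out_dim != self.input_dim:
                raise ValueError("decoder must end at the input dimension")

    @property
    def code_dim(self) -> int:
        return self.encoder[-1].out_dim

    @property
    def layers(self) -> list[LayerParams]:
        return [*self.encoder, *self.decoder]


def _check_input(x: np.ndarray, dim: int, name: str) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.shape[1] != dim:
        raise ValueError(f"{name} has dimension {arr.shape[1]}, expected {dim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def encode(x: np.ndarray, model: AutoencoderModel) -> np.ndarray:
    """Apply the encoder stack; accepts a vector or a row matrix."""
    arr = _check_input(x, model.input_dim, "input")
    for layer in model.encoder:
        arr = layer.apply(arr)
    return arr[0] if np.asarray(x).ndim == 1 else arr


def decode(h: np.ndarray, model: AutoencoderModel) -> np.ndarray:
    """Apply the mirrored decoder stack to a hidden code."""
    arr = _check_input(h, model.code_dim, "code")
    for layer in model.decoder:
        arr = layer.apply(arr)
    return arr[0] if np.asarray(h).ndim == 1 else arr


def reconstruction_loss(x: np.ndarray, y: np.ndarray) -> float:
    """Summed binary cross-entropy between input x and reconstruction y.

    For row matrices the mean of the per-row sums is returned. y components
    outside (0, 1) are clamped to [EPS, 1-EPS] (logged); the 0*log(0)
    convention gives exact zero loss for exact binary reconstruction.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have the same shape")
    if np.any(xa < 0) or np.any(xa > 1):
        raise ValueError("x must lie in [0, 1]")
    if np.any(ya <= 0) or np.any(ya >= 1):
        logger.warning("reconstruction outside (0,1); clamping to [%g, %g]", EPS, 1 - EPS)
    ya = np.clip(ya, EPS, 1.0 - EPS)
    with np.errstate(invalid="ignore"):
        terms = -(xa * np.log(ya) + (1.0 - xa) * np.log(1.0 - ya))
    # 0*log(0) -> 0: exact matches at the clamp boundary contribute ~0 anyway
    total = terms.sum(axis=-1)
    return float(total if total.ndim == 0 else total.mean())


# ---------------------------------------------------------------------------
# Training


def _init_layer(rng: np.random.Generator, out_dim: int, in_dim: int) -> LayerParams:
    bound = 1.0 / np.sqrt(in_dim)
    return LayerParams(
        weights=rng.uniform(-bound, bound, size=(out_dim, in_dim)),
        bias=np.zeros(out_dim),
    )


def _forward(layers: list[LayerParams], x: np.ndarray) -> list[np.ndarray]:
    acts = [x]
    for layer in layers:
        acts.append(layer.apply(acts[-1]))
    return acts


def _bce_grads(
    layers: list[LayerParams], x: np.ndarray, target: np.ndarray
) -> tuple[float, list[tuple[np.ndarray, np.ndarray]]]:
    """Mean summed-BCE loss and its gradients for a sigmoid-output stack.

    With a sigmoid output the loss gradient w.r.t. the output pre-activation
    is simply (y - target), which keeps backpropagation exact.
    """
    if layers[-1].activation != "sigmoid":
        raise ValueError("BCE training requires a sigmoid output layer")
    acts = _forward(layers, x)
    y = acts[-1]
    n = x.shape[0]
    loss = reconstruction_loss(target, y)
    delta = (y - target) / n
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(layers)  # type: ignore[list-item]
    for i in range(len(layers) - 1, -1, -1):
        a_prev = acts[i]
        grads[i] = (delta.T @ a_prev, delta.sum(axis=0))
        if i > 0:
            delta = delta @ layers[i].weights
            a = acts[i]
            if layers[i - 1].activation == "sigmoid":
                delta = delta * a * (1.0 - a)
    return loss, grads


def _gd_epochs(
    layers: list[LayerParams],
    loss_grad_fn,
    epochs: int,
    lr: float,
) -> list[float]:
    """Full-batch gradient descent with a backtracking step size: the
    learning rate is halved whenever a step would increase the loss, and
    grows slowly again after accepted steps (capped at 100x the initial
    rate). Returns the per-epoch loss history, nonincreasing by
    construction."""
    loss, grads = loss_grad_fn(layers)
    history = [loss]
    lr_cap = lr * 100.0
    for _ in range(epochs):
        while True:
            trial = [
                LayerParams(l.weights - lr * gw, l.bias - lr * gb, l.activation)
                for l, (gw, gb) in zip(layers, grads)
            ]
            new_loss, new_grads = loss_grad_fn(trial)
            if new_loss <= loss or lr <= 1e-12:
                break
            lr *= 0.5
        if new_loss > loss:  # learning rate exhausted: stay put
            history.append(loss)
            continue
        for l, t in zip(layers, trial):
            l.weights, l.bias = t.weights, t.bias
        loss, grads = new_loss, new_grads
        lr = min(lr * 1.2, lr_cap)
        history.append(loss)
    return history


def train_autoencoder(
    data: np.ndarray,
    layer_dims: list[int] | None = None,
    epochs: int = 150,
    learning_rate: float = 0.1,
    seed: int = 0,
    pretrain_epochs: int | None = None,
) -> AutoencoderModel:
    """Greedy layer-wise pretraining followed by end-to-end fine-tuning.

    ``layer_dims`` are the hidden widths down to the code; they must be
    strictly decreasing from the input dimension (the model reduces
    dimension). Default: the three-hidden-layer geometric schedule
    M -> ceil(M/2) -> ceil(M/4) -> ceil(M/8). Data must lie in [0, 1]
    (the loss domain). Deterministic given seed.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("data must be an n x M matrix with n >= 2")
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("data must lie in [0, 1]")
    m = x.shape[1]
    if layer_dims is None:
        layer_dims = [int(np.ceil(m / 2)), int(np.ceil(m / 4)), int(np.ceil(m / 8))]
    dims = [m, *layer_dims]
    if any(b >= a for a, b in zip(dims[:-1], dims[1:])):
        raise ValueError(f"layer dims must be strictly decreasing from {m}, got {layer_dims}")
    if pretrain_epochs is None:
        pretrain_epochs = epochs
    rng = np.random.default_rng(seed)

    encoder: list[LayerParams] = []
    decoder_rev: list[LayerParams] = []
    current = x
    for out_dim in layer_dims:
        enc = _init_layer(rng, out_dim, current.shape[1])
        dec = _init_layer(rng, current.shape[1], out_dim)
        pair = [enc, dec]
        target = current
        _gd_epochs(pair, lambda ls, tgt=target: _bce_grads(ls, tgt, tgt), pretrain_epochs, learning_rate)
        encoder.append(pair[0])
        decoder_rev.append(pair[1])
        current = pair[0].apply(current)

    layers = [*encoder, *decoder_rev[::-1]]
    history = _gd_epochs(layers, lambda ls: _bce_grads(ls, x, x), epochs, learning_rate)
    n_enc = len(encoder)
    return AutoencoderModel(
        encoder=layers[:n_enc],
        decoder=layers[n_enc:],
        input_dim=m,
        history=history,
        seed=seed,
    )


def fine_features(data: np.ndarray, model: AutoencoderModel) -> np.ndarray:
    """Code-layer activations, row-wise: the model's 'fine' features."""
    arr = _check_input(data, model.input_dim, "data")
    return encode(arr, model)


# ---------------------------------------------------------------------------
# Softmax classifier (multinomial logistic regression by gradient descent)


@dataclass
class SoftmaxClassifier:
    """Multinomial logistic model fit by full-batch gradient descent."""

    weights: np.ndarray | None = None
    bias: np.ndarray | None = None
    classes_: np.ndarray | None = None
    history: list[float] = field(default_factory=list)

    def _scores(self, x: np.ndarray) -> np.ndarray:
        return x @ self.weights.T + self.bias

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self._scores(np.atleast_2d(np.asarray(x, dtype=float)))
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(x), axis=1)]

    def score(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(x) == np.asarray(y)))

    def fit(self, x: np.ndarray, y: np.ndarray, epochs: int = 300, lr: float = 0.5, seed: int = 0) -> "SoftmaxClassifier":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        k = len(self.classes_)
        if k < 2:
            raise ValueError("need at least 2 classes")
        onehot = (y[:, None] == self.classes_[None, :]).astype(float)
        rng = np.random.default_rng(seed)
        d = x.shape[1]
        self.weights = rng.uniform(-1.0 / np.sqrt(d), 1.0 / np.sqrt(d), size=(k, d))
        self.bias = np.zeros(k)
        n = x.shape[0]

        def loss_grads(w, b):
            z = x @ w.T + b
            z = z - z.max(axis=1, keepdims=True)
            logsum = np.log(np.exp(z).sum(axis=1, keepdims=True))
            logp = z - logsum
            loss = -float((onehot * logp).sum() / n)
            p = np.exp(logp)
            delta = (p - onehot) / n
            return loss, delta.T @ x, delta.sum(axis=0)

        loss, gw, gb = loss_grads(self.weights, self.bias)
        self.history = [loss]
        step = lr
        for _ in range(epochs):
            while True:
                w_new = self.weights - step * gw
                b_new = self.bias - step * gb
                new_loss, new_gw, new_gb = loss_grads(w_new, b_new)
                if new_loss <= loss or step <= 1e-12:
                    break
                step *= 0.5
            if new_loss > loss:
                self.history.append(loss)
                continue
            self.weights, self.bias = w_new, b_new
            loss, gw, gb = new_loss, new_gw, new_gb
            self.history.append(loss)
        return self


def train_softmax(
    features: np.ndarray,
    labels: np.ndarray,
    epochs: int = 300,
    lr: float = 0.5,
    seed: int = 0,
    test_fraction: float = 0.25,
) -> tuple[SoftmaxClassifier, float]:
    """Fit the softmax classifier on a stratified split and report held-out
    accuracy."""
    x_tr, x_te, y_tr, y_te = train_test_split(
        np.asarray(features, dtype=float),
        np.asarray(labels),
        test_size=test_fraction,
        random_state=seed,
        stratify=labels,
    )
    clf = SoftmaxClassifier().fit(x_tr, y_tr, epochs=epochs, lr=lr, seed=seed)
    return clf, clf.score(x_te, y_te)


def finetune_with_softmax(
    model: AutoencoderModel,
    data: np.ndarray,
    labels: np.ndarray,
    epochs: int = 300,
    lr: float = 0.5,
    seed: int = 0,
    n_restarts: int = 1,
) -> tuple[AutoencoderModel, SoftmaxClassifier]:
    """Adjust the encoder's hidden weights jointly with a softmax head on the
    code layer, by gradient descent on the classification cross-entropy.

    This is the supervised coupling of autoencoder and classifier: the
    encoder's representation is tuned by the classifier's loss. The decoder
    is left untouched (it no longer mirrors a trained inverse afterwards).
    Full-batch descent on a small sigmoid stack can stall in a poor basin
    (the classic XOR-type local minimum), so up to ``n_restarts`` restarts
    are run from seed-derived head initializations and the run with the
    lowest final training loss is kept; everything stays deterministic
    given ``seed``.
    """
    x = _check_input(data, model.input_dim, "data")
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    onehot = (y[:, None] == classes[None, :]).astype(float)
    k, code = len(classes), model.code_dim
    n = x.shape[0]

    def make_loss_grads(x_local):
        def loss_grads(layers):
            acts = _forward(layers, x_local)
            z = acts[-1]
            z = z - z.max(axis=1, keepdims=True)
            logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
            loss = -float((onehot * logp).sum() / n)
            delta = (np.exp(logp) - onehot) / n
            grads = [None] * len(layers)
            for i in range(len(layers) - 1, -1, -1):
                grads[i] = (delta.T @ acts[i], delta.sum(axis=0))
                if i > 0:
                    delta = delta @ layers[i].weights
                    a = acts[i]
                    if layers[i - 1].activation == "sigmoid":
                        delta = delta * a * (1.0 - a)
            return loss, grads

        return loss_grads

    loss_grads = make_loss_grads(x)
    best_stack, best_loss = None, np.inf
    for attempt in range(max(1, n_restarts)):
        rng = np.random.default_rng(np.random.SeedSequence((seed, attempt)))
        head = _init_layer(rng, k, code)
        head.activation = "identity"
        enc = [LayerParams(l.weights.copy(), l.bias.copy(), l.activation) for l in model.encoder]
        if attempt > 0:  # progressively larger jitter; the basin is what we escape
            for layer in enc:
                layer.weights = layer.weights + rng.normal(0.0, 0.15 * attempt, layer.weights.shape)
                layer.bias = layer.bias + rng.normal(0.0, 0.05 * attempt, layer.bias.shape)
        stack = [*enc, head]
        history = _gd_epochs(stack, loss_grads, epochs, lr)
        if history[-1] < best_loss:
            best_stack, best_loss = stack, history[-1]
        if best_loss < 1e-3:  # converged; further restarts cannot do better
            break

    tuned = AutoencoderModel(
        encoder=best_stack[:-1],
        decoder=[],
        input_dim=model.input_dim,
        history=list(model.history),
        seed=model.seed,
    )
    clf = SoftmaxClassifier(
        weights=best_stack[-1].weights, bias=best_stack[-1].bias, classes_=classes
    )
    return tuned, clf


# ---------------------------------------------------------------------------
# Raw vs fine comparison experiment


def _classifier_bank(seed: int) -> dict[str, object]:
    return {
        "linear_svm": SVC(kernel="linear", random_state=seed),
        "rbf_svm": SVC(kernel="rbf", random_state=seed),
        "softmax": SoftmaxClassifier(),
    }


def _fit_score(name: str, clf, x_tr, y_tr, x_te, y_te, seed: int) -> float:
    if name == "softmax":
        clf.fit(x_tr, y_tr, seed=seed)
        return clf.score(x_te, y_te)
    clf.fit(x_tr, y_tr)
    return float(clf.score(x_te, y_te))


def comparison_experiment(
    feature_table: np.ndarray,
    labels: np.ndarray,
    split_fraction: float = 0.25,
    seeds: range | list[int] = range(20),
    layer_dims: list[int] | None = None,
    epochs: int = 200,
    finetune_epochs: int = 4000,
    learning_rate: float = 2.0,
    n_restarts: int = 5,
) -> pd.DataFrame:
    """Held-out accuracy of {softmax, linear SVM, RBF-SVM} on raw features
    versus autoencoder fine features, over several train/test splits.

    For each seed the autoencoder is pretrained and reconstruction-tuned on
    the training split only, then its encoder is tuned jointly with a
    softmax head on the training labels; fine features are the resulting
    code-layer activations. Splits are stratified, so every class appears in
    both halves.
    """
    x = np.asarray(feature_table, dtype=float)
    y = np.asarray(labels)
    rows = []
    for seed in seeds:
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, test_size=split_fraction, random_state=int(seed), stratify=y
        )
        model = train_autoencoder(
            x_tr, layer_dims=layer_dims, epochs=epochs, learning_rate=0.1, seed=int(seed)
        )
        tuned, _ = finetune_with_softmax(
            model,
            x_tr,
            y_tr,
            epochs=finetune_epochs,
            lr=learning_rate,
            seed=int(seed),
            n_restarts=n_restarts,
        )
        f_tr = fine_features(x_tr, tuned)
        f_te = fine_features(x_te, tuned)
        for feat_name, (a_tr, a_te) in (("raw", (x_tr, x_te)), ("fine", (f_tr, f_te))):
            for clf_name, clf in _classifier_bank(int(seed)).items():
                acc = _fit_score(clf_name, clf, a_tr, y_tr, a_te, y_te, int(seed))
                rows.append(
                    {
                        "classifier": clf_name,
                        "features": feat_name,
                        "seed": int(seed),
                        "accuracy": acc,
                        "n_train": len(y_tr),
                        "n_test": len(y_te),
                    }
                )
    return pd.DataFrame(rows)
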