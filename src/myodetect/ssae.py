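"""Stacked sparse autoencoder (SSAE) feature learning.

A sparse autoencoder (SAE) is a one-hidden-layer network trained to
reproduce its input through a logistic-sigmoid bottleneck under three
penalties: mean-squared reconstruction error, a quadratic weight decay
(lambda/2 * sum W^2 over all weight matrices), and a KL-divergence sparsity
penalty beta * sum_j KL(rho || rho_hat_j) that pushes each hidden unit's
mean activation rho_hat_j toward a small target rate rho.

An SSAE stacks several SAEs trained greedily — layer l learns to encode the
hidden activations of layer l-1 — after which the decoders are discarded, a
two-class softmax head is attached to the deepest code, and the whole
encoder+head is fine-tuned by mini-batch gradient descent on cross-entropy
(with class-balanced batches to counter the background/target imbalance).

Crops enter as tau x tau patches, min-max scaled per crop to [0, 1] and
flattened; the deepest hidden layer is the feature vector used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "SAELayer",
    "SSAEModel",
    "kl_sparsity",
    "sae_cost_grad",
    "sae_train",
    "ssae_pretrain",
    "ssae_finetune",
    "ssae_encode",
    "prepare_crop",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class SAELayer:
    """One sparse autoencoder layer (encoder retained, decoder optional).

    ``W1`` (n_hidden x n_in) and ``b1`` encode; ``W2`` (n_in x n_hidden) and
    ``b2`` decode. Activation is the logistic sigmoid throughout.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray | None = None
    b2: np.ndarray | None = None

    @property
    def n_in(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        """Hidden activations for rows of X (n_samples x n_in)."""
        return _sigmoid(X @ self.W1.T + self.b1)


@dataclass
class SSAEModel:
    """Stacked encoder plus an optional 2-class softmax head.

    ``layer_sizes`` is [input, h1, h2, ...]; the deepest hidden layer is the
    feature dimension. ``tau`` is the crop side: input size must equal tau^2.
    """

    layers: list[SAELayer]
    tau: int
    lam: float = 1e-2
    beta: float = 0.3
    rho: float = 0.2
    softmax_W: np.ndarray | None = None  # (2, n_feature)
    softmax_b: np.ndarray | None = None  # (2,)

    @property
    def layer_sizes(self) -> list[int]:
        return [self.layers[0].n_in] + [l.n_hidden for l in self.layers]

    @property
    def n_feature(self) -> int:
        return self.layers[-1].n_hidden

    def encode(self, X: np.ndarray) -> np.ndarray:
        H = np.asarray(X, dtype=float)
        for layer in self.layers:
            H = layer.encode(H)
        return H

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.softmax_W is None:
            raise ValueError("model has no softmax head; fine-tune first")
        H = self.encode(X)
        logits = H @ self.softmax_W.T + self.softmax_b
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    """Summed Bernoulli KL divergence between the target rate and each
    hidden unit's mean activation:

    sum_j [rho log(rho/rho_hat_j) + (1-rho) log((1-rho)/(1-rho_hat_j))].

    Boundary values (0 or 1) are rejected: the divergence is infinite there.
    """
    rho_hat = np.asarray(rho_hat, dtype=float)
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie strictly in (0, 1)")
    if np.any(rho_hat <= 0.0) or np.any(rho_hat >= 1.0):
        raise ValueError("rho_hat entries must lie strictly in (0, 1)")
    return float(
        np.sum(rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat)))
    )


def _unpack(theta: np.ndarray, n_in: int, n_hidden: int):
    i0 = 0
    W1 = theta[i0 : i0 + n_hidden * n_in].reshape(n_hidden, n_in); i0 += n_hidden * n_in
    W2 = theta[i0 : i0 + n_in * n_hidden].reshape(n_in, n_hidden); i0 += n_in * n_hidden
    b1 = theta[i0 : i0 + n_hidden]; i0 += n_hidden
    b2 = theta[i0 : i0 + n_in]
    return W1, W2, b1, b2


def sae_cost_grad(
    theta_or_layer,
    X: np.ndarray,
    lam: float,
    beta: float,
    rho: float,
) -> tuple[float, np.ndarray]:
    """Cost and flat gradient of one SAE on batch X (n_samples x n_in).

    cost = (1/n) sum_i 1/2 ||y_i - x_i||^2 + lam/2 sum W^2 + beta * KL,
    where the KL term uses the batch-mean hidden activations; its gradient
    contribution is back-propagated through rho_hat. The weight penalty
    covers both weight matrices, not the biases.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D batch")
    if np.isnan(X).any():
        raise ValueError("NaN in input batch")
    n, n_in = X.shape
    if isinstance(theta_or_layer, SAELayer):
        layer = theta_or_layer
        if layer.W2 is None:
            raise ValueError("layer has no decoder")
        theta = np.concatenate(
            [layer.W1.ravel(), layer.W2.ravel(), layer.b1.ravel(), layer.b2.ravel()]
        )
        n_hidden = layer.n_hidden
    else:
        theta = np.asarray(theta_or_layer, dtype=float)
        # infer n_hidden from the flat length: 2*h*d + h + d = len
        n_hidden = (theta.size - n_in) // (2 * n_in + 1)
    W1, W2, b1, b2 = _unpack(theta, n_in, n_hidden)

    Z1 = X @ W1.T + b1
    H = _sigmoid(Z1)
    Z2 = H @ W2.T + b2
    Y = _sigmoid(Z2)

    diff = Y - X
    rec = 0.5 * np.sum(diff**2) / n
    wpen = 0.5 * lam * (np.sum(W1**2) + np.sum(W2**2))
    rho_hat = np.clip(H.mean(axis=0), 1e-12, 1 - 1e-12)
    kl = kl_sparsity(rho, rho_hat) if beta != 0 else 0.0
    cost = rec + wpen + beta * kl

    # backprop
    d2 = diff * Y * (1 - Y) / n  # (n, n_in)
    gW2 = d2.T @ H + lam * W2
    gb2 = d2.sum(axis=0)
    sparsity_grad = beta * (-(rho / rho_hat) + (1 - rho) / (1 - rho_hat)) / n
    d1 = (d2 @ W2 + sparsity_grad) * H * (1 - H)
    gW1 = d1.T @ X + lam * W1
    gb1 = d1.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gW2.ravel(), gb1.ravel(), gb2.ravel()])
    return cost, grad


def _init_theta(n_in: int, n_hidden: int, rng: np.random.Generator) -> np.ndarray:
    r1 = np.sqrt(6.0 / (n_in + n_hidden))
    W1 = rng.uniform(-r1, r1, (n_hidden, n_in))
    W2 = rng.uniform(-r1, r1, (n_in, n_hidden))
    return np.concatenate([W1.ravel(), W2.ravel(), np.zeros(n_hidden + n_in)])


def sae_train(
    X: np.ndarray,
    n_hidden: int,
    lam: float = 1e-2,
    beta: float = 0.3,
    rho: float = 0.2,
    max_iter: int = 400,
    seed: int = 0,
) -> SAELayer:
    """Train one SAE by full-batch L-BFGS on ``sae_cost_grad``.

    Weights start uniform in +/- sqrt(6/(fan_in+fan_out)) (seeded), biases at
    zero. The returned parameters never cost more than the initialization.
    """
    X = np.asarray(X, dtype=float)
    n, n_in = X.shape
    rng = np.random.default_rng(seed)
    theta0 = _init_theta(n_in, n_hidden, rng)
    cost0, _ = sae_cost_grad(theta0, X, lam, beta, rho)

    res = optimize.minimize(
        sae_cost_grad,
        theta0,
        args=(X, lam, beta, rho),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"SAE training diverged (cost NaN) at iteration {res.nit}")
    theta = res.x if res.fun <= cost0 else theta0
    W1, W2, b1, b2 = _unpack(theta, n_in, n_hidden)
    return SAELayer(W1=W1.copy(), b1=b1.copy(), W2=W2.copy(), b2=b2.copy())


def ssae_pretrain(
    X: np.ndarray,
    layer_sizes: list[int],
    tau: int,
    lam: float = 1e-2,
    beta: float = 0.3,
    rho: float = 0.2,
    max_iter: int = 400,
    seed: int = 0,
) -> SSAEModel:
    """Greedy layerwise pretraining.

    ``layer_sizes`` is [input, h1, h2, ...] and must be strictly decreasing
    (sparse bottleneck design). Layer l is trained on the activations of the
    trained layer l-1; decoders are kept on each layer (pretraining only).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != layer_sizes[0]:
        raise ValueError("input dimension does not match layer_sizes[0]")
    if layer_sizes[0] != tau * tau:
        raise ValueError("first layer input must equal tau^2")
    if any(b >= a for a, b in zip(layer_sizes, layer_sizes[1:])):
        raise ValueError("layer_sizes must be strictly decreasing")
    rng = np.random.default_rng(seed)
    layers: list[SAELayer] = []
    H = X
    for h in layer_sizes[1:]:
        layer = sae_train(H, h, lam, beta, rho, max_iter, seed=int(rng.integers(2**31)))
        layers.append(layer)
        H = layer.encode(H)
    return SSAEModel(layers=layers, tau=tau, lam=lam, beta=beta, rho=rho)


def _softmax_xent_grads(model: SSAEModel, Xb: np.ndarray, yb: np.ndarray, lam: float):
    """Cross-entropy + weight-decay cost and gradients for encoder + head."""
    acts = [Xb]
    H = Xb
    for layer in model.layers:
        H = layer.encode(H)
        acts.append(H)
    logits = H @ model.softmax_W.T + model.softmax_b
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    P = e / e.sum(axis=1, keepdims=True)
    n = Xb.shape[0]
    Y = np.zeros_like(P)
    Y[np.arange(n), yb] = 1.0
    xent = -np.sum(Y * np.log(np.clip(P, 1e-12, None))) / n
    wpen = 0.5 * lam * (
        sum(np.sum(l.W1**2) for l in model.layers) + np.sum(model.softmax_W**2)
    )
    dlogits = (P - Y) / n
    gW_s = dlogits.T @ H + lam * model.softmax_W
    gb_s = dlogits.sum(axis=0)
    delta = dlogits @ model.softmax_W
    gW, gb = [], []
    for li in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[li]
        Hl = acts[li + 1]
        delta = delta * Hl * (1 - Hl)
        gW.append(delta.T @ acts[li] + lam * layer.W1)
        gb.append(delta.sum(axis=0))
        delta = delta @ layer.W1
    gW.reverse()
    gb.reverse()
    return xent + wpen, gW, gb, gW_s, gb_s


def ssae_finetune(
    model: SSAEModel,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 30,
    batch_size: int = 128,
    learning_rate: float = 0.1,
    lr_decay: float = 0.98,
    seed: int = 0,
    freeze_encoder: bool = False,
) -> SSAEModel:
    """Joint fine-tuning of encoder and softmax head.

    Mini-batches are drawn with equal class proportions (each batch is half
    positives, half negatives, sampling the minority class with replacement)
    to counter the target/background imbalance. Optimizes cross-entropy plus
    the quadratic weight penalty by plain gradient descent with a decaying
    learning rate. The sparsity penalty is not applied during fine-tuning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("fine-tuning requires exactly two classes")
    idx_pos = np.where(y == classes.max())[0]
    idx_neg = np.where(y == classes.min())[0]
    if idx_pos.size == 0 or idx_neg.size == 0:
        raise ValueError("cannot build balanced batches from a single class")
    yb01 = (y == classes.max()).astype(int)

    rng = np.random.default_rng(seed)
    if model.softmax_W is None:
        r = np.sqrt(6.0 / (model.n_feature + 2))
        model.softmax_W = rng.uniform(-r, r, (2, model.n_feature))
        model.softmax_b = np.zeros(2)

    half = max(batch_size // 2, 1)
    n_batches = max(int(np.ceil(max(idx_pos.size, idx_neg.size) / half)), 1)
    lr = learning_rate
    for epoch in range(epochs):
        for _ in range(n_batches):
            bi = np.concatenate(
                [rng.choice(idx_pos, half, replace=True), rng.choice(idx_neg, half, replace=True)]
            )
            cost, gW, gb, gW_s, gb_s = _softmax_xent_grads(model, X[bi], yb01[bi], model.lam)
            model.softmax_W -= lr * gW_s
            model.softmax_b -= lr * gb_s
            if not freeze_encoder:
                for layer, gw, gbias in zip(model.layers, gW, gb):
                    layer.W1 -= lr * gw
                    layer.b1 -= lr * gbias
        lr *= lr_decay
    return model


def prepare_crop(image: np.ndarray, tau: int) -> np.ndarray:
    """Resize a 2-D crop to tau x tau (bilinear) and min-max scale to [0,1]."""
    from skimage.transform import resize

    crop = np.asarray(image, dtype=float)
    if crop.shape != (tau, tau):
        crop = resize(crop, (tau, tau), order=1, mode="reflect", anti_aliasing=False)
    lo, hi = crop.min(), crop.max()
    if hi - lo < 1e-12:
        return np.zeros((tau, tau))
    return (crop - lo) / (hi - lo)


def ssae_encode(model: SSAEModel, crops: np.ndarray) -> np.ndarray:
    """Deterministic forward pass: (n, tau, tau) crops -> (n, n_feature).

    Crops must already be tau x tau in [0, 1] (see ``prepare_crop``).
    """
    crops = np.asarray(crops, dtype=float)
    single = crops.ndim == 2
    if single:
        crops = crops[None]
    if crops.shape[1:] != (model.tau, model.tau):
        raise ValueError(f"crops must be {model.tau}x{model.tau}")
    feats = model.encode(crops.reshape(crops.shape[0], -1))
    return feats[0] if single else feats
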