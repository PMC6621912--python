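"""Two-stage attention over the concatenated trace state, plus the readout.

Given the deep state ``x`` (the concatenated per-layer trace snapshot,
length L*N), the readout computes

    A_deep    = softmax(W_deep @ x)            # one coefficient per layer
    X_S       = sum_l A_deep[l] * X_l          # collapse layers, length N
    A_spatial = sigmoid(W_spatial @ x)         # per-neuron gates, length N
    X_F       = X_S * A_spatial                # gated representation
    y         = sigmoid(W_out @ X_F)           # per-class scores

and predicts ``argmax y``.  Training minimizes the cross-entropy of a
softmax over ``y`` by full-batch gradient descent; gradients flow only
through these readout equations — the network state is a constant, so no
backpropagation-through-time is ever required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AttentionParams",
    "deep_attention",
    "collapse_layers",
    "spatial_attention",
    "readout",
    "predict",
    "train_readout",
    "loss_and_gradients",
]


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class AttentionParams:
    """Weight blocks of the attention readout.

    ``w_deep``: (L, L*N) layer-importance logits; ``w_spatial``:
    (N, L*N) per-neuron gate logits; ``w_out``: (O, N) classifier.
    ``mean``/``scale`` hold the feature standardization fitted during
    training (identity until trained).
    """

    w_deep: np.ndarray
    w_spatial: np.ndarray
    w_out: np.ndarray
    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    @property
    def n_layers(self) -> int:
        return self.w_deep.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_spatial.shape[0]

    @property
    def n_classes(self) -> int:
        return self.w_out.shape[0]

    def __post_init__(self) -> None:
        L, N, O = self.n_layers, self.n_hidden, self.n_classes
        if self.w_deep.shape != (L, L * N) or self.w_spatial.shape != (N, L * N):
            raise ValueError("attention weight shapes inconsistent with L and N")
        if self.w_out.shape != (O, N):
            raise ValueError("readout weight shape inconsistent with N")
        for w in (self.w_deep, self.w_spatial, self.w_out):
            if not np.all(np.isfinite(w)):
                raise ValueError("weights must be finite")

    @classmethod
    def create(cls, n_layers: int, n_hidden: int, n_classes: int,
               seed: int = 0, init_scale: float = 0.01) -> "AttentionParams":
        rng = np.random.default_rng(seed)
        return cls(
            w_deep=init_scale * rng.standard_normal((n_layers, n_layers * n_hidden)),
            w_spatial=init_scale
            * rng.standard_normal((n_hidden, n_layers * n_hidden)),
            w_out=init_scale * rng.standard_normal((n_classes, n_hidden)),
        )

    def standardize(self, x_deep: np.ndarray) -> np.ndarray:
        if self.mean is None:
            return x_deep
        return (x_deep - self.mean) / self.scale


def deep_attention(x_deep: np.ndarray, w_deep: np.ndarray) -> np.ndarray:
    """Layer-importance coefficients: softmax over per-layer logits.

    Always a proper distribution over layers (sums to 1, each in (0,1));
    shifting all logits by a constant leaves it unchanged.
    """
    x_deep = np.asarray(x_deep, dtype=float)
    if x_deep.shape[-1] != w_deep.shape[1]:
        raise ValueError("x_deep length does not match deep-attention fan-in")
    return _softmax(w_deep @ x_deep, axis=0)


def collapse_layers(x_deep: np.ndarray, a_deep: np.ndarray) -> np.ndarray:
    """Convex combination of the per-layer states: ``X_S = sum_l A_l X_l``."""
    a_deep = np.asarray(a_deep, dtype=float)
    L = a_deep.shape[0]
    layers = np.asarray(x_deep, dtype=float).reshape(L, -1)
    return a_deep @ layers


def spatial_attention(x_deep: np.ndarray, w_spatial: np.ndarray) -> np.ndarray:
    """Independent per-neuron gates in (0,1): sigmoid of each gate logit."""
    return _sigmoid(w_spatial @ np.asarray(x_deep, dtype=float))


def readout(x_deep: np.ndarray, params: AttentionParams
            ) -> tuple[np.ndarray, int]:
    """Full attention-readout chain: class scores and predicted label.

    ``y = sigmoid(W_out @ (X_S * A_spatial))``; the label is the argmax
    (ties resolve to the lowest class index).
    """
    x = params.standardize(np.asarray(x_deep, dtype=float))
    a_deep = deep_attention(x, params.w_deep)
    x_s = collapse_layers(x, a_deep)
    a_sp = spatial_attention(x, params.w_spatial)
    y = _sigmoid(params.w_out @ (x_s * a_sp))
    return y, int(np.argmax(y))


def predict(snapshots: np.ndarray, params: AttentionParams,
            noise_sigma: float = 0.0, noise_seed: int = 0) -> np.ndarray:
    """Predicted labels for a batch of state snapshots.

    ``noise_sigma`` adds fresh Gaussian read noise to each weight block
    per evaluation (analog weight-storage emulation); zero sigma is
    bit-identical to the noise-free path.
    """
    p = params
    if noise_sigma:
        from .reservoir import NoisyWeightStore

        stores = [
            NoisyWeightStore(w, sigma_read=noise_sigma, seed=noise_seed + i)
            for i, w in enumerate((p.w_deep, p.w_spatial, p.w_out))
        ]
        p = AttentionParams(
            w_deep=stores[0].read(),
            w_spatial=stores[1].read(),
            w_out=stores[2].read(),
            mean=params.mean,
            scale=params.scale,
        )
    return np.array([readout(x, p)[1] for x in np.atleast_2d(snapshots)])


def loss_and_gradients(
    params: AttentionParams,
    snapshots: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean softmax-cross-entropy over ``y`` and its analytic gradients.

    Manual backpropagation through the readout chain only; verified
    against central finite differences in the test suite.  Snapshots are
    assumed already standardized.
    """
    X = np.atleast_2d(np.asarray(snapshots, dtype=float))  # (B, L*N)
    labels = np.asarray(labels, dtype=int)
    B = X.shape[0]
    L, N, O = params.n_layers, params.n_hidden, params.n_classes

    A_logits = X @ params.w_deep.T               # (B, L)
    A = _softmax(A_logits, axis=1)
    Xl = X.reshape(B, L, N)
    Xs = np.einsum("bl,bln->bn", A, Xl)          # (B, N)
    S_logits = X @ params.w_spatial.T            # (B, N)
    Asp = _sigmoid(S_logits)
    Xf = Xs * Asp
    Z = Xf @ params.w_out.T                      # (B, O)
    Y = _sigmoid(Z)
    P = _softmax(Y, axis=1)
    loss = float(-np.mean(np.log(P[np.arange(B), labels] + 1e-300)))

    dY = P.copy()
    dY[np.arange(B), labels] -= 1.0
    dY /= B
    dZ = dY * Y * (1.0 - Y)
    g_out = dZ.T @ Xf                            # (O, N)
    dXf = dZ @ params.w_out                      # (B, N)
    dAsp = dXf * Xs
    dXs = dXf * Asp
    dS = dAsp * Asp * (1.0 - Asp)
    g_spatial = dS.T @ X                         # (N, L*N)
    dA = np.einsum("bn,bln->bl", dXs, Xl)        # (B, L)
    dAl = A * (dA - np.sum(A * dA, axis=1, keepdims=True))
    g_deep = dAl.T @ X                           # (L, L*N)
    return loss, {"w_deep": g_deep, "w_spatial": g_spatial, "w_out": g_out}


def train_readout(
    snapshots: np.ndarray,
    labels: np.ndarray,
    n_layers: int,
    lr: float = 0.05,
    epochs: int = 500,
    seed: int = 0,
    standardize: bool = True,
    weight_decay: float = 0.0,
) -> tuple[AttentionParams, np.ndarray]:
    """Full-batch gradient descent on the attention-readout weights.

    The reservoirs and WTA layers are frozen — snapshots are constants —
    so this is ordinary feed-forward training, deterministic under the
    seed.  A single global shift/scale (fitted here, stored in the
    returned params) conditions the gradient while preserving the
    relative magnitudes of the layer blocks, so weakly active deep
    layers are not noise-amplified.  Returns the trained parameters and
    the loss curve.
    """
    X = np.atleast_2d(np.asarray(snapshots, dtype=float))
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("training requires at least two classes")
    n_hidden = X.shape[1] // n_layers
    if n_hidden * n_layers != X.shape[1]:
        raise ValueError("snapshot length is not a multiple of n_layers")
    params = AttentionParams.create(
        n_layers, n_hidden, int(classes.max()) + 1, seed=seed
    )
    if standardize:
        params.mean = np.full(X.shape[1], X.mean())
        params.scale = np.full(X.shape[1], X.std() + 1e-8)
        X = (X - params.mean) / params.scale

    losses = np.empty(epochs)
    for e in range(epochs):
        loss, grads = loss_and_gradients(params, X, labels)
        losses[e] = loss
        for name in ("w_deep", "w_spatial", "w_out"):
            w = getattr(params, name)
            w -= lr * (grads[name] + weight_decay * w)
    return params, losses
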