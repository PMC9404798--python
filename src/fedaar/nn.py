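"""Lightweight numpy CNN classifiers with flat-parameter access.

Federated aggregation treats a model as a single flat vector of trainable
weights, so the model contract here is deliberately small: deterministic
initialisation from a seed, forward pass to logits, penultimate-layer feature
extraction, exact manual backpropagation, and a stable flatten/unflatten of
all parameters.

Two architectures are provided:

``small_cnn``
    two temporal-convolution blocks (valid 1-D convolution -> ReLU -> max-pool
    by 2) over all input channels, global average pooling over time, a linear
    layer to a ``feature_dim``-dimensional ReLU feature, and a linear head to
    class logits.

``dual_branch_cnn``
    the same, but with separate convolution trunks for the first and second
    half of the channels (accelerometer vs gyroscope) whose pooled outputs are
    concatenated before the feature layer — a nod to dual-trunk designs used
    for cross-modality motion data.

Neither architecture uses batch normalisation, so the flat parameter vector
fully determines behaviour and gradient refinement operates on pure trainable
weights.

Parameter ordering is layer-major in declaration order: for each trunk in
order, ``conv1_w, conv1_b, conv2_w, conv2_b``; then ``fc_w, fc_b, head_w,
head_b``.  Arrays are flattened in C order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ModelSpec", "ConvNet", "Adam", "init_model", "softmax_cross_entropy"]

_ARCHITECTURES = ("small_cnn", "dual_branch_cnn")


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyper-parameters; fully determines the parameter layout."""

    n_classes: int
    window_len: int
    architecture: str = "small_cnn"
    feature_dim: int = 64
    n_channels: int = 6
    hidden: tuple[int, int] = (16, 32)
    kernel_size: int = 5
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in _ARCHITECTURES:
            raise ValueError(f"architecture must be one of {_ARCHITECTURES}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")
        if self.architecture == "dual_branch_cnn" and self.n_channels % 2:
            raise ValueError("dual_branch_cnn needs an even channel count")
        k = self.kernel_size
        length = self.window_len
        for _ in range(2):
            length = (length - k + 1) // 2
        if length < 1:
            raise ValueError(
                f"window_len={self.window_len} too short for two "
                f"conv(kernel={k})+pool blocks"
            )


def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Valid 1-D convolution. x: (B, Cin, L), w: (Cout, Cin, k) -> (B, Cout, L-k+1)."""
    xw = sliding_window_view(x, w.shape[2], axis=2)       # (B, Cin, Lo, k)
    y = np.einsum("fck,bclk->bfl", w, xw, optimize=True) + b[:, None]
    return y, xw


def _conv1d_backward(
    dy: np.ndarray, xw: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = w.shape[2]
    dw = np.einsum("bfl,bclk->fck", dy, xw, optimize=True)
    db = dy.sum(axis=(0, 2))
    dyp = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
    dyw = sliding_window_view(dyp, k, axis=2)             # (B, Cout, L, k)
    dx = np.einsum("bflk,fck->bcl", dyw, w[:, :, ::-1], optimize=True)
    return dx, dw, db


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Max-pool by 2 along time, dropping a trailing odd sample."""
    L = x.shape[2]
    Le = L - (L % 2)
    xr = x[:, :, :Le].reshape(x.shape[0], x.shape[1], Le // 2, 2)
    arg = xr.argmax(axis=3)
    y = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
    return y, arg, L


def _maxpool2_backward(dy: np.ndarray, arg: np.ndarray, L: int) -> np.ndarray:
    B, C, P = dy.shape
    dxr = np.zeros((B, C, P, 2))
    np.put_along_axis(dxr, arg[..., None], dy[..., None], axis=3)
    dx = np.zeros((B, C, L))
    dx[:, :, : 2 * P] = dxr.reshape(B, C, 2 * P)
    return dx


class ConvNet:
    """A small temporal CNN with exact manual backpropagation.

    Two models holding equal flat parameter vectors produce equal outputs on
    equal inputs; there is no hidden state.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        if spec.architecture == "small_cnn":
            self._slices = [(0, spec.n_channels)]
        else:
            half = spec.n_channels // 2
            self._slices = [(0, half), (half, spec.n_channels)]
        h1, h2 = spec.hidden
        k, d, C = spec.kernel_size, spec.feature_dim, spec.n_classes
        template: list[tuple[str, tuple[int, ...]]] = []
        for t, (lo, hi) in enumerate(self._slices):
            cin = hi - lo
            template += [
                (f"trunk{t}.conv1_w", (h1, cin, k)),
                (f"trunk{t}.conv1_b", (h1,)),
                (f"trunk{t}.conv2_w", (h2, h1, k)),
                (f"trunk{t}.conv2_b", (h2,)),
            ]
        trunk_out = h2 * len(self._slices)
        template += [
            ("fc_w", (d, trunk_out)),
            ("fc_b", (d,)),
            ("head_w", (C, d)),
            ("head_b", (C,)),
        ]
        self._template = template
        self.params = self._init_params()

    def _init_params(self) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(self.spec.init_seed)
        params: dict[str, np.ndarray] = {}
        for name, shape in self._template:
            if name.endswith("_b"):
                params[name] = np.zeros(shape)
            else:
                fan_in = int(np.prod(shape[1:]))
                scale = 1.0 if name.startswith("head") else 2.0
                params[name] = rng.normal(0.0, np.sqrt(scale / fan_in), size=shape)
        return params

    # -- flat parameter access --------------------------------------------

    @property
    def n_params(self) -> int:
        return sum(int(np.prod(shape)) for _, shape in self._template)

    def get_flat_params(self) -> np.ndarray:
        return np.concatenate([self.params[n].ravel() for n, _ in self._template])

    def set_flat_params(self, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=np.float64)
        if values.shape != (self.n_params,):
            raise ValueError(
                f"parameter vector has length {values.size}, expected {self.n_params}"
            )
        pos = 0
        for name, shape in self._template:
            size = int(np.prod(shape))
            self.params[name] = values[pos : pos + size].reshape(shape).copy()
            pos += size

    # -- forward / backward ------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[2] != self.spec.n_channels:
            raise ValueError(
                f"expected input of shape (B, W, {self.spec.n_channels}), got {x.shape}"
            )
        return x

    def forward_full(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """Forward pass keeping the intermediates needed for backprop.

        Input convention: ``x`` is (B, W, channels) as stored in datasets.
        """
        x = self._check_input(x)
        xc = np.ascontiguousarray(x.transpose(0, 2, 1))   # (B, C, W)
        p = self.params
        cache: dict = {"trunks": []}
        gaps = []
        for t, (lo, hi) in enumerate(self._slices):
            xt = xc[:, lo:hi, :]
            h1, xw1 = _conv1d(xt, p[f"trunk{t}.conv1_w"], p[f"trunk{t}.conv1_b"])
            r1 = np.maximum(h1, 0.0)
            p1, arg1, L1 = _maxpool2(r1)
            h2, xw2 = _conv1d(p1, p[f"trunk{t}.conv2_w"], p[f"trunk{t}.conv2_b"])
            r2 = np.maximum(h2, 0.0)
            p2, arg2, L2 = _maxpool2(r2)
            gaps.append(p2.mean(axis=2))
            cache["trunks"].append(
                dict(xw1=xw1, h1=h1, arg1=arg1, L1=L1, p1=p1,
                     xw2=xw2, h2=h2, arg2=arg2, L2=L2, p2_len=p2.shape[2])
            )
        z = np.concatenate(gaps, axis=1)                  # (B, trunk_out)
        feat_pre = z @ p["fc_w"].T + p["fc_b"]
        feat = np.maximum(feat_pre, 0.0)
        logits = feat @ p["head_w"].T + p["head_b"]
        cache.update(z=z, feat_pre=feat_pre, feat=feat)
        return logits, cache

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class logits, shape (B, n_classes)."""
        return self.forward_full(x)[0]

    def features(self, x: np.ndarray) -> np.ndarray:
        """Penultimate-layer features, shape (B, feature_dim).

        The head is a pure linear map of these features:
        ``forward(x) == features(x) @ head_w.T + head_b``.
        """
        _, cache = self.forward_full(x)
        return cache["feat"]

    def backward(
        self,
        cache: dict,
        dlogits: np.ndarray,
        dfeat_extra: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Gradient of the loss w.r.t. the flat parameter vector.

        ``dlogits`` is dLoss/dlogits; ``dfeat_extra`` is an optional extra
        dLoss/dfeatures term (e.g. from a feature-space regulariser) that by
        construction never touches the head weights.
        """
        p = self.params
        grads: dict[str, np.ndarray] = {}
        feat, feat_pre, z = cache["feat"], cache["feat_pre"], cache["z"]
        grads["head_w"] = dlogits.T @ feat
        grads["head_b"] = dlogits.sum(axis=0)
        dfeat = dlogits @ p["head_w"]
        if dfeat_extra is not None:
            dfeat = dfeat + dfeat_extra
        dfeat_pre = dfeat * (feat_pre > 0)
        grads["fc_w"] = dfeat_pre.T @ z
        grads["fc_b"] = dfeat_pre.sum(axis=0)
        dz = dfeat_pre @ p["fc_w"]
        h2_width = self.spec.hidden[1]
        for t, tc in enumerate(cache["trunks"]):
            dgap = dz[:, t * h2_width : (t + 1) * h2_width]
            dp2 = np.repeat(dgap[:, :, None] / tc["p2_len"], tc["p2_len"], axis=2)
            dr2 = _maxpool2_backward(dp2, tc["arg2"], tc["L2"])
            dh2 = dr2 * (tc["h2"] > 0)
            dp1, dw2, db2 = _conv1d_backward(dh2, tc["xw2"], p[f"trunk{t}.conv2_w"])
            dr1 = _maxpool2_backward(dp1, tc["arg1"], tc["L1"])
            dh1 = dr1 * (tc["h1"] > 0)
            _, dw1, db1 = _conv1d_backward(dh1, tc["xw1"], p[f"trunk{t}.conv1_w"])
            grads[f"trunk{t}.conv1_w"] = dw1
            grads[f"trunk{t}.conv1_b"] = db1
            grads[f"trunk{t}.conv2_w"] = dw2
            grads[f"trunk{t}.conv2_b"] = db2
        return np.concatenate([grads[n].ravel() for n, _ in self._template])

    def predict(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Predicted labels in 1..C; argmax ties break toward the lowest class."""
        out = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start : start + batch_size])
            out.append(np.argmax(logits, axis=1) + 1)
        return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def init_model(spec: ModelSpec) -> tuple[ConvNet, np.ndarray]:
    """Build a model and return it with its (deterministic) flat parameters."""
    model = ConvNet(spec)
    return model, model.get_flat_params()


def softmax_cross_entropy(
    logits: np.ndarray, labels0: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. logits.

    ``labels0`` are 0-based class indices.
    """
    B = logits.shape[0]
    shifted = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(shifted).sum(axis=1))
    loss = float(np.mean(logsumexp - shifted[np.arange(B), labels0]))
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    probs[np.arange(B), labels0] -= 1.0
    return loss, probs / B


class Adam:
    """Adam with L2 weight decay folded into the gradient (the classic
    ``weight_decay`` convention), acting on a flat parameter vector."""

    def __init__(
        self,
        n_params: int,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = np.zeros(n_params)
        self.v = np.zeros(n_params)
        self.t = 0

    def step(self, w: np.ndarray, grad: np.ndarray) -> np.ndarray:
        if self.weight_decay:
            grad = grad + self.weight_decay * w
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        return w - self.lr * mhat / (np.sqrt(vhat) + self.eps)
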