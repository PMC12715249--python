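"""Capsule-network primitives, a desk-scale CapsNet, a small CNN baseline,
and the training harness (Adam, gradient clipping, LR decay, early stopping).

Capsule networks represent a class as a vector whose length encodes the
probability that the class is present. Primary capsules are produced by a
convolutional stem; their predictions for each output ("digit") capsule
are combined by routing-by-agreement: coupling logits start at zero
(uniform couplings), each iteration forms the coupled sum, squashes it,
and reinforces the logits by the dot product between each prediction and
the resulting output vector. Three routing iterations are the default.

Implementation notes: everything is plain numpy with hand-written
gradients. The CapsNet trains its (channel-shared) routing transform and
decoder over a frozen seeded random convolutional stem, treating coupling
coefficients as constants in the gradient — the usual desk-scale
approximation to backpropagating through routing. The baseline CNN is
trained end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mitigation import FocalParams, MarginParams

# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Capsule nonlinearity: v = (|s|^2 / (1 + |s|^2)) * s/|s|; squash(0) = 0."""
    s = np.asarray(s, float)
    sq = np.sum(s * s, axis=axis, keepdims=True)
    norm = np.sqrt(sq)
    scale = np.divide(norm, 1.0 + sq, out=np.zeros_like(norm), where=norm > 0)
    return scale * s


@dataclass
class RoutingState:
    predictions: np.ndarray  # (n_primary, n_out, d_out)
    logits: np.ndarray       # (n_primary, n_out)
    couplings: np.ndarray    # softmax of logits over outputs
    outputs: np.ndarray      # (n_out, d_out)
    agreements: np.ndarray   # (n_primary, n_out)


def _softmax(x: np.ndarray, axis: int) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def dynamic_routing(predictions: np.ndarray, r: int = 3) -> RoutingState:
    """Routing-by-agreement over prediction vectors u_hat (i -> j).

    Logits b_ij start at 0 (couplings uniform over output capsules).
    Each of the ``r`` iterations computes c = softmax_j(b),
    s_j = sum_i c_ij u_hat_ij, v_j = squash(s_j), and updates
    b_ij += u_hat_ij . v_j.
    """
    u = np.asarray(predictions, float)
    if u.ndim != 3:
        raise ValueError("predictions must be (n_primary, n_out, d_out)")
    if not np.all(np.isfinite(u)):
        raise ValueError("predictions contain non-finite values")
    if r < 1:
        raise ValueError("r must be >= 1")
    n_in, n_out, _ = u.shape
    b = np.zeros((n_in, n_out))
    for _ in range(r):
        c = _softmax(b, axis=1)
        s = np.einsum("ij,ijd->jd", c, u)
        v = squash(s, axis=-1)
        a = np.einsum("ijd,jd->ij", u, v)
        b = b + a
    return RoutingState(predictions=u, logits=b, couplings=c, outputs=v, agreements=a)


def _route_batch(u: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched routing with coupling-normalized sums.

    Identical update equations to :func:`dynamic_routing`, except the
    coupled sum is divided by the total coupling mass per output capsule
    (a weighted mean). With tens of thousands of primary capsules the
    plain sum drives squash deep into saturation where gradients vanish;
    the normalized form keeps capsule lengths in the responsive range at
    any primary-capsule count. Returns (couplings, weights, outputs).
    """
    n, n_in, n_out, _ = u.shape
    b = np.zeros((n, n_in, n_out), dtype=u.dtype)
    for _ in range(r):
        c = _softmax(b, axis=2)
        w = c / np.maximum(c.sum(axis=1, keepdims=True), 1e-12)
        s = np.einsum("nij,nijd->njd", w, u)
        v = squash(s, axis=-1)
        b = b + np.einsum("nijd,njd->nij", u, v)
    return c, w, v


def _squash_backward(s: np.ndarray, dv: np.ndarray) -> np.ndarray:
    """Jacobian-transpose product of squash along the last axis."""
    sq = np.sum(s * s, axis=-1, keepdims=True)
    n = np.sqrt(np.maximum(sq, 1e-30))
    g = n / (1.0 + sq)                       # v = g(|s|) * s / ... actually v = (n/(1+n^2)) s
    dg_dn = (1.0 - sq) / (1.0 + sq) ** 2
    s_dot_dv = np.sum(s * dv, axis=-1, keepdims=True)
    return g * dv + dg_dn / np.maximum(n, 1e-30) * s_dot_dv * s


# ---------------------------------------------------------------------------
# conv helpers (im2col)
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """x (n, H, W, C) -> patches (n, oh*ow, k*k*C), valid padding."""
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (n, oh, ow, C, k, k)
    n, oh, ow = win.shape[:3]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n, oh * ow, k * k * x.shape[3])
    return np.ascontiguousarray(cols)


def _conv_out(side: int, k: int, stride: int) -> int:
    out = (side - k) / stride + 1
    if out < 1 or out != int(out):
        raise ValueError(f"kernel {k}/stride {stride} incompatible with side {side} "
                         f"(would give {out} positions)")
    return int(out)


# ---------------------------------------------------------------------------
# loss gradients on scores
# ---------------------------------------------------------------------------


@dataclass
class LossSpec:
    """Which objective drives training: ce | wce | focal | margin."""

    kind: str = "ce"
    weights: np.ndarray | None = None          # (3,) for wce, CN/MCI/AD order
    focal: FocalParams = field(default_factory=FocalParams)
    margin: MarginParams = field(default_factory=MarginParams)

    def __post_init__(self) -> None:
        if self.kind not in ("ce", "wce", "focal", "margin"):
            raise ValueError(f"unknown loss kind {self.kind!r}")


def _prob_loss_and_dlogits(probs, y, spec: LossSpec):
    n = len(y)
    idx = np.arange(n)
    p_y = np.clip(probs[idx, y], 1e-7, 1 - 1e-7)
    onehot = np.zeros_like(probs)
    onehot[idx, y] = 1.0
    if spec.kind == "ce":
        loss = float(np.mean(-np.log(p_y)))
        dlogits = (probs - onehot) / n
    elif spec.kind == "wce":
        w = np.asarray(spec.weights, float)[y]
        loss = float(np.mean(-w * np.log(p_y)))
        dlogits = w[:, None] * (probs - onehot) / n
    elif spec.kind == "focal":
        g, alpha = spec.focal.gamma, np.asarray(spec.focal.alpha)[y]
        loss = float(np.mean(-alpha * (1 - p_y) ** g * np.log(p_y)))
        # d/dp [-alpha (1-p)^g log p] = alpha g (1-p)^(g-1) log p - alpha (1-p)^g / p
        dldp = (alpha * g * (1 - p_y) ** np.maximum(g - 1, 0) * np.log(p_y)
                - alpha * (1 - p_y) ** g / p_y)
        # dp_y/dlogit_k = p_y (delta_yk - p_k)
        dlogits = (dldp * p_y)[:, None] * (onehot - probs) / n
    else:
        raise ValueError("margin loss applies to capsule lengths, not probabilities")
    return loss, dlogits


def _margin_loss_and_dlengths(lengths, y, params: MarginParams):
    n = len(y)
    T = np.zeros_like(lengths)
    T[np.arange(n), y] = 1.0
    pos = np.maximum(0.0, params.m_plus - lengths)
    neg = np.maximum(0.0, lengths - params.m_minus)
    loss = float(np.mean((T * pos**2 + params.lam * (1 - T) * neg**2).sum(axis=1)))
    dL = (-2 * T * pos + 2 * params.lam * (1 - T) * neg) / n
    return loss, dL


# ---------------------------------------------------------------------------
# CapsNet
# ---------------------------------------------------------------------------


@dataclass
class CapsNetSpec:
    input_side: int = 64
    conv_filters: int = 256
    conv_kernel: int = 9
    primary_channels: int = 32
    primary_dim: int = 8
    primary_kernel: int = 6
    primary_stride: int = 2
    n_classes: int = 3
    digit_dim: int = 16
    routing_iters: int = 3
    recon_side: int = 64
    decoder_hidden: tuple[int, int] = (512, 1024)

    def __post_init__(self) -> None:
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if min(self.primary_dim, self.digit_dim) < 1:
            raise ValueError("capsule dims must be positive")
        # raises with computed shapes if the stem arithmetic does not work out
        self.stem_side = _conv_out(self.input_side, self.conv_kernel, 1)
        self.primary_side = _conv_out(self.stem_side, self.primary_kernel,
                                      self.primary_stride)
        self.n_primary = self.primary_side**2 * self.primary_channels


def parameter_count(spec: CapsNetSpec) -> int:
    """Analytic parameter count of the architecture described by ``spec``.

    Routing transform weights are shared across spatial positions within
    each primary-capsule channel; the reconstruction decoder maps the
    masked digit-capsule vector through two hidden layers to a
    ``recon_side``-square target.
    """
    k, f = spec.conv_kernel, spec.conv_filters
    stem = k * k * 1 * f + f
    pk, pc, pd = spec.primary_kernel, spec.primary_channels, spec.primary_dim
    primary = pk * pk * f * (pc * pd) + pc * pd
    routing = pc * spec.n_classes * pd * spec.digit_dim
    h1, h2 = spec.decoder_hidden
    d_in = spec.n_classes * spec.digit_dim
    decoder = (d_in * h1 + h1) + (h1 * h2 + h2) + (h2 * spec.recon_side**2
                                                   + spec.recon_side**2)
    return stem + primary + routing + decoder


class CapsNet:
    """Desk-scale capsule classifier; scores are digit-capsule lengths in [0, 1)."""

    def __init__(self, spec: CapsNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        k, f = spec.conv_kernel, spec.conv_filters
        pc, pd = spec.primary_channels, spec.primary_dim
        pk = spec.primary_kernel
        self.params = {
            "conv1_w": (rng.standard_normal((k * k * 1, f)) * np.sqrt(2.0 / (k * k))
                        ).astype(np.float32),
            "conv1_b": np.zeros(f, dtype=np.float32),
            "prim_w": (rng.standard_normal((pk * pk * f, pc * pd))
                       * np.sqrt(2.0 / (pk * pk * f))).astype(np.float32),
            "prim_b": np.zeros(pc * pd, dtype=np.float32),
            "route_w": (rng.standard_normal((pc, spec.n_classes, pd, spec.digit_dim))
                        * 0.5 / np.sqrt(pd)).astype(np.float32),
        }
        # frozen random stem at desk scale; only the routing transform trains
        self.trainable = ("route_w",)
        self._chunk = 4

    # -- forward ------------------------------------------------------------

    def _primary_caps(self, X: np.ndarray) -> np.ndarray:
        """images (n, side, side) in [0, 255] -> squashed primary capsules
        (n, P, channels, dim) with P spatial positions."""
        sp = self.spec
        x = (np.asarray(X, np.float32) / 255.0 - 0.5)[..., None]
        outs = []
        for lo in range(0, len(x), self._chunk):
            xb = x[lo:lo + self._chunk]
            c1 = _im2col(xb, sp.conv_kernel, 1) @ self.params["conv1_w"] + self.params["conv1_b"]
            c1 = np.maximum(c1, 0.0)
            n, _, _ = c1.shape
            c1 = c1.reshape(n, sp.stem_side, sp.stem_side, sp.conv_filters)
            cols = _im2col(c1, sp.primary_kernel, sp.primary_stride)
            pc = cols @ self.params["prim_w"] + self.params["prim_b"]
            P = sp.primary_side**2
            outs.append(pc.reshape(n, P, sp.primary_channels, sp.primary_dim))
        u = np.concatenate(outs, axis=0)
        return squash(u, axis=-1)

    def _predictions(self, caps: np.ndarray) -> np.ndarray:
        """(n, P, C, D) -> u_hat (n, P*C, J, digit_dim) via channel-shared W."""
        sp = self.spec
        uh = np.einsum("npcd,cjde->npcje", caps, self.params["route_w"])
        n = caps.shape[0]
        return uh.reshape(n, sp.n_primary, sp.n_classes, sp.digit_dim)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class scores = capsule lengths, shape (n, n_classes), values in [0, 1)."""
        caps = self._primary_caps(X)
        uh = self._predictions(caps)
        _, _, v = _route_batch(uh, self.spec.routing_iters)
        return np.linalg.norm(v, axis=-1)

    # -- training interface -------------------------------------------------

    def loss_and_grads(self, X, y, loss: LossSpec):
        if loss.kind != "margin":
            raise ValueError("the capsule head trains with the margin loss")
        sp = self.spec
        caps = self._primary_caps(X)                      # (n, P, C, D)
        uh4 = self._predictions(caps)                     # (n, I, J, E)
        _, w, v = _route_batch(uh4, sp.routing_iters)     # couplings treated as constants
        lengths = np.linalg.norm(v, axis=-1)
        lval, dL = _margin_loss_and_dlengths(lengths, y, loss.margin)
        dv = dL[..., None] * v / np.maximum(lengths[..., None], 1e-12)
        s = np.einsum("nij,nijd->njd", w, uh4)
        ds = _squash_backward(s, dv)                      # (n, J, E)
        duh = w[..., None] * ds[:, None, :, :]            # (n, I, J, E)
        n = X.shape[0]
        duh5 = duh.reshape(n, sp.primary_side**2, sp.primary_channels,
                           sp.n_classes, sp.digit_dim)
        d_route = np.einsum("npcd,npcje->cjde", caps, duh5)
        return lval, {"route_w": d_route.astype(np.float32)}


# ---------------------------------------------------------------------------
# baseline CNN
# ---------------------------------------------------------------------------


class BaselineCNN:
    """Small convolutional softmax classifier (the desk-scale stand-in for
    large pretrained backbones); emits probability rows on the simplex."""

    def __init__(self, input_side: int = 64, seed: int = 0,
                 n_filters: int = 8, kernel: int = 7, stride: int = 4,
                 hidden: int = 32, n_classes: int = 3):
        if input_side < 32:
            raise ValueError("input side must be >= 32")
        self.side = input_side
        self.kernel, self.stride = kernel, stride
        self.out_side = (input_side - kernel) // stride + 1  # valid conv, floored
        rng = np.random.default_rng(seed)
        d_flat = self.out_side**2 * n_filters
        self.params = {
            "conv_w": rng.standard_normal((kernel * kernel, n_filters))
            * np.sqrt(2.0 / (kernel * kernel)),
            "conv_b": np.zeros(n_filters),
            "h_w": rng.standard_normal((d_flat, hidden)) * np.sqrt(2.0 / d_flat),
            "h_b": np.zeros(hidden),
            "o_w": rng.standard_normal((hidden, n_classes)) * np.sqrt(2.0 / hidden),
            "o_b": np.zeros(n_classes),
        }
        self.trainable = tuple(self.params)

    def _forward_cached(self, X):
        x = (np.asarray(X, float) / 255.0 - 0.5)[..., None]
        cols = _im2col(x, self.kernel, self.stride)
        a1 = cols @ self.params["conv_w"] + self.params["conv_b"]
        r1 = np.maximum(a1, 0.0)
        flat = r1.reshape(len(X), -1)
        a2 = flat @ self.params["h_w"] + self.params["h_b"]
        r2 = np.maximum(a2, 0.0)
        logits = r2 @ self.params["o_w"] + self.params["o_b"]
        probs = _softmax(logits, axis=1)
        return probs, (cols, a1, flat, a2, r2)

    def forward(self, X: np.ndarray) -> np.ndarray:
        return self._forward_cached(X)[0]

    def loss_and_grads(self, X, y, loss: LossSpec):
        if loss.kind == "margin":
            raise ValueError("margin loss applies to capsule lengths")
        probs, (cols, a1, flat, a2, r2) = self._forward_cached(X)
        lval, dlogits = _prob_loss_and_dlogits(probs, np.asarray(y, int), loss)
        g = {}
        g["o_w"] = r2.T @ dlogits
        g["o_b"] = dlogits.sum(axis=0)
        dr2 = dlogits @ self.params["o_w"].T
        da2 = dr2 * (a2 > 0)
        g["h_w"] = flat.T @ da2
        g["h_b"] = da2.sum(axis=0)
        dflat = da2 @ self.params["h_w"].T
        da1 = dflat.reshape(a1.shape) * (a1 > 0)
        g["conv_w"] = np.einsum("npk,npf->kf", cols, da1)
        g["conv_b"] = da1.sum(axis=(0, 1))
        return lval, g


def build_capsnet(spec: CapsNetSpec | None = None, seed: int = 0) -> CapsNet:
    return CapsNet(spec or CapsNetSpec(), seed=seed)


def build_baseline_cnn(input_side: int = 64, seed: int = 0) -> BaselineCNN:
    return BaselineCNN(input_side=input_side, seed=seed)


def predict_scores(model, grids: np.ndarray) -> np.ndarray:
    """Per-sample class scores; argmax gives predicted labels.

    CNN rows lie on the probability simplex; capsule rows are vector
    lengths in [0, 1) and do not sum to 1.
    """
    grids = np.asarray(grids)
    if grids.ndim != 3:
        raise ValueError("grids must be (n, side, side)")
    scores = model.forward(grids)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    return scores


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    lr_decay: float = 0.9
    lr_decay_every: int = 100
    grad_clip: float = 0.5
    batch_size: int = 16
    patience: int = 50
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.lr_decay, self.grad_clip,
               self.batch_size, self.max_epochs) <= 0:
            raise ValueError("all training parameters must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class TrainData:
    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    leakage_ok: bool = True


def _clip_grads(grads: dict, max_norm: float) -> dict:
    total = np.sqrt(sum(float(np.sum(g.astype(np.float64)**2)) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        return {k: g * scale for k, g in grads.items()}
    return grads


def train_model(model, data: TrainData, loss: LossSpec,
                config: TrainingConfig) -> tuple[object, list[dict]]:
    """Adam training loop with LR decay, gradient clipping and early stopping.

    Stops when the validation loss has failed to improve for ``patience``
    consecutive epochs (patience 0: first non-improving epoch) and
    restores the best parameters. Fully deterministic for a fixed config.
    Raises if the data is flagged as having failed leakage verification.
    """
    if not data.leakage_ok:
        raise ValueError("refusing to train: leakage verification not passed")
    rng = np.random.default_rng(config.seed)
    m = {k: np.zeros_like(model.params[k]) for k in model.trainable}
    vv = {k: np.zeros_like(model.params[k]) for k in model.trainable}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_val = np.inf
    best_params = {k: model.params[k].copy() for k in model.trainable}
    stale = 0
    history: list[dict] = []
    n = len(data.X_train)
    for epoch in range(config.max_epochs):
        lr = config.learning_rate * config.lr_decay ** (epoch // config.lr_decay_every)
        order = rng.permutation(n)
        ep_loss = 0.0
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            lval, grads = model.loss_and_grads(data.X_train[idx], data.y_train[idx], loss)
            grads = _clip_grads(grads, config.grad_clip)
            t += 1
            for k in model.trainable:
                g = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                vv[k] = beta2 * vv[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**t)
                vhat = vv[k] / (1 - beta2**t)
                model.params[k] = model.params[k] - lr * mhat / (np.sqrt(vhat) + eps)
            ep_loss += lval * len(idx)
        val_loss, _ = model.loss_and_grads(data.X_val, data.y_val, loss)
        history.append({"epoch": epoch, "train_loss": ep_loss / n,
                        "val_loss": float(val_loss), "lr": lr})
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = {k: model.params[k].copy() for k in model.trainable}
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break
    for k in model.trainable:
        model.params[k] = best_params[k]
    return model, history
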