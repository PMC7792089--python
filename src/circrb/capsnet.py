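"""Capsule-network model core.

Architecture (one forward pass over an ``L x 4`` one-hot fragment):

1. **Convolution motif detectors** — ``K`` filters of width ``h`` slide over
   the fragment; each position yields ``ReLU(sum_j w_j . x_j + b)``, giving a
   feature map of length ``L - h + 1`` per filter.  All-zero (``N``) rows
   contribute nothing to the sum, so N-padding is inert.
2. **Global max pooling** — one scalar per filter, the maximum response of
   that detector anywhere on the fragment (argmax retained for motif
   discovery).  Optional: the ablation mode feeds the full maps forward.
3. **Primary capsules** — the ``K`` pooled responses are regrouped into
   ``n = K / 8`` capsules of dimension 8 and squashed so each capsule's norm
   lies in [0, 1).
4. **Affine transform** — a learned ``16 x 8`` matrix per (input capsule,
   output capsule) pair produces prediction vectors ``u``.
5. **Dynamic routing** — ``T`` rounds of agreement-weighted averaging: the
   coupling coefficients are a softmax of accumulated agreement logits, the
   weighted sum is squashed, and each round adds ``v . u`` to the logits.
6. **Digit capsules** — two 16-dimensional output capsules (bound / not
   bound); the norm of each is the class confidence, and the positive
   capsule's norm is the binding score.

Training minimises the per-class margin loss
``T_c max(0, m+ - ||v_c||)^2 + lambda (1 - T_c) max(0, ||v_c|| - m-)^2``
summed over the two classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, softmax as t_softmax
from .encoding import OneHotMatrix

__all__ = [
    "CapsNetConfig",
    "LossConfig",
    "RoutingState",
    "CapsuleNetwork",
    "squash",
    "dynamic_routing",
    "margin_loss",
    "conv_feature_maps",
    "global_max_pool",
]

_EPS = 1e-8  # inside squash's norm


@dataclass(frozen=True)
class LossConfig:
    """Margin-loss constants; the true-class norm is pushed above ``m_plus``
    and the other class's below ``m_minus``."""

    m_plus: float = 0.9
    m_minus: float = 0.1
    lam: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.m_minus < self.m_plus < 1.0):
            raise ValueError("need 0 < m_minus < m_plus < 1")


@dataclass(frozen=True)
class CapsNetConfig:
    """Full architecture description (serialised into checkpoints)."""

    input_length: int
    kernel_size: int = 9
    n_filters: int = 128
    caps_dim: int = 8
    out_caps_dim: int = 16
    n_classes: int = 2
    routing_iters: int = 2
    maxpool: bool = True
    routing_softmax: str = "inputs"  # "inputs" (per-output softmax over the n
    # input capsules, the reading used here) or "outputs" (Sabour et al.)
    loss: LossConfig = field(default_factory=LossConfig)
    init_scale: float = 0.1

    def __post_init__(self):
        if self.input_length < self.kernel_size:
            raise ValueError("fragment shorter than the convolution window")
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if self.routing_softmax not in ("inputs", "outputs"):
            raise ValueError("routing_softmax must be 'inputs' or 'outputs'")
        flat = self.n_filters if self.maxpool else self.n_filters * self.map_length
        if flat % self.caps_dim != 0:
            raise ValueError(
                f"{flat} pooled features do not divide into {self.caps_dim}-dim capsules"
            )

    @property
    def map_length(self) -> int:
        return self.input_length - self.kernel_size + 1

    @property
    def n_primary(self) -> int:
        flat = self.n_filters if self.maxpool else self.n_filters * self.map_length
        return flat // self.caps_dim


@dataclass
class RoutingState:
    """Per-round internals of one routing execution (for inspection/tests)."""

    logits: list[np.ndarray]  # b after each round
    couplings: list[np.ndarray]  # c used in each round
    aggregates: list[np.ndarray]  # a = sum_i c_i u_i
    outputs: list[np.ndarray]  # v = squash(a)


# ---------------------------------------------------------------------------
# Functional pieces (numpy in, numpy out; the network wires the Tensor path)


def squash(v, axis: int = -1):
    """Norm-squashing nonlinearity ``(|v|^2 / (1 + |v|^2)) * v / |v|``.

    Direction is preserved; the norm maps to ``r^2 / (1 + r^2)`` in [0, 1).
    Accepts an ndarray or an autodiff :class:`Tensor` (the zero vector maps
    to zero via an epsilon guard on the norm).
    """
    if isinstance(v, Tensor):
        norm_sq = (v * v).sum(axis=axis, keepdims=True)
        norm = (norm_sq + _EPS**2).sqrt()
        return v * (norm_sq / (1.0 + norm_sq)) / norm
    v = np.asarray(v, dtype=np.float64)
    norm_sq = np.sum(v * v, axis=axis, keepdims=True)
    norm = np.sqrt(norm_sq + _EPS**2)
    return v * (norm_sq / (1.0 + norm_sq)) / norm


def _routing_t(u: Tensor, T: int, softmax_axis: str) -> Tensor:
    """Tensor-path dynamic routing; u has shape (B, n, n_classes, d_out)."""
    B, n, ncls, d = u.shape
    axis = 1 if softmax_axis == "inputs" else 2
    b_log = Tensor(np.zeros((B, n, ncls)))
    v = None
    for t in range(T):
        c = t_softmax(b_log, axis=axis)
        a = (c.reshape(B, n, ncls, 1) * u).sum(axis=1)  # (B, ncls, d)
        v = squash(a, axis=-1)
        if t < T - 1:
            agree = (v.reshape(B, 1, ncls, d) * u).sum(axis=-1)  # (B, n, ncls)
            b_log = b_log + agree
    return v


def dynamic_routing(
    u: np.ndarray,
    T: int,
    softmax_axis: str = "inputs",
    return_state: bool = False,
):
    """Route ``n`` prediction vectors into the output capsules.

    ``u`` has shape ``(n, n_classes, d_out)`` (one instance) or a leading
    batch axis.  Per round: couplings ``c = softmax(b)``, aggregate
    ``a = sum_i c_i u_i``, output ``v = squash(a)``, logit update
    ``b += v . u``.  Logits start at zero, so at ``T = 1`` the couplings are
    uniform and the output is ``squash(mean(u))``.
    """
    if T < 1:
        raise ValueError("routing needs at least one round")
    u = np.asarray(u, dtype=np.float64)
    single = u.ndim == 3
    if single:
        u = u[None]
    B, n, ncls, d = u.shape
    axis = 1 if softmax_axis == "inputs" else 2
    b = np.zeros((B, n, ncls))
    state = RoutingState([], [], [], [])
    for t in range(T):
        shifted = b - b.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        c = e / e.sum(axis=axis, keepdims=True)
        a = np.einsum("bnc,bncd->bcd", c, u)
        v = squash(a, axis=-1)
        b = b + np.einsum("bcd,bncd->bnc", v, u)
        state.logits.append(b[0] if single else b)
        state.couplings.append(c[0] if single else c)
        state.aggregates.append(a[0] if single else a)
        state.outputs.append(v[0] if single else v)
    v = state.outputs[-1]
    return (v, state) if return_state else v


def conv_feature_maps(X: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """ReLU convolution maps: X (B, L, 4) or (L, 4) -> (B, P, K) or (P, K)."""
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 2
    if single:
        X = X[None]
    K, hc = weights.shape
    h = hc // 4
    if X.shape[1] < h:
        raise ValueError(f"fragment length {X.shape[1]} shorter than window {h}")
    cols = _im2col(X, h)
    out = np.maximum(cols @ weights.T + bias, 0.0)
    return out[0] if single else out


def global_max_pool(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-filter maximum over positions, with leftmost argmax positions.

    ``maps`` is (P, K) or (B, P, K); returns (pooled, argmax) dropping the
    position axis.
    """
    maps = np.asarray(maps)
    if maps.shape[-2] == 0:
        raise ValueError("empty feature maps")
    axis = maps.ndim - 2
    idx = np.argmax(maps, axis=axis)
    pooled = np.take_along_axis(maps, np.expand_dims(idx, axis), axis=axis).squeeze(axis)
    return pooled, idx


def margin_loss(score_pos: float, score_neg: float, label: str, cfg: LossConfig = LossConfig()) -> float:
    """Two-class margin loss for a single instance.

    ``label`` is ``"positive"`` or ``"negative"``; the loss is summed over
    both capsules (true class hinged at ``m_plus`` from below, other class
    at ``m_minus`` from above, weighted by ``lam``).
    """
    if label not in ("positive", "negative"):
        raise ValueError(f"bad label {label!r}")
    total = 0.0
    for score, is_true in ((score_pos, label == "positive"), (score_neg, label == "negative")):
        if is_true:
            total += max(0.0, cfg.m_plus - score) ** 2
        else:
            total += cfg.lam * max(0.0, score - cfg.m_minus) ** 2
    return total


def _im2col(X: np.ndarray, h: int) -> np.ndarray:
    """(B, L, 4) -> (B, L - h + 1, h * 4) sliding windows (copy-free view)."""
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(X, (h, 4), axis=(1, 2))  # (B, P, 1, h, 4)
    B, P = win.shape[0], win.shape[1]
    return win.reshape(B, P, h * 4)


# ---------------------------------------------------------------------------
# The trainable network


class CapsuleNetwork:
    """All trainable state plus the differentiable forward pass.

    Parameters are float64 numpy arrays wrapped in autodiff Tensors:

    - ``conv_w`` (K, h*4), ``conv_b`` (K,) — motif detectors,
    - ``caps_w`` (n_primary, n_classes, d_out, d_in) — one affine matrix per
      (input capsule, output capsule) pair.
    """

    def __init__(self, config: CapsNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        h4 = config.kernel_size * 4
        s = config.init_scale
        self.params: dict[str, Tensor] = {
            "conv_w": Tensor(rng.normal(0.0, s, (config.n_filters, h4)), requires_grad=True),
            "conv_b": Tensor(np.zeros(config.n_filters), requires_grad=True),
            "caps_w": Tensor(
                rng.normal(
                    0.0,
                    s,
                    (config.n_primary, config.n_classes, config.out_caps_dim, config.caps_dim),
                ),
                requires_grad=True,
            ),
        }

    # -- forward -----------------------------------------------------------

    def forward_tensor(self, X: np.ndarray) -> Tensor:
        """Differentiable forward: X (B, L, 4) -> class-score Tensor (B, 2)."""
        cfg = self.config
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != cfg.input_length or X.shape[2] != 4:
            raise ValueError(
                f"input shape {X.shape[1:]} does not match model ({cfg.input_length}, 4)"
            )
        B = X.shape[0]
        cols = Tensor(np.ascontiguousarray(_im2col(X, cfg.kernel_size)))
        conv = (cols @ self.params["conv_w"].transpose((1, 0)) + self.params["conv_b"]).relu()
        if cfg.maxpool:
            feat = conv.max(axis=1)  # (B, K), leftmost-argmax ties
        else:
            feat = conv.transpose((0, 2, 1)).reshape(B, cfg.n_filters * cfg.map_length)
        prim = squash(feat.reshape(B, cfg.n_primary, cfg.caps_dim), axis=-1)
        v_r = prim.reshape(B, cfg.n_primary, 1, cfg.caps_dim, 1)
        u = (self.params["caps_w"] @ v_r).reshape(
            B, cfg.n_primary, cfg.n_classes, cfg.out_caps_dim
        )
        v_out = _routing_t(u, cfg.routing_iters, cfg.routing_softmax)
        scores = ((v_out * v_out).sum(axis=-1) + _EPS**2).sqrt()  # (B, 2)
        return scores

    def forward(self, M: OneHotMatrix | np.ndarray) -> tuple[float, float]:
        """Score one fragment; returns ``(score_pos, score_neg)`` in [0, 1)."""
        X = M.matrix if isinstance(M, OneHotMatrix) else np.asarray(M)
        s = self.forward_tensor(X[None] if X.ndim == 2 else X).data
        return float(s[0, 1]), float(s[0, 0])

    def predict_scores(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Positive-capsule norms for a batch (the binding scores)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        out = np.empty(X.shape[0])
        for lo in range(0, X.shape[0], batch_size):
            out[lo : lo + batch_size] = self.forward_tensor(X[lo : lo + batch_size]).data[:, 1]
        return out

    # -- loss --------------------------------------------------------------

    def loss_tensor(self, scores: Tensor, y: np.ndarray) -> Tensor:
        """Mean-over-batch margin loss; column c of ``scores`` is class c
        (0 = not bound, 1 = bound)."""
        cfg = self.config.loss
        y = np.asarray(y, dtype=np.int64)
        T_c = np.zeros(scores.shape)
        T_c[np.arange(len(y)), y] = 1.0
        present = (Tensor(T_c) * (cfg.m_plus - scores).relu().power(2)).sum(axis=1)
        absent = (Tensor(1.0 - T_c) * (scores - cfg.m_minus).relu().power(2)).sum(axis=1)
        return (present + cfg.lam * absent).mean()

    # -- persistence -------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            if arrays[k].shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = arrays[k].astype(np.float64).copy()

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        """Self-describing checkpoint: all weights + the full config."""
        cfg = asdict(self.config)
        meta = {"config": cfg, "extra": extra or {}, "format": "circrb-checkpoint-1"}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.state_arrays())

    @classmethod
    def load(cls, path: str | Path) -> "CapsuleNetwork":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            cfg_d = meta["config"]
            cfg_d["loss"] = LossConfig(**cfg_d["loss"])
            net = cls(CapsNetConfig(**cfg_d), seed=0)
            net.load_state_arrays({k: z[k] for k in net.params})
        return net
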