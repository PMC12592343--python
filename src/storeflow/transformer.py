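"""A compact decoder-only transformer in numpy (forward + analytic backward).

This is a self-contained GPT-style network — token + learned positional
embeddings, pre-norm causal self-attention blocks, GELU MLPs, tied output
head — with hand-derived gradients and an AdamW optimiser. It is sized for
CPU experiments (the desk preset is 2 layers / 128 hidden); the full-scale
configuration (12 layers / 768 hidden / 6144 context) is expressible but not
intended to be trained here.

Everything is float32. All randomness flows through explicit
``numpy.random.Generator`` objects, so runs are bitwise reproducible on a
given platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = ["ModelConfig", "init_params", "forward", "loss_and_grads",
           "masked_cross_entropy", "AdamW", "IncrementalDecoder",
           "DegenerateBatchError"]

_NEG = np.float32(-1e9)  # additive mask for disallowed attention scores


class DegenerateBatchError(ValueError):
    """Raised when a loss is requested over an all-masked-out batch."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``context_length`` bounds the sub-token sequence the model can condition
    on; longer inputs must be head-truncated by the caller (in whole frames,
    so the most recent context is kept).
    """

    n_layers: int
    n_heads: int
    hidden_size: int
    context_length: int
    vocab_size: int
    use_positional: bool = True

    def __post_init__(self) -> None:
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        for name in ("n_layers", "n_heads", "hidden_size", "context_length",
                     "vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def full(cls, vocab_size: int = 200) -> "ModelConfig":
        """Full-scale preset: 12 layers, 12 heads, 768 hidden, 6144 context."""
        return cls(12, 12, 768, 6144, vocab_size)

    @classmethod
    def desk(cls, vocab_size: int = 200, context_length: int = 768) -> "ModelConfig":
        """CPU-scale preset: 2 layers, 4 heads, 128 hidden, 768 context."""
        return cls(2, 4, 128, context_length, vocab_size)

    def to_dict(self) -> dict:
        return {
            "n_layers": self.n_layers,
            "n_heads": self.n_heads,
            "hidden_size": self.hidden_size,
            "context_length": self.context_length,
            "vocab_size": self.vocab_size,
            "use_positional": self.use_positional,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            n_layers=int(d["n_layers"]),
            n_heads=int(d["n_heads"]),
            hidden_size=int(d["hidden_size"]),
            context_length=int(d["context_length"]),
            vocab_size=int(d["vocab_size"]),
            use_positional=bool(d.get("use_positional", True)),
        )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def init_params(cfg: ModelConfig, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    d = cfg.hidden_size
    std = 0.02
    # residual-branch projections scaled down as in standard GPT inits
    res_std = std / math.sqrt(2 * cfg.n_layers)
    p: Dict[str, np.ndarray] = {
        "wte": rng.normal(0, std, (cfg.vocab_size, d)).astype(np.float32),
        "wpe": rng.normal(0, std, (cfg.context_length, d)).astype(np.float32),
        "lnf_g": np.ones(d, np.float32),
        "lnf_b": np.zeros(d, np.float32),
    }
    if not cfg.use_positional:
        p["wpe"][:] = 0
    for l in range(cfg.n_layers):
        p[f"l{l}.ln1_g"] = np.ones(d, np.float32)
        p[f"l{l}.ln1_b"] = np.zeros(d, np.float32)
        p[f"l{l}.w_qkv"] = rng.normal(0, std, (d, 3 * d)).astype(np.float32)
        p[f"l{l}.b_qkv"] = np.zeros(3 * d, np.float32)
        p[f"l{l}.w_o"] = rng.normal(0, res_std, (d, d)).astype(np.float32)
        p[f"l{l}.b_o"] = np.zeros(d, np.float32)
        p[f"l{l}.ln2_g"] = np.ones(d, np.float32)
        p[f"l{l}.ln2_b"] = np.zeros(d, np.float32)
        p[f"l{l}.w_fc"] = rng.normal(0, std, (d, 4 * d)).astype(np.float32)
        p[f"l{l}.b_fc"] = np.zeros(4 * d, np.float32)
        p[f"l{l}.w_pr"] = rng.normal(0, res_std, (4 * d, d)).astype(np.float32)
        p[f"l{l}.b_pr"] = np.zeros(d, np.float32)
    return p


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------

_LN_EPS = np.float32(1e-5)


def _ln_forward(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_backward(dy, cache):
    xhat, inv, g = cache
    dxhat = dy * g
    m1 = dxhat.mean(-1, keepdims=True)
    m2 = (dxhat * xhat).mean(-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    return dx, dg, db


_GC = np.float32(math.sqrt(2.0 / math.pi))
_GA = np.float32(0.044715)


def _gelu_forward(x):
    u = _GC * (x + _GA * x * x * x)
    t = np.tanh(u)
    return np.float32(0.5) * x * (1.0 + t), (x, t)


def _gelu_backward(dy, cache):
    x, t = cache
    du = _GC * (1.0 + 3.0 * _GA * x * x)
    return dy * (np.float32(0.5) * (1.0 + t) + np.float32(0.5) * x * (1.0 - t * t) * du)


def _split_heads(x, n_heads):
    B, T, d = x.shape
    hd = d // n_heads
    return x.reshape(B, T, n_heads, hd).transpose(0, 2, 1, 3)


def _merge_heads(x):
    B, h, T, hd = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, h * hd)


# ---------------------------------------------------------------------------
# full forward / backward
# ---------------------------------------------------------------------------

def forward(params: Dict[str, np.ndarray], cfg: ModelConfig, ids: np.ndarray):
    """Logits ``(B, T, V)`` plus the cache needed for :func:`backward`."""
    ids = np.asarray(ids)
    if ids.ndim == 1:
        ids = ids[None, :]
    B, T = ids.shape
    if T > cfg.context_length:
        raise ValueError(f"sequence length {T} exceeds context {cfg.context_length}")
    x = params["wte"][ids] + params["wpe"][:T]
    causal = np.triu(np.full((T, T), _NEG, np.float32), k=1)
    layer_caches = []
    for l in range(cfg.n_layers):
        x, c = _block_forward(params, l, cfg, x, causal)
        layer_caches.append(c)
    xf, cf = _ln_forward(x, params["lnf_g"], params["lnf_b"])
    logits = xf @ params["wte"].T
    return logits, (ids, layer_caches, cf, xf)


def _block_forward(params, l, cfg, x, causal):
    g1, b1 = params[f"l{l}.ln1_g"], params[f"l{l}.ln1_b"]
    a, c_ln1 = _ln_forward(x, g1, b1)
    qkv = a @ params[f"l{l}.w_qkv"] + params[f"l{l}.b_qkv"]
    d = cfg.hidden_size
    q = _split_heads(qkv[..., :d], cfg.n_heads)
    k = _split_heads(qkv[..., d:2 * d], cfg.n_heads)
    v = _split_heads(qkv[..., 2 * d:], cfg.n_heads)
    scale = np.float32(1.0 / math.sqrt(d // cfg.n_heads))
    scores = q @ k.transpose(0, 1, 3, 2) * scale + causal
    scores -= scores.max(-1, keepdims=True)
    e = np.exp(scores)
    att = e / e.sum(-1, keepdims=True)
    ov = att @ v
    o = _merge_heads(ov)
    proj = o @ params[f"l{l}.w_o"] + params[f"l{l}.b_o"]
    x1 = x + proj
    g2, b2 = params[f"l{l}.ln2_g"], params[f"l{l}.ln2_b"]
    m, c_ln2 = _ln_forward(x1, g2, b2)
    h_pre = m @ params[f"l{l}.w_fc"] + params[f"l{l}.b_fc"]
    h, c_gelu = _gelu_forward(h_pre)
    x2 = x1 + h @ params[f"l{l}.w_pr"] + params[f"l{l}.b_pr"]
    cache = (a, c_ln1, q, k, v, att, o, c_ln2, m, c_gelu, h, scale)
    return x2, cache


def backward(params, cfg, cache, dlogits):
    """Gradients of a scalar loss wrt every parameter, given d(loss)/d(logits)."""
    ids, layer_caches, cf, xf = cache
    B, T, V = dlogits.shape
    grads: Dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in params.items()}
    flat_dl = dlogits.reshape(-1, V)
    flat_xf = xf.reshape(-1, cfg.hidden_size)
    grads["wte"] += flat_dl.T @ flat_xf
    dxf = dlogits @ params["wte"]
    dx, dg, db = _ln_backward(dxf, cf)
    grads["lnf_g"] += dg
    grads["lnf_b"] += db
    for l in reversed(range(cfg.n_layers)):
        dx = _block_backward(params, l, cfg, layer_caches[l], dx, grads)
    # embeddings
    np.add.at(grads["wte"], ids.reshape(-1), dx.reshape(-1, cfg.hidden_size))
    grads["wpe"][:T] += dx.sum(0)
    return grads


def _block_backward(params, l, cfg, cache, dx2, grads):
    a, c_ln1, q, k, v, att, o, c_ln2, m, c_gelu, h, scale = cache
    d = cfg.hidden_size
    # MLP branch
    flat_h = h.reshape(-1, 4 * d)
    grads[f"l{l}.w_pr"] += flat_h.T @ dx2.reshape(-1, d)
    grads[f"l{l}.b_pr"] += dx2.sum((0, 1))
    dh = dx2 @ params[f"l{l}.w_pr"].T
    dh_pre = _gelu_backward(dh, c_gelu)
    grads[f"l{l}.w_fc"] += m.reshape(-1, d).T @ dh_pre.reshape(-1, 4 * d)
    grads[f"l{l}.b_fc"] += dh_pre.sum((0, 1))
    dm = dh_pre @ params[f"l{l}.w_fc"].T
    dx1_ln, dg2, db2 = _ln_backward(dm, c_ln2)
    grads[f"l{l}.ln2_g"] += dg2
    grads[f"l{l}.ln2_b"] += db2
    dx1 = dx2 + dx1_ln
    # attention branch
    grads[f"l{l}.w_o"] += o.reshape(-1, d).T @ dx1.reshape(-1, d)
    grads[f"l{l}.b_o"] += dx1.sum((0, 1))
    do = dx1 @ params[f"l{l}.w_o"].T
    dov = _split_heads(do, cfg.n_heads)
    datt = dov @ v.transpose(0, 1, 3, 2)
    dv = att.transpose(0, 1, 3, 2) @ dov
    ds = att * (datt - (datt * att).sum(-1, keepdims=True))
    dq = ds @ k * scale
    dk = ds.transpose(0, 1, 3, 2) @ q * scale
    dqkv = np.concatenate(
        [_merge_heads(dq), _merge_heads(dk), _merge_heads(dv)], axis=-1
    )
    grads[f"l{l}.w_qkv"] += a.reshape(-1, d).T @ dqkv.reshape(-1, 3 * d)
    grads[f"l{l}.b_qkv"] += dqkv.sum((0, 1))
    da = dqkv @ params[f"l{l}.w_qkv"].T
    dx_ln, dg1, db1 = _ln_backward(da, c_ln1)
    grads[f"l{l}.ln1_g"] += dg1
    grads[f"l{l}.ln1_b"] += db1
    return dx1 + dx_ln


# ---------------------------------------------------------------------------
# masked loss
# ---------------------------------------------------------------------------

def masked_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    return_grad: bool = False,
):
    """Mean cross-entropy over masked-in positions only.

    ``logits`` is ``(B, T, V)`` (or ``(T, V)``), ``labels`` and ``mask`` are
    ``(B, T)``; position ``(b, t)`` contributes iff ``mask[b, t]``. Positions
    with ``mask`` False contribute exactly zero to the value and — when
    ``return_grad`` is set — exactly zero gradient (the returned
    ``d(loss)/d(logits)`` is identically 0.0 there, not merely small).
    """
    logits = np.asarray(logits)
    squeeze = logits.ndim == 2
    if squeeze:
        logits = logits[None]
        labels = np.asarray(labels)[None]
        mask = np.asarray(mask)[None]
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    n_in = int(mask.sum())
    if n_in == 0:
        raise DegenerateBatchError("all positions are masked out of the loss")
    sel = logits[mask].astype(np.float64)  # (n_in, V)
    lab = labels[mask]
    mx = sel.max(-1, keepdims=True)
    lse = mx[:, 0] + np.log(np.exp(sel - mx).sum(-1))
    loss = float(np.mean(lse - sel[np.arange(n_in), lab]))
    if not return_grad:
        return loss
    probs = np.exp(sel - lse[:, None])
    probs[np.arange(n_in), lab] -= 1.0
    dlogits = np.zeros(logits.shape, np.float32)
    dlogits[mask] = (probs / n_in).astype(np.float32)
    if squeeze:
        dlogits = dlogits[0]
    return loss, dlogits


def loss_and_grads(params, cfg, ids, labels, mask):
    """Masked-loss value and parameter gradients for one padded batch."""
    logits, cache = forward(params, cfg, ids)
    loss, dlogits = masked_cross_entropy(logits, labels, mask, return_grad=True)
    grads = backward(params, cfg, cache, dlogits)
    return loss, grads


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class AdamW:
    """Adam with decoupled weight decay (decay applied to matrices only)."""

    def __init__(self, params, lr=3e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.01):
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, lr: Optional[float] = None):
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        c1 = 1 - b1**self.t
        c2 = 1 - b2**self.t
        for k, p in params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            upd = (m / c1) / (np.sqrt(v / c2) + self.eps)
            if self.weight_decay and p.ndim >= 2:
                upd = upd + self.weight_decay * p
            p -= np.float32(lr) * upd.astype(np.float32)


# ---------------------------------------------------------------------------
# incremental decoding with a key/value cache
# ---------------------------------------------------------------------------

class IncrementalDecoder:
    """Single-sequence autoregressive decoder that reuses past keys/values.

    Appending ``n`` new tokens costs O(n · (n + past)) attention instead of
    re-running the whole prefix, which is what makes multi-agent simulation
    affordable on a CPU. The context is append-only; when it would exceed
    ``cfg.context_length`` the caller truncates and calls :meth:`reset`.
    """

    def __init__(self, params: Dict[str, np.ndarray], cfg: ModelConfig):
        self.params = params
        self.cfg = cfg
        self.length = 0
        self._k: List[np.ndarray] = [
            np.empty((cfg.n_heads, 0, cfg.hidden_size // cfg.n_heads), np.float32)
            for _ in range(cfg.n_layers)
        ]
        self._v = [k.copy() for k in self._k]
        self._last_logits: Optional[np.ndarray] = None

    def reset(self, ids: Optional[np.ndarray] = None) -> None:
        cfg = self.cfg
        self.length = 0
        hd = cfg.hidden_size // cfg.n_heads
        self._k = [np.empty((cfg.n_heads, 0, hd), np.float32) for _ in range(cfg.n_layers)]
        self._v = [k.copy() for k in self._k]
        self._last_logits = None
        if ids is not None and len(ids) > 0:
            self.append(ids)

    def append(self, new_ids) -> np.ndarray:
        """Extend the context; returns the logits at the final new position."""
        p, cfg = self.params, self.cfg
        new_ids = np.asarray(new_ids, dtype=np.int64).reshape(-1)
        n = len(new_ids)
        if n == 0:
            if self._last_logits is None:
                raise ValueError("empty append on an empty decoder")
            return self._last_logits
        past = self.length
        if past + n > cfg.context_length:
            raise ValueError("context overflow; truncate and reset the decoder")
        x = p["wte"][new_ids] + p["wpe"][past:past + n]  # (n, d)
        d = cfg.hidden_size
        hd = d // cfg.n_heads
        scale = np.float32(1.0 / math.sqrt(hd))
        block_mask = np.triu(np.full((n, n), _NEG, np.float32), k=1)
        for l in range(cfg.n_layers):
            a, _ = _ln_forward(x, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
            qkv = a @ p[f"l{l}.w_qkv"] + p[f"l{l}.b_qkv"]
            q = qkv[:, :d].reshape(n, cfg.n_heads, hd).transpose(1, 0, 2)
            k = qkv[:, d:2 * d].reshape(n, cfg.n_heads, hd).transpose(1, 0, 2)
            v = qkv[:, 2 * d:].reshape(n, cfg.n_heads, hd).transpose(1, 0, 2)
            k_full = np.concatenate([self._k[l], k], axis=1)
            v_full = np.concatenate([self._v[l], v], axis=1)
            self._k[l] = k_full
            self._v[l] = v_full
            scores = q @ k_full.transpose(0, 2, 1) * scale  # (h, n, past+n)
            scores[:, :, past:] += block_mask
            scores -= scores.max(-1, keepdims=True)
            e = np.exp(scores)
            att = e / e.sum(-1, keepdims=True)
            o = (att @ v_full).transpose(1, 0, 2).reshape(n, d)
            x = x + o @ p[f"l{l}.w_o"] + p[f"l{l}.b_o"]
            m, _ = _ln_forward(x, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
            h, _ = _gelu_forward(m @ p[f"l{l}.w_fc"] + p[f"l{l}.b_fc"])
            x = x + h @ p[f"l{l}.w_pr"] + p[f"l{l}.b_pr"]
        self.length = past + n
        xf, _ = _ln_forward(x[-1:], p["lnf_g"], p["lnf_b"])
        self._last_logits = (xf @ p["wte"].T)[0]
        return self._last_logits
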