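"""Encoder-decoder transformer for next-wave MCI risk.

One token per wave.  Input feature vectors are linearly projected to
``d_model`` and a learnable positional embedding is added elementwise.
Encoder blocks use multi-head self-attention with a learnable relative
positional bias (one table per head over clipped signed distances, shared
across layers), then a GELU feedforward network whose output is filtered by
a sigmoid gated linear unit and a depthwise-separable convolution along the
wave axis.  Every sublayer is wired as AdaLN(x + Sublayer(x)) where AdaLN is
layer normalization followed by learnable scale gamma and shift beta
(epsilon 1e-12).  The decoder is a single learned query token cross-attending
to the encoder output; a linear + sigmoid head maps it to the risk
probability.

All arrays are batched: feature input is (batch, seq_len, n_features).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, sigmoid, gelu, softmax

__all__ = [
    "ModelConfig",
    "init_params",
    "count_parameters",
    "embed_sequence",
    "relative_attention",
    "multi_head",
    "glu_gate",
    "ds_conv",
    "ada_layer_norm",
    "forward_predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    n_features: int
    d_model: int = 512
    n_heads: int = 8
    n_encoder_layers: int = 2
    n_decoder_layers: int = 1
    d_ffn: int | None = None  # defaults to 4 * d_model
    dropout: float = 0.1
    conv_kernel: int = 3
    max_relative_distance: int = 8
    layernorm_eps: float = 1e-12
    max_seq_len: int = 8

    def __post_init__(self):
        if self.d_ffn is None:
            self.d_ffn = 4 * self.d_model
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    def to_dict(self) -> dict:
        return asdict(self)


def _xavier(rng, n_in, n_out):
    return rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), size=(n_in, n_out))


def _attn_params(rng, d, prefix, params):
    for w in ("Wq", "Wk", "Wv", "Wo"):
        params[f"{prefix}.{w}"] = Tensor(_xavier(rng, d, d), requires_grad=True)


def _block_params(rng, cfg: ModelConfig, prefix: str, params: dict):
    d, f = cfg.d_model, cfg.d_ffn
    params[f"{prefix}.norm1.gamma"] = Tensor(np.ones(d), requires_grad=True)
    params[f"{prefix}.norm1.beta"] = Tensor(np.zeros(d), requires_grad=True)
    params[f"{prefix}.ffn.W1"] = Tensor(_xavier(rng, d, f), requires_grad=True)
    params[f"{prefix}.ffn.b1"] = Tensor(np.zeros(f), requires_grad=True)
    params[f"{prefix}.ffn.W2"] = Tensor(_xavier(rng, f, d), requires_grad=True)
    params[f"{prefix}.ffn.b2"] = Tensor(np.zeros(d), requires_grad=True)
    params[f"{prefix}.glu.W"] = Tensor(_xavier(rng, d, d), requires_grad=True)
    params[f"{prefix}.glu.b"] = Tensor(np.zeros(d), requires_grad=True)
    # depthwise kernel initialized to the identity tap; pointwise to identity
    dw = np.zeros((cfg.conv_kernel, d))
    dw[cfg.conv_kernel // 2, :] = 1.0
    params[f"{prefix}.conv.depthwise"] = Tensor(dw, requires_grad=True)
    params[f"{prefix}.conv.pointwise"] = Tensor(np.eye(d), requires_grad=True)
    params[f"{prefix}.conv.bias"] = Tensor(np.zeros(d), requires_grad=True)
    params[f"{prefix}.norm2.gamma"] = Tensor(np.ones(d), requires_grad=True)
    params[f"{prefix}.norm2.beta"] = Tensor(np.zeros(d), requires_grad=True)


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    """Initialize all learnable weights (Xavier for projections)."""
    rng = np.random.default_rng(seed)
    d = config.d_model
    params: dict[str, Tensor] = {}
    params["input_proj.W"] = Tensor(_xavier(rng, config.n_features, d), requires_grad=True)
    params["input_proj.b"] = Tensor(np.zeros(d), requires_grad=True)
    params["pos_embedding"] = Tensor(
        rng.normal(0.0, 0.02, size=(config.max_seq_len, d)), requires_grad=True
    )
    params["rel_bias"] = Tensor(
        np.zeros((config.n_heads, 2 * config.max_relative_distance + 1)),
        requires_grad=True,
    )
    for i in range(config.n_encoder_layers):
        _attn_params(rng, d, f"enc{i}.attn", params)
        _block_params(rng, config, f"enc{i}", params)
    params["dec_query"] = Tensor(rng.normal(0.0, 0.02, size=(1, d)), requires_grad=True)
    for i in range(config.n_decoder_layers):
        _attn_params(rng, d, f"dec{i}.attn", params)
        _block_params(rng, config, f"dec{i}", params)
    # a small random head lets gradients reach the body from the first step
    # (a zero head would give sigmoid(0)=0.5 but also zero body gradients)
    params["head.W"] = Tensor(_xavier(rng, d, 1), requires_grad=True)
    params["head.b"] = Tensor(np.zeros(1), requires_grad=True)
    return params


def count_parameters(params: dict[str, Tensor]) -> int:
    return int(sum(p.data.size for p in params.values()))


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def embed_sequence(x, W, b, pos_embedding) -> Tensor:
    """hidden[pos] = x[pos] @ W + b + PE[pos] for a (B, L, F) batch."""
    x = Tensor.as_tensor(x)
    L = x.shape[-2]
    if L > pos_embedding.shape[0]:
        raise ValueError(
            f"sequence length {L} exceeds positional table size {pos_embedding.shape[0]}"
        )
    return x @ W + b + pos_embedding[:L]


def relative_bias_matrix(table: Tensor, L: int, max_distance: int) -> Tensor:
    """(H, L, L) additive bias: table indexed by clipped distance j - i."""
    i = np.arange(L)
    rel = np.clip(i[None, :] - i[:, None], -max_distance, max_distance) + max_distance
    return table[:, rel]


def relative_attention(Q, K, V, B=None, d_k: int | None = None,
                       return_weights: bool = False, dropout_mask=None):
    """softmax((Q K^T + B) / sqrt(d_k)) V with additive relative bias B.

    Shapes: Q (..., Lq, d_k), K/V (..., Lk, d_k); B broadcastable to
    (..., Lq, Lk) or None.  Rows of the weight matrix are non-negative and
    sum to one.
    """
    Q, K, V = map(Tensor.as_tensor, (Q, K, V))
    if d_k is None:
        d_k = Q.shape[-1]
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    logits = Q @ K.swapaxes(-1, -2)
    if B is not None:
        logits = logits + Tensor.as_tensor(B)
    logits = logits * (1.0 / np.sqrt(d_k))
    weights = softmax(logits, axis=-1)
    if dropout_mask is not None:
        weights = weights * dropout_mask
    context = weights @ V
    if return_weights:
        return context, weights
    return context


def multi_head(Q, K, V, params: dict, prefix: str, config: ModelConfig,
               bias_table: Tensor | None = None, dropout_mask=None,
               return_weights: bool = False):
    """Concat(head_1..head_h) W_O with per-head projections and relative bias.

    Q is (B, Lq, d_model); K, V are (B, Lk, d_model).
    """
    Q, K, V = map(Tensor.as_tensor, (Q, K, V))
    H, dk = config.n_heads, config.d_k
    B_, Lq = Q.shape[0], Q.shape[1]
    Lk = K.shape[1]

    def split(x, W, L):
        # (B, L, d) @ (d, d) -> (B, L, H, dk) -> (B, H, L, dk)
        return (x @ W).reshape(B_, L, H, dk).transpose(0, 2, 1, 3)

    q = split(Q, params[f"{prefix}.Wq"], Lq)
    k = split(K, params[f"{prefix}.Wk"], Lk)
    v = split(V, params[f"{prefix}.Wv"], Lk)
    bias = None
    if bias_table is not None:
        bias = relative_bias_matrix(bias_table, Lk, config.max_relative_distance)
        if Lq != Lk:  # cross-attention from a short query: take matching rows
            bias = bias[:, :Lq, :]
    out = relative_attention(q, k, v, B=bias, d_k=dk,
                             return_weights=return_weights,
                             dropout_mask=dropout_mask)
    if return_weights:
        out, weights = out
    merged = out.transpose(0, 2, 1, 3).reshape(B_, Lq, config.d_model)
    result = merged @ params[f"{prefix}.Wo"]
    if return_weights:
        return result, weights
    return result


def glu_gate(x, W, b) -> Tensor:
    """x * sigmoid(x @ W + b), elementwise."""
    x = Tensor.as_tensor(x)
    return x * sigmoid(x @ W + b)


def ds_conv(x, depthwise, pointwise, bias=None) -> Tensor:
    """Depthwise then pointwise (1x1) convolution along the sequence axis.

    x: (B, L, C); depthwise: (K, C) one kernel per channel; pointwise (C, C).
    Zero padding keeps the output length equal to the input length.
    """
    x = Tensor.as_tensor(x)
    depthwise = Tensor.as_tensor(depthwise)
    pointwise = Tensor.as_tensor(pointwise)
    K = depthwise.shape[0]
    if K % 2 == 0:
        raise ValueError("depthwise kernel length must be odd")
    L = x.shape[1]
    P = K // 2
    xp = x.pad(axis=1, before=P, after=P)
    acc = None
    for k in range(K):
        term = xp[:, k:k + L, :] * depthwise[k]
        acc = term if acc is None else acc + term
    out = acc @ pointwise
    if bias is not None:
        out = out + Tensor.as_tensor(bias)
    return out


def ada_layer_norm(x, gamma, beta, eps: float = 1e-12) -> Tensor:
    """gamma * LayerNorm(x) + beta over the last axis (population variance)."""
    x = Tensor.as_tensor(x)
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    normed = xc * ((var + eps) ** -0.5)
    return Tensor.as_tensor(gamma) * normed + beta


# ---------------------------------------------------------------------------
# full forward pass
# ---------------------------------------------------------------------------

def _dropout_mask(rng, shape, rate):
    if rng is None or rate <= 0:
        return None
    keep = (rng.random(shape) >= rate).astype(np.float64) / (1.0 - rate)
    return Tensor(keep)


def _block(x, params, prefix, config, bias_table, rng, attn_kv=None,
           collect=None):
    """One encoder/decoder block: attention sublayer + gated conv FFN sublayer."""
    kv = x if attn_kv is None else attn_kv
    B_, Lq, Lk = x.shape[0], x.shape[1], kv.shape[1]
    mask = _dropout_mask(rng, (B_, config.n_heads, Lq, Lk), config.dropout)
    attn_out = multi_head(x, kv, kv, params, f"{prefix}.attn", config,
                          bias_table=bias_table, dropout_mask=mask,
                          return_weights=collect is not None)
    if collect is not None:
        attn_out, weights = attn_out
        collect.append(weights.data)
    x = ada_layer_norm(x + attn_out, params[f"{prefix}.norm1.gamma"],
                       params[f"{prefix}.norm1.beta"], config.layernorm_eps)
    h = gelu(x @ params[f"{prefix}.ffn.W1"] + params[f"{prefix}.ffn.b1"])
    hmask = _dropout_mask(rng, h.shape, config.dropout)
    if hmask is not None:
        h = h * hmask
    f = h @ params[f"{prefix}.ffn.W2"] + params[f"{prefix}.ffn.b2"]
    f = glu_gate(f, params[f"{prefix}.glu.W"], params[f"{prefix}.glu.b"])
    f = ds_conv(f, params[f"{prefix}.conv.depthwise"],
                params[f"{prefix}.conv.pointwise"], params[f"{prefix}.conv.bias"])
    return ada_layer_norm(x + f, params[f"{prefix}.norm2.gamma"],
                          params[f"{prefix}.norm2.beta"], config.layernorm_eps)


def forward_predict(params: dict, config: ModelConfig, x,
                    rng: np.random.Generator | None = None,
                    collect_attention: list | None = None) -> Tensor:
    """Risk probability in (0, 1) for each sample of a (B, L, F) batch.

    ``rng`` enables (seeded) dropout for training; with ``rng=None`` the pass
    is deterministic.  ``collect_attention`` (a list, if given) receives the
    raw attention-weight arrays of every block for interpretability exports.
    """
    x = Tensor.as_tensor(x)
    if x.ndim == 2:
        x = x.reshape(1, *x.shape)
    h = embed_sequence(x, params["input_proj.W"], params["input_proj.b"],
                       params["pos_embedding"])
    bias_table = params["rel_bias"]
    for i in range(config.n_encoder_layers):
        h = _block(h, params, f"enc{i}", config, bias_table, rng,
                   collect=collect_attention)
    B_ = h.shape[0]
    q = params["dec_query"].reshape(1, 1, config.d_model) * Tensor(np.ones((B_, 1, 1)))
    for i in range(config.n_decoder_layers):
        q = _block(q, params, f"dec{i}", config, bias_table, rng, attn_kv=h,
                   collect=collect_attention)
    logit = q.reshape(B_, config.d_model) @ params["head.W"] + params["head.b"]
    return sigmoid(logit.reshape(B_))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, config: ModelConfig, params: dict[str, Tensor]) -> None:
    """Portable .npz: named parameter arrays plus the JSON-encoded config."""
    arrays = {name: p.data for name, p in params.items()}
    np.savez(path, __config__=np.frombuffer(
        json.dumps(config.to_dict()).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    with np.load(path) as z:
        cfg = ModelConfig(**json.loads(bytes(z["__config__"]).decode()))
        params = {k: Tensor(z[k], requires_grad=True)
                  for k in z.files if k != "__config__"}
    return cfg, params
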