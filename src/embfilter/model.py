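"""Residue-embedding network: a 1-D residual convolutional stack.

The model maps an amino-acid sequence ``S = S1..Sn`` to a sequence of
d-dimensional vectors, one per residue.  Each residue's vector reflects its
local sequence context only: the stack is a learnable per-symbol lookup table
followed by ``n_blocks`` residual blocks, each computing

    x  ->  x + Conv2(sigma(Conv1(sigma(x))))

where Conv1 and Conv2 are independent 1-D convolutions with identical
hyper-parameters (no weight sharing anywhere) and sigma is ELU.  Convolutions
use symmetric zero padding, so the output always has exactly one row per
residue.  The receptive field of one output row is therefore
``1 + 2 * n_blocks * (kernel_size - 1)`` input residues.

Everything here is plain numpy; the backward pass lives alongside the forward
pass because the training objective (see :mod:`embfilter.training`)
differentiates through the whole stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_SYMBOL = "X"
#: 20 canonical amino acids plus one catch-all symbol.
DEFAULT_VOCAB = AMINO_ACIDS + UNKNOWN_SYMBOL


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    Defaults are the production architecture: 256-dimensional embeddings,
    8 residual blocks, kernel size 7, ELU activation.
    """

    embed_dim: int = 256
    n_blocks: int = 8
    kernel_size: int = 7
    activation: str = "ELU"
    vocab: str = DEFAULT_VOCAB

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError(f"embed_dim must be >= 1, got {self.embed_dim}")
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(
                f"kernel_size must be an odd positive integer, got {self.kernel_size}"
            )
        if self.activation != "ELU":
            raise ValueError(f"unsupported activation: {self.activation!r}")
        if len(set(self.vocab)) != len(self.vocab):
            raise ValueError("vocab symbols must be unique")
        if UNKNOWN_SYMBOL not in self.vocab:
            raise ValueError(f"vocab must contain the unknown symbol {UNKNOWN_SYMBOL!r}")


@dataclass
class Sequence:
    """A named amino-acid string."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def elu(x: np.ndarray) -> np.ndarray:
    """ELU activation with alpha = 1."""
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def elu_grad(x: np.ndarray) -> np.ndarray:
    """d ELU(x) / dx evaluated at pre-activation x."""
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def receptive_field(cfg: ModelConfig) -> int:
    """Width of the input window that can influence one output row.

    Each of the 2 * n_blocks convolutions widens the window by
    kernel_size - 1; the lookup encoder contributes the residue itself.
    """
    return 1 + 2 * cfg.n_blocks * (cfg.kernel_size - 1)


def count_parameters(cfg: ModelConfig) -> int:
    """Exact number of learnable scalars in a model built from cfg."""
    v, d, k = len(cfg.vocab), cfg.embed_dim, cfg.kernel_size
    per_conv = k * d * d + d
    return v * d + cfg.n_blocks * 2 * per_conv


def init_params(cfg: ModelConfig, rng: np.random.Generator | int | None = None) -> dict:
    """Fan-in-scaled random initialization.

    The lookup table uses std 1/sqrt(d) so initial residue vectors have
    roughly unit norm; conv weights use std 1/sqrt(fan_in) with zero biases.
    """
    rng = np.random.default_rng(rng)
    d, k = cfg.embed_dim, cfg.kernel_size
    params: dict[str, np.ndarray] = {
        "embed": rng.normal(0.0, 1.0 / np.sqrt(d), size=(len(cfg.vocab), d))
    }
    w_std = 1.0 / np.sqrt(k * d)
    for i in range(cfg.n_blocks):
        for conv in ("conv1", "conv2"):
            params[f"block{i}.{conv}.w"] = rng.normal(0.0, w_std, size=(k, d, d))
            params[f"block{i}.{conv}.b"] = np.zeros(d)
    return params


def zero_like_params(params: dict) -> dict:
    return {k: np.zeros_like(v) for k, v in params.items()}


def validate_params(cfg: ModelConfig, params: dict) -> None:
    """Check that a parameter dict matches cfg's shape invariants."""
    d, k = cfg.embed_dim, cfg.kernel_size
    expected = {"embed": (len(cfg.vocab), d)}
    for i in range(cfg.n_blocks):
        for conv in ("conv1", "conv2"):
            expected[f"block{i}.{conv}.w"] = (k, d, d)
            expected[f"block{i}.{conv}.b"] = (d,)
    if set(params) != set(expected):
        raise ValueError("parameter names do not match the configuration")
    for name, shape in expected.items():
        if params[name].shape != shape:
            raise ValueError(
                f"parameter {name} has shape {params[name].shape}, expected {shape}"
            )


def conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Length-preserving 1-D convolution.

    x: (n, d_in); w: (k, d_in, d_out); b: (d_out,).  Symmetric zero padding of
    (k-1)/2 on each side.
    """
    k = w.shape[0]
    if x.shape[1] != w.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]}, convolution expects {w.shape[1]}"
        )
    n = x.shape[0]
    pad = (k - 1) // 2
    xp = np.zeros((n + k - 1, x.shape[1]))
    xp[pad : pad + n] = x
    y = np.tile(b, (n, 1))
    for tau in range(k):
        y += xp[tau : tau + n] @ w[tau]
    return y


def _conv1d_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of conv1d w.r.t. input, weights and bias."""
    k = w.shape[0]
    n = x.shape[0]
    pad = (k - 1) // 2
    xp = np.zeros((n + k - 1, x.shape[1]))
    xp[pad : pad + n] = x
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for tau in range(k):
        dw[tau] = xp[tau : tau + n].T @ dy
        dxp[tau : tau + n] += dy @ w[tau].T
    db = dy.sum(axis=0)
    return dxp[pad : pad + n], dw, db


def residual_block(
    x: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: np.ndarray,
) -> np.ndarray:
    """x + Conv2(ELU(Conv1(ELU(x)))) — forward only."""
    a = elu(x)
    c1 = conv1d(a, w1, b1)
    h = elu(c1)
    c2 = conv1d(h, w2, b2)
    return x + c2


def tokenize(seq: str, cfg: ModelConfig) -> np.ndarray:
    """Map residues to vocab indices; non-vocab letters map to the unknown symbol."""
    if len(seq) == 0:
        raise ValueError("cannot encode an empty sequence")
    if not seq.isalpha():
        bad = sorted({c for c in seq if not c.isalpha()})
        raise ValueError(f"sequence contains non-alphabetic characters: {bad}")
    index = {sym: i for i, sym in enumerate(cfg.vocab)}
    unk = index[UNKNOWN_SYMBOL]
    return np.array([index.get(c.upper(), unk) for c in seq], dtype=np.intp)


def forward(
    tokens: np.ndarray, params: dict, cfg: ModelConfig, want_cache: bool = False
):
    """Run the stack over a token vector.

    Returns the (n, d) embedding matrix, plus per-block caches of the
    intermediate pre-activations when ``want_cache`` is set (used by the
    backward pass during training).
    """
    x = params["embed"][tokens]
    cache: list[tuple] = []
    for i in range(cfg.n_blocks):
        w1 = params[f"block{i}.conv1.w"]
        b1 = params[f"block{i}.conv1.b"]
        w2 = params[f"block{i}.conv2.w"]
        b2 = params[f"block{i}.conv2.b"]
        a = elu(x)
        c1 = conv1d(a, w1, b1)
        h = elu(c1)
        c2 = conv1d(h, w2, b2)
        if want_cache:
            cache.append((x, a, c1, h))
        x = x + c2
    if want_cache:
        return x, cache
    return x


def backward(
    d_out: np.ndarray,
    tokens: np.ndarray,
    cache: list[tuple],
    params: dict,
    cfg: ModelConfig,
    grads: dict,
) -> None:
    """Accumulate parameter gradients for one sequence into ``grads``.

    ``d_out`` is the gradient of the loss w.r.t. the final embedding matrix.
    """
    dx = d_out.copy()
    for i in reversed(range(cfg.n_blocks)):
        x_in, a, c1, h = cache[i]
        w1 = params[f"block{i}.conv1.w"]
        w2 = params[f"block{i}.conv2.w"]
        # out = x_in + conv2(h); dx covers both the skip and the branch
        dh, dw2, db2 = _conv1d_backward(h, w2, dx)
        grads[f"block{i}.conv2.w"] += dw2
        grads[f"block{i}.conv2.b"] += db2
        dc1 = dh * elu_grad(c1)
        da, dw1, db1 = _conv1d_backward(a, w1, dc1)
        grads[f"block{i}.conv1.w"] += dw1
        grads[f"block{i}.conv1.b"] += db1
        dx = dx + da * elu_grad(x_in)
    np.add.at(grads["embed"], tokens, dx)


def encode_sequence(seq: Sequence | str, params: dict, cfg: ModelConfig) -> np.ndarray:
    """Embed one sequence independently of any other; one row per residue."""
    residues = seq.seq if isinstance(seq, Sequence) else seq
    tokens = tokenize(residues, cfg)
    return forward(tokens, params, cfg)


def save_model(path, cfg: ModelConfig, params: dict) -> None:
    """Serialize cfg + weights into one self-describing .npz file."""
    import json

    meta = json.dumps(
        {
            "embed_dim": cfg.embed_dim,
            "n_blocks": cfg.n_blocks,
            "kernel_size": cfg.kernel_size,
            "activation": cfg.activation,
            "vocab": cfg.vocab,
        }
    )
    np.savez(path, __config__=np.array(meta), **params)


def load_model(path) -> tuple[ModelConfig, dict]:
    import json

    with np.load(path) as data:
        meta = json.loads(str(data["__config__"]))
        cfg = ModelConfig(**meta)
        params = {k: data[k] for k in data.files if k != "__config__"}
    validate_params(cfg, params)
    return cfg, params
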