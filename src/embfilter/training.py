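"""Contrastive training of the residue embedder from trusted pairwise alignments.

Supervision comes from pairwise alignments of homologous sequences (A, B): a
binary target matrix T marks residue pairs that share an alignment column.
Both sequences are embedded independently; the raw dot-product matrix
``D[i, j] = a_i . b_j`` feeds a masked N-pair loss

    L = sum_{i,j} -Ra_i * Rb_j * T_ij * log( exp(D_ij) / sum_w exp(D_iw) )
        + (gamma / n) * ( sum_i Ra_i |a_i|^2  +  sum_j Rb_j |b_j|^2 )

where Ra, Rb are per-residue repeat masks (0 silences repetitive regions) and
the softmax denominator runs over *all* residues w of B.  Minimizing the
N-pair term pulls aligned embeddings into similar directions and, through the
shared denominator, pushes unaligned embeddings toward orthogonality.  The L2
term (scale gamma, normalizer n = number of unmasked residues in the pair)
keeps embedding norms bounded.  Optimization uses AdamW.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence as TypingSequence

import numpy as np
from scipy.special import logsumexp
from scipy.sparse import coo_matrix

from . import model as _model
from .model import ModelConfig, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Gap-free column pairing of two homologous sequences.

    ``cols`` lists 1-based (i, j) residue index pairs of A and B that occupy
    the same alignment column; both coordinates are strictly increasing.
    """

    id_a: str
    id_b: str
    cols: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        cols = tuple((int(i), int(j)) for i, j in self.cols)
        object.__setattr__(self, "cols", cols)
        for (i0, j0), (i1, j1) in zip(cols, cols[1:]):
            if not (i0 < i1 and j0 < j1):
                raise ValueError("alignment columns must be strictly increasing in both indices")
        if cols and (cols[0][0] < 1 or cols[0][1] < 1):
            raise ValueError("alignment columns are 1-based; got index < 1")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyper-parameters (defaults: the production recipe)."""

    steps: int = 24000
    batch_size: int = 512
    crop_len: int = 256
    learning_rate: float = 1e-5
    weight_decay: float = 1e-2
    gamma: float = 5e-3
    symmetrized: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        for name in ("batch_size", "crop_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("learning_rate", "weight_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class TrainingRecord:
    step: int
    loss: float
    npair_term: float
    l2_term: float


def targets_from_alignment(aln: PairwiseAlignment, len_a: int, len_b: int) -> coo_matrix:
    """Binary len_a x len_b matrix with T[i-1, j-1] = 1 for each aligned column (i, j)."""
    for i, j in aln.cols:
        if not (1 <= i <= len_a and 1 <= j <= len_b):
            raise ValueError(f"alignment column ({i}, {j}) outside sequence bounds "
                             f"({len_a}, {len_b})")
    rows = [i - 1 for i, _ in aln.cols]
    cols = [j - 1 for _, j in aln.cols]
    data = np.ones(len(aln.cols), dtype=np.int8)
    return coo_matrix((data, (rows, cols)), shape=(len_a, len_b))


def _npair_terms(
    emb_a: np.ndarray,
    emb_b: np.ndarray,
    T: coo_matrix,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """One direction (A -> B) of the N-pair loss and its embedding gradients."""
    D = emb_a @ emb_b.T
    rows = np.asarray(T.row)
    cols = np.asarray(T.col)
    weights = mask_a[rows] * mask_b[cols]
    active = weights > 0
    rows, cols, weights = rows[active], cols[active], weights[active]
    if rows.size == 0:
        return 0.0, np.zeros_like(emb_a), np.zeros_like(emb_b)
    lse = logsumexp(D, axis=1)
    log_softmax = D[rows, cols] - lse[rows]
    npair = float(-np.sum(weights * log_softmax))

    # dL/dD: for each aligned (i, j) with weight w, w * (softmax(D_i) - e_j)
    dD = np.zeros_like(D)
    uniq_rows, inverse = np.unique(rows, return_inverse=True)
    row_weight = np.zeros(len(uniq_rows))
    np.add.at(row_weight, inverse, weights)
    p = np.exp(D[uniq_rows] - lse[uniq_rows, None])
    dD[uniq_rows] = row_weight[:, None] * p
    np.subtract.at(dD, (rows, cols), weights)
    return npair, dD @ emb_b, dD.T @ emb_a


def masked_npair_loss(
    emb_a: np.ndarray,
    emb_b: np.ndarray,
    T: coo_matrix,
    mask_a: np.ndarray | None = None,
    mask_b: np.ndarray | None = None,
    gamma: float = 5e-3,
    symmetrized: bool = False,
    return_grads: bool = False,
):
    """Masked N-pair loss plus L2 regularization for one sequence pair.

    Returns ``(loss, npair_term, l2_term)``; with ``return_grads`` also the
    gradients w.r.t. the two embedding matrices.  The softmax normalizes over
    all residues of B (the partner sequence), masked or not; masks only
    multiply the outer per-pair terms and the L2 contributions.  With
    ``symmetrized`` the N-pair term is the average of the A->B and B->A
    directions.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    mask_a = np.ones(emb_a.shape[0]) if mask_a is None else np.asarray(mask_a, dtype=float)
    mask_b = np.ones(emb_b.shape[0]) if mask_b is None else np.asarray(mask_b, dtype=float)
    if emb_a.shape[1] != emb_b.shape[1]:
        raise ValueError("embedding dimensionalities differ")
    if mask_a.shape[0] != emb_a.shape[0] or mask_b.shape[0] != emb_b.shape[0]:
        raise ValueError("mask length does not match embedding rows")
    T = coo_matrix(T)
    if T.shape != (emb_a.shape[0], emb_b.shape[0]):
        raise ValueError(f"target matrix shape {T.shape} does not match embeddings "
                         f"({emb_a.shape[0]}, {emb_b.shape[0]})")

    npair, dA, dB = _npair_terms(emb_a, emb_b, T, mask_a, mask_b)
    if symmetrized:
        npair_rev, dB_rev, dA_rev = _npair_terms(emb_b, emb_a, T.T, mask_b, mask_a)
        npair = 0.5 * (npair + npair_rev)
        dA = 0.5 * (dA + dA_rev)
        dB = 0.5 * (dB + dB_rev)

    n_unmasked = float(mask_a.sum() + mask_b.sum())
    if gamma > 0 and n_unmasked > 0:
        scale = gamma / n_unmasked
        l2 = scale * float(
            np.sum(mask_a * np.einsum("ij,ij->i", emb_a, emb_a))
            + np.sum(mask_b * np.einsum("ij,ij->i", emb_b, emb_b))
        )
        dA = dA + 2.0 * scale * mask_a[:, None] * emb_a
        dB = dB + 2.0 * scale * mask_b[:, None] * emb_b
    else:
        l2 = 0.0
    loss = npair + l2
    if return_grads:
        return loss, npair, l2, dA, dB
    return loss, npair, l2


@dataclass
class TrainingPair:
    """One supervised example: two sequences, their alignment, optional masks."""

    seq_a: Sequence
    seq_b: Sequence
    alignment: PairwiseAlignment
    mask_a: np.ndarray | None = None
    mask_b: np.ndarray | None = None


def _crop_pair(pair: TrainingPair, crop_len: int, rng: np.random.Generator) -> TrainingPair | None:
    """Crop both sequences to at most crop_len residues, keeping >= 1 aligned column.

    A window on A is drawn uniformly among those containing a randomly chosen
    aligned column; the window on B spans the columns aligned inside it,
    clamped to crop_len.  Coordinates are re-indexed to the crops.
    """
    la, lb = len(pair.seq_a), len(pair.seq_b)
    cols = pair.alignment.cols
    if not cols:
        return None
    if la <= crop_len and lb <= crop_len:
        return pair
    anchor_i, _ = cols[rng.integers(len(cols))]
    win_a = min(crop_len, la)
    lo = max(0, anchor_i - win_a)          # window start (0-based), must cover anchor_i-1
    hi = min(anchor_i - 1, la - win_a)
    start_a = int(rng.integers(lo, hi + 1)) if hi >= lo else max(0, anchor_i - win_a)
    end_a = start_a + win_a
    inside = [(i, j) for i, j in cols if start_a < i <= end_a]
    if not inside:
        return None
    win_b = min(crop_len, lb)
    j_lo, j_hi = inside[0][1], inside[-1][1]
    start_b = j_lo - 1
    if j_hi - start_b > win_b:             # clamp: keep the leading columns that fit
        inside = [(i, j) for i, j in inside if j - start_b <= win_b]
    end_b = min(lb, start_b + win_b)
    kept = tuple((i - start_a, j - start_b) for i, j in inside)
    return TrainingPair(
        seq_a=Sequence(pair.seq_a.id, pair.seq_a.seq[start_a:end_a]),
        seq_b=Sequence(pair.seq_b.id, pair.seq_b.seq[start_b:end_b]),
        alignment=PairwiseAlignment(pair.alignment.id_a, pair.alignment.id_b, kept),
        mask_a=None if pair.mask_a is None else pair.mask_a[start_a:end_a],
        mask_b=None if pair.mask_b is None else pair.mask_b[start_b:end_b],
    )


def make_training_batch(
    pairs: TypingSequence[TrainingPair],
    cfg: TrainingConfig,
    rng: np.random.Generator,
) -> list[TrainingPair]:
    """Sample batch_size pairs with replacement and crop each to crop_len."""
    batch: list[TrainingPair] = []
    attempts = 0
    while len(batch) < cfg.batch_size and attempts < 20 * cfg.batch_size:
        attempts += 1
        pair = pairs[rng.integers(len(pairs))]
        cropped = _crop_pair(pair, cfg.crop_len, rng)
        if cropped is None:
            logger.warning("skipping pair (%s, %s): alignment does not fit any crop window",
                           pair.alignment.id_a, pair.alignment.id_b)
            continue
        batch.append(cropped)
    if not batch:
        raise ValueError("no training pair admits a crop window with an aligned column")
    return batch


class AdamW:
    """Decoupled weight decay Adam over a flat dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / bc1
            v_hat = self.v[k] / bc2
            p -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p)


def _pair_loss_and_grads(pair: TrainingPair, params: dict, model_cfg: ModelConfig,
                         cfg: TrainingConfig, grads: dict) -> tuple[float, float, float]:
    tokens_a = _model.tokenize(pair.seq_a.seq, model_cfg)
    tokens_b = _model.tokenize(pair.seq_b.seq, model_cfg)
    emb_a, cache_a = _model.forward(tokens_a, params, model_cfg, want_cache=True)
    emb_b, cache_b = _model.forward(tokens_b, params, model_cfg, want_cache=True)
    T = targets_from_alignment(pair.alignment, len(tokens_a), len(tokens_b))
    loss, npair, l2, dA, dB = masked_npair_loss(
        emb_a, emb_b, T, pair.mask_a, pair.mask_b,
        gamma=cfg.gamma, symmetrized=cfg.symmetrized, return_grads=True,
    )
    _model.backward(dA, tokens_a, cache_a, params, model_cfg, grads)
    _model.backward(dB, tokens_b, cache_b, params, model_cfg, grads)
    return loss, npair, l2


def train(
    params: dict,
    pairs: TypingSequence[TrainingPair],
    cfg: TrainingConfig,
    model_cfg: ModelConfig,
    callback=None,
) -> tuple[dict, list[TrainingRecord]]:
    """Run cfg.steps AdamW steps on the batch-mean masked N-pair loss.

    Returns the trained parameters (updated in place on a copy) and the per-step
    loss history.  Deterministic for a fixed cfg.seed.
    """
    if cfg.steps > 0 and not pairs:
        raise ValueError("need at least one training pair")
    params = {k: np.array(v, dtype=float) for k, v in params.items()}
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    history: list[TrainingRecord] = []
    for step in range(cfg.steps):
        batch = make_training_batch(pairs, cfg, rng)
        grads = _model.zero_like_params(params)
        tot_loss = tot_npair = tot_l2 = 0.0
        for pair in batch:
            loss, npair, l2 = _pair_loss_and_grads(pair, params, model_cfg, cfg, grads)
            tot_loss += loss
            tot_npair += npair
            tot_l2 += l2
        scale = 1.0 / len(batch)
        for k in grads:
            grads[k] *= scale
        mean_loss = tot_loss * scale
        if not np.isfinite(mean_loss):
            raise FloatingPointError(
                f"non-finite training loss at step {step}: {mean_loss!r}; "
                "try a lower learning rate"
            )
        opt.step(params, grads)
        rec = TrainingRecord(step, mean_loss, tot_npair * scale, tot_l2 * scale)
        history.append(rec)
        if callback is not None:
            callback(rec)
    return params, history
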