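"""Synthetic homolog pairs and mini-benchmarks with known alignment truth.

A common ancestor is drawn uniformly over the 20 amino acids; two descendant
copies evolve independently by per-residue substitution (probability
``sub_rate``, uniform over the 19 alternatives) and geometric-length
insertions / deletions (an indel event with probability ``indel_rate`` per
ancestral position, equally likely insertion or deletion, lengths geometric
with mean ``indel_len_mean``).  Ancestral positions retained in both copies
define the true residue-level alignment columns, which are strictly
increasing in both coordinates by construction.

This generator stands in for curated homolog-pair datasets: it produces
gapped pairs with exact column truth but makes no attempt to mimic real
substitution matrices (BLOSUM), domain architecture, or database cluster
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .benchmark import TruthTable, shuffle_decoys
from .model import AMINO_ACIDS, Sequence
from .training import PairwiseAlignment, TrainingPair

import pandas as pd


@dataclass(frozen=True)
class SimConfig:
    """Mutation-model parameters for simulated homolog pairs.

    Defaults give remote-but-detectable homologs: expected aligned-column
    identity (1 - sub_rate)^2 + sub_rate^2 / 19 ~ 0.50 at sub_rate 0.3.
    """

    alphabet: str = AMINO_ACIDS
    ancestor_len: int = 256
    sub_rate: float = 0.3
    indel_rate: float = 0.05
    indel_len_mean: float = 3.0
    n_pairs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sub_rate < 1 and 0 <= self.indel_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.ancestor_len < 1 or self.n_pairs < 1:
            raise ValueError("lengths and counts must be positive")
        if self.indel_len_mean < 1:
            raise ValueError("indel_len_mean must be >= 1")


def _random_seq(length: int, alphabet: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _derive_copy(ancestor: str, cfg: SimConfig, rng: np.random.Generator):
    """Mutate one descendant; returns (sequence, map ancestor pos -> 1-based pos or None)."""
    alphabet = cfg.alphabet
    out: list[str] = []
    anc_to_child: list[int | None] = []
    skip = 0
    for p, residue in enumerate(ancestor):
        if skip > 0:
            skip -= 1
            anc_to_child.append(None)
            continue
        if cfg.indel_rate > 0 and rng.random() < cfg.indel_rate:
            length = int(rng.geometric(1.0 / cfg.indel_len_mean))
            if rng.random() < 0.5:
                out.extend(_random_seq(length, alphabet, rng))  # insertion before p
            else:
                skip = length - 1                                # deletion starting at p
                anc_to_child.append(None)
                continue
        if cfg.sub_rate > 0 and rng.random() < cfg.sub_rate:
            choices = [c for c in alphabet if c != residue]
            residue = choices[rng.integers(len(choices))]
        out.append(residue)
        anc_to_child.append(len(out))
    return "".join(out), anc_to_child


def simulate_homolog_pair(
    cfg: SimConfig,
    rng: np.random.Generator | int | None = None,
    id_a: str = "A",
    id_b: str = "B",
    max_retries: int = 20,
) -> tuple[Sequence, Sequence, PairwiseAlignment]:
    """Draw an ancestor and two independent descendants with column truth."""
    rng = np.random.default_rng(rng)
    for _ in range(max_retries):
        ancestor = _random_seq(cfg.ancestor_len, cfg.alphabet, rng)
        seq_a, map_a = _derive_copy(ancestor, cfg, rng)
        seq_b, map_b = _derive_copy(ancestor, cfg, rng)
        cols = tuple(
            (ia, ib) for ia, ib in zip(map_a, map_b) if ia is not None and ib is not None
        )
        if seq_a and seq_b and cols:
            return (Sequence(id_a, seq_a), Sequence(id_b, seq_b),
                    PairwiseAlignment(id_a, id_b, cols))
    raise ValueError("could not simulate a non-degenerate homolog pair; "
                     "check sub_rate / indel_rate")


def simulate_training_pairs(
    cfg: SimConfig, rng: np.random.Generator | int | None = None
) -> list[TrainingPair]:
    """cfg.n_pairs homolog pairs packaged as supervised training examples."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    pairs = []
    for i in range(cfg.n_pairs):
        a, b, aln = simulate_homolog_pair(cfg, rng, id_a=f"pair{i}_a", id_b=f"pair{i}_b")
        pairs.append(TrainingPair(a, b, aln))
    return pairs


def simulate_benchmark(
    cfg: SimConfig,
    n_queries: int,
    n_targets_per_query: int = 2,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[Sequence], list[Sequence], list[Sequence], TruthTable]:
    """A self-contained mini-benchmark: queries, targets, shuffled decoys, truth.

    Each query has exactly one homologous target (label true_strong) plus
    n_targets_per_query - 1 unrelated targets (independent ancestors, label
    unlabeled).  The decoy set shuffles every target (all query-decoy pairs
    labelled decoy_shuffled).  The truth table covers the full cross product.
    """
    if n_queries < 1 or n_targets_per_query < 1:
        raise ValueError("need at least one query and one target per query")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    queries: list[Sequence] = []
    targets: list[Sequence] = []
    homolog_of: dict[str, str] = {}
    for qi in range(n_queries):
        q, t, _ = simulate_homolog_pair(cfg, rng, id_a=f"query{qi}", id_b=f"target{qi}_hom")
        queries.append(q)
        targets.append(t)
        homolog_of[q.id] = t.id
        for ui in range(n_targets_per_query - 1):
            targets.append(Sequence(f"target{qi}_bg{ui}",
                                    _random_seq(cfg.ancestor_len, cfg.alphabet, rng)))
    decoys = shuffle_decoys(targets, seed=rng)
    records = []
    for q in queries:
        for t in targets:
            label = "true_strong" if homolog_of[q.id] == t.id else "unlabeled"
            records.append((q.id, t.id, label))
        for d in decoys:
            records.append((q.id, d.id, "decoy_shuffled"))
    truth = TruthTable(pd.DataFrame(records, columns=["query_id", "target_id", "label"]))
    return queries, targets, decoys, truth


def insert_repeat(
    seq: Sequence, motif: str, n_copies: int, pos: int
) -> tuple[Sequence, tuple[int, int]]:
    """Insert motif * n_copies at 0-based position pos.

    Returns the new sequence and the inserted interval as a 0-based half-open
    (start, end) pair — ground truth for mask evaluation.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not (0 <= pos <= len(seq)):
        raise ValueError(f"pos {pos} outside [0, {len(seq)}]")
    insert = motif * n_copies
    new = Sequence(seq.id, seq.seq[:pos] + insert + seq.seq[pos:])
    return new, (pos, pos + len(insert))
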