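"""Recall-vs-filtration evaluation of pre-filter hit lists.

A pre-filter is judged by how many true homologous pairs it retains (recall)
while removing decoy pairs (filtration) as the score threshold rises.  Truth
labels are stratified by alignment confidence: strong matches (E <= 1e-10),
weaker matches (E <= 1e-3), low-similarity decoys (E >= 10), and shuffled
decoys (composition-preserving permutations of real targets, which destroy
any homology signal).  Pairs between the weak and decoy cuts are excluded
from both populations.  A truth pair absent from the hit list scores -inf:
it is filtered at every threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .model import Sequence
from .search import ScoredHit

LABELS = ("true_strong", "true_weak", "decoy_low_sim", "decoy_shuffled", "unlabeled")


@dataclass
class TruthTable:
    """(query_id, target_id) -> label, optionally with the underlying E-value."""

    records: pd.DataFrame  # columns: query_id, target_id, label[, evalue]

    def __post_init__(self) -> None:
        df = self.records
        required = {"query_id", "target_id", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"truth table needs columns {sorted(required)}")
        if df.duplicated(["query_id", "target_id"]).any():
            raise ValueError("duplicate (query, target) pair in truth table")
        bad = set(df["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown truth labels: {sorted(bad)}")

    def pairs(self, label: str) -> set[tuple[str, str]]:
        df = self.records
        sub = df[df["label"] == label]
        return set(zip(sub["query_id"], sub["target_id"]))


@dataclass
class CurvePoint:
    threshold: float
    recall: float
    filtration: float


def shuffle_decoys(targets: list[Sequence], seed: int | np.random.Generator = 0,
                   suffix: str = "_shuffled") -> list[Sequence]:
    """One decoy per target: a uniform permutation of its residues.

    Length and residue composition are conserved; homology signal is not.
    Deterministic under the seed; decoy ids get a suffix to stay distinct.
    """
    if not targets:
        raise ValueError("no sequences to shuffle")
    rng = np.random.default_rng(seed)
    decoys = []
    for t in targets:
        chars = np.array(list(t.seq))
        rng.shuffle(chars)
        decoys.append(Sequence(t.id + suffix, "".join(chars)))
    return decoys


def label_truth(evalues: pd.DataFrame, strong_cut: float = 1e-10,
                weak_cut: float = 1e-3, decoy_cut: float = 10.0) -> TruthTable:
    """Stratify (query, target, E-value) records into truth labels.

    true_strong: E <= strong_cut (these are also true_weak by definition, but
    each pair carries its most stringent label; curve construction treats
    true_strong pairs as members of the weak stratum too).
    """
    df = evalues.copy()
    required = {"query_id", "target_id", "evalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"E-value table needs columns {sorted(required)}")
    if (df["evalue"] < 0).any():
        raise ValueError("E-values must be >= 0")
    if df.duplicated(["query_id", "target_id"]).any():
        raise ValueError("duplicate (query, target) pair in E-value table")
    e = df["evalue"].to_numpy(dtype=float)
    label = np.where(e <= strong_cut, "true_strong",
             np.where(e <= weak_cut, "true_weak",
              np.where(e >= decoy_cut, "decoy_low_sim", "unlabeled")))
    df["label"] = label
    return TruthTable(df[["query_id", "target_id", "label", "evalue"]])


def _truth_pairs(truth: TruthTable, label: str) -> set[tuple[str, str]]:
    pairs = truth.pairs(label)
    # the strong stratum is a subset of the weak one
    if label == "true_weak":
        pairs |= truth.pairs("true_strong")
    return pairs


def recall_filtration_curve(
    hits: Iterable[ScoredHit],
    truth: TruthTable,
    true_label: str = "true_strong",
    decoy_label: str = "decoy_shuffled",
) -> list[CurvePoint]:
    """Sweep thresholds over the distinct hit scores, descending.

    At each threshold t, a pair is retained iff its pre-filter score >= t;
    recall = retained true pairs / all true pairs, filtration = removed decoy
    pairs / all decoy pairs.  Truth pairs absent from the hit list are never
    retained.
    """
    true_pairs = _truth_pairs(truth, true_label)
    decoy_pairs = _truth_pairs(truth, decoy_label)
    if not true_pairs:
        raise ValueError(f"no truth pairs with label {true_label!r}")
    if not decoy_pairs:
        raise ValueError(f"no truth pairs with label {decoy_label!r}")
    score = {}
    for h in hits:
        score[(h.query_id, h.target_id)] = h.score
    true_scores = np.array([score.get(p, -np.inf) for p in true_pairs])
    decoy_scores = np.array([score.get(p, -np.inf) for p in decoy_pairs])
    thresholds = sorted({s for s in score.values()}, reverse=True)
    points = []
    for t in thresholds:
        recall = float(np.mean(true_scores >= t))
        filtration = float(np.mean(decoy_scores < t))
        points.append(CurvePoint(t, recall, filtration))
    return points


def recall_at_filtration(curve: list[CurvePoint], level: float) -> float:
    """Recall at the smallest threshold achieving filtration >= level.

    Step function over the curve's thresholds; no interpolation.  Raises if
    no threshold reaches the requested filtration.
    """
    if not curve:
        raise ValueError("empty curve")
    eligible = [p for p in curve if p.filtration >= level]
    if not eligible:
        raise ValueError(f"no threshold achieves filtration >= {level}")
    best = min(eligible, key=lambda p: p.threshold)
    return best.recall


def curve_to_frame(curve: list[CurvePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {"threshold": [p.threshold for p in curve],
         "recall": [p.recall for p in curve],
         "filtration": [p.filtration for p in curve]}
    )


def plot_curve(curve: list[CurvePoint], ax=None, **kwargs):
    """Recall (y) against filtration (x); requires matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = curve_to_frame(curve).sort_values("filtration")
    ax.plot(df["filtration"], df["recall"], **kwargs)
    ax.set_xlabel("filtration")
    ax.set_ylabel("recall")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    return ax
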