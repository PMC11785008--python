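"""Repeat / low-complexity masks.

Compositionally biased regions (homopolymers, tandem repeats) produce high
similarity scores between unrelated sequences, so their residues are silenced
in the training loss and excluded from the search index and from querying.
Masks are per-residue binary vectors: 0 = repetitive/biased, 1 = keep.

Masks normally come from an external repeat masker (e.g. tantan run with a
16-residue window), ingested either as lower-case-masked FASTA or as
BED-style intervals.  A built-in entropy-based fallback masker is provided
for self-contained use; it flags windows of low Shannon entropy and is not a
reproduction of any external tool's model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import Sequence


@dataclass
class RepeatMask:
    """Per-residue keep/drop bits for one sequence (0 = masked)."""

    seq_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("mask bits must be 0 or 1")

    def __len__(self) -> int:
        return len(self.bits)


def all_ones_mask(seq: Sequence) -> RepeatMask:
    return RepeatMask(seq.id, np.ones(len(seq), dtype=np.int8))


def mask_from_lowercase(seq: Sequence) -> RepeatMask:
    """Lower-case residues (the convention of tantan and dustmasker) -> bit 0."""
    bits = np.array([0 if c.islower() else 1 for c in seq.seq], dtype=np.int8)
    return RepeatMask(seq.id, bits)


def read_mask(path, sequences: list[Sequence]) -> dict[str, RepeatMask]:
    """Read masks for ``sequences`` from a masked FASTA or a BED interval file.

    FASTA input: lower-case residues are masked.  BED input: 0-based
    half-open intervals marking masked regions; all other positions keep
    bit 1.  Sequences the file does not mention get all-ones masks.
    """
    path = Path(path)
    by_id = {s.id: s for s in sequences}
    masks = {s.id: all_ones_mask(s) for s in sequences}
    text = path.read_text()
    if text.lstrip().startswith(">"):
        from .io import read_fasta

        for rec in read_fasta(path):
            if rec.id not in by_id:
                raise ValueError(f"mask FASTA names unknown sequence id {rec.id!r}")
            if len(rec) != len(by_id[rec.id]):
                raise ValueError(f"mask FASTA length mismatch for {rec.id!r}")
            masks[rec.id] = mask_from_lowercase(rec)
        return masks
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
        seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
        if seq_id not in by_id:
            raise ValueError(f"{path}:{lineno}: unknown sequence id {seq_id!r}")
        n = len(by_id[seq_id])
        if not (0 <= start < end <= n):
            raise ValueError(f"{path}:{lineno}: interval [{start}, {end}) outside "
                             f"sequence of length {n}")
        masks[seq_id].bits[start:end] = 0
    return masks


def window_entropy(window: str) -> float:
    """Shannon entropy (bits) of the residue frequencies in a window."""
    _, counts = np.unique(list(window), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def builtin_mask(seq: Sequence, window: int = 16, max_entropy_bits: float = 1.5) -> RepeatMask:
    """Entropy-based low-complexity masker.

    Residue i is masked iff some length-``window`` window covering i has
    Shannon entropy <= ``max_entropy_bits``.  A sequence shorter than the
    window is evaluated as a single window.  Deterministic; default window 16
    flags homopolymer and short-period repeat runs.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = len(seq)
    s = seq.seq.upper()
    bits = np.ones(n, dtype=np.int8)
    if n <= window:
        if window_entropy(s) <= max_entropy_bits:
            bits[:] = 0
        return RepeatMask(seq.id, bits)
    for start in range(n - window + 1):
        if window_entropy(s[start : start + window]) <= max_entropy_bits:
            bits[start : start + window] = 0
    return RepeatMask(seq.id, bits)


def apply_mask_lowercase(seq: Sequence, mask: RepeatMask) -> Sequence:
    """Render a mask as lower-case residues (for masked-FASTA output)."""
    chars = [c.lower() if b == 0 else c.upper() for c, b in zip(seq.seq, mask.bits)]
    return Sequence(seq.id, "".join(chars))


def masked_positions(mask: RepeatMask) -> list[int]:
    """1-based indices of kept (bit 1) residues, in order."""
    return [int(i) + 1 for i in np.flatnonzero(mask.bits)]
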