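"""Readers and writers for the pipeline's file formats.

FASTA (via Biopython, case preserved for mask ingestion), training-pair TSV,
aligned-pair FASTA, hits TSV, truth TSV, and the HDF5 embedding store.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .benchmark import TruthTable, label_truth
from .model import Sequence
from .search import ScoredHit
from .training import PairwiseAlignment, TrainingPair

HITS_COLUMNS = ["query_id", "target_id", "score", "n_matches"]


def read_fasta(path) -> list[Sequence]:
    """Read records preserving order, ids and residue case."""
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        s = str(rec.seq).strip()
        if not s:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        seqs.append(Sequence(rec.id, s))
    return seqs


def write_fasta(seqs: list[Sequence], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_hits(hits: list[ScoredHit], path) -> None:
    """TSV with header; scores at full precision (>= 9 significant digits)."""
    df = pd.DataFrame(
        [(h.query_id, h.target_id, h.score, h.n_matches) for h in hits],
        columns=HITS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_hits(path) -> list[ScoredHit]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "target_id": str})
        return [
            ScoredHit(r.query_id, r.target_id, float(r.score), int(r.n_matches))
            for r in df.itertuples()
        ]
    except (ValueError, KeyError, AttributeError) as exc:
        raise ValueError(f"malformed hits file {path}: {exc}") from exc


def _parse_cols(text: str) -> tuple[tuple[int, int], ...]:
    if not text.strip():
        return ()
    pairs = []
    for token in text.strip().split(","):
        i, j = token.split(":")
        pairs.append((int(i), int(j)))
    return tuple(pairs)


def write_training_pairs(pairs: list[TrainingPair], path) -> None:
    """Tab-separated: id_a, id_b, seq_a, seq_b, "i:j,i:j,..." (1-based)."""
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tseq_a\tseq_b\tcols\n")
        for p in pairs:
            cols = ",".join(f"{i}:{j}" for i, j in p.alignment.cols)
            fh.write(f"{p.seq_a.id}\t{p.seq_b.id}\t{p.seq_a.seq}\t{p.seq_b.seq}\t{cols}\n")


def read_training_pairs(path) -> list[TrainingPair]:
    pairs: list[TrainingPair] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id_a"):
            raise ValueError(f"{path}: expected a training-pairs header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 tab-separated fields")
            id_a, id_b, seq_a, seq_b, cols = fields
            aln = PairwiseAlignment(id_a, id_b, _parse_cols(cols))
            pairs.append(TrainingPair(Sequence(id_a, seq_a), Sequence(id_b, seq_b), aln))
    return pairs


def alignment_from_aligned_rows(id_a: str, row_a: str, id_b: str, row_b: str) -> TrainingPair:
    """Extract a column pairing from two gapped rows of equal length ('-' = gap)."""
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    cols = []
    i = j = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-":
            i += 1
        if cb != "-":
            j += 1
        if ca != "-" and cb != "-":
            cols.append((i, j))
    seq_a = row_a.replace("-", "")
    seq_b = row_b.replace("-", "")
    aln = PairwiseAlignment(id_a, id_b, tuple(cols))
    return TrainingPair(Sequence(id_a, seq_a), Sequence(id_b, seq_b), aln)


def read_aligned_pair_fasta(path, max_pairs_per_cluster: int | None = None) -> list[TrainingPair]:
    """Consecutive record pairs of a gapped FASTA become training pairs.

    With ``max_pairs_per_cluster``, at most that many pairs are kept per
    cluster, where the cluster key is the id prefix before the last '/'
    (ids without '/' are their own cluster).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise ValueError(f"{path}: aligned-pair FASTA needs an even number of records")
    pairs = []
    per_cluster: dict[str, int] = {}
    for a, b in zip(records[::2], records[1::2]):
        cluster = a.id.rsplit("/", 1)[0]
        if max_pairs_per_cluster is not None:
            if per_cluster.get(cluster, 0) >= max_pairs_per_cluster:
                continue
            per_cluster[cluster] = per_cluster.get(cluster, 0) + 1
        pairs.append(alignment_from_aligned_rows(a.id, str(a.seq), b.id, str(b.seq)))
    return pairs


def write_truth(truth: TruthTable, path) -> None:
    truth.records.to_csv(path, sep="\t", index=False)


def read_truth(path, strong_cut: float = 1e-10, weak_cut: float = 1e-3,
               decoy_cut: float = 10.0) -> TruthTable:
    """Read a truth TSV carrying either a label column or an evalue column."""
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "target_id": str})
    if "label" in df.columns:
        return TruthTable(df)
    if "evalue" in df.columns:
        return label_truth(df, strong_cut, weak_cut, decoy_cut)
    raise ValueError(f"{path}: truth table needs a 'label' or 'evalue' column")


def write_embedding_store(embeddings: dict[str, np.ndarray], path) -> None:
    """One named (n, d) dataset per sequence in an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        for seq_id, emb in embeddings.items():
            fh.create_dataset(seq_id, data=np.asarray(emb))


def read_embedding_store(path) -> dict[str, np.ndarray]:
    import h5py

    with h5py.File(path, "r") as fh:
        return {name: fh[name][()] for name in fh}
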