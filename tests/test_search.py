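import numpy as np
import pytest

import embfilter as ef
from embfilter.masking import RepeatMask
from embfilter.search import ExactIndex, Match, QuantizedIndex, ResidueRef


def random_embeddings(rng, lengths, d):
    return {f"s{i}": rng.normal(size=(n, d)) for i, n in enumerate(lengths)}


def brute_force_knn(vectors, seq_ids, positions, q, k):
    """Full-scan oracle: cosine desc, ties by (seq_id, pos)."""
    qn = q / np.linalg.norm(q)
    vn = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    cos = vn @ qn
    order = sorted(range(len(cos)), key=lambda i: (-cos[i], seq_ids[i], positions[i]))
    return [(seq_ids[i], positions[i], cos[i]) for i in order[:k]]


class TestBuildIndex:
    def test_counts_all_unmasked_residues(self, rng):
        emb = random_embeddings(rng, [5, 7], 4)
        cfg = ef.SearchConfig(k=3, d=4)
        assert ef.build_index(emb, None, cfg).count == 12

    def test_masked_residues_absent(self, rng):
        emb = random_embeddings(rng, [5, 7], 4)
        masks = {"s0": RepeatMask("s0", np.array([1, 0, 0, 0, 1])),
                 "s1": RepeatMask("s1", np.ones(7, dtype=int))}
        cfg = ef.SearchConfig(k=3, d=4)
        assert ef.build_index(emb, masks, cfg).count == 9

    def test_backends_index_identical_counts(self, rng):
        emb = random_embeddings(rng, [6, 6], 4)
        exact = ef.build_index(emb, None, ef.SearchConfig(k=3, d=4, backend="exact"))
        quant = ef.build_index(emb, None, ef.SearchConfig(k=3, d=4, backend="quantized"))
        assert exact.count == quant.count == 12

    def test_zero_indexable_vectors_raises(self, rng):
        emb = random_embeddings(rng, [3], 4)
        masks = {"s0": RepeatMask("s0", np.zeros(3, dtype=int))}
        with pytest.raises(ValueError, match="no unmasked"):
            ef.build_index(emb, masks, ef.SearchConfig(k=3, d=4))

    def test_width_mismatch_raises(self, rng):
        emb = random_embeddings(rng, [3], 5)
        with pytest.raises(ValueError, match="width"):
            ef.build_index(emb, None, ef.SearchConfig(k=3, d=4))


class TestKnn:
    def test_indexed_vector_is_its_own_nearest_neighbor(self, rng):
        emb = random_embeddings(rng, [10], 8)
        index = ef.build_index(emb, None, ef.SearchConfig(k=3, d=8))
        ref, cos = ef.knn(index, emb["s0"][4], 1)[0]
        assert ref == ResidueRef("s0", 5)
        assert np.isclose(cos, 1.0)

    def test_k_larger_than_index_returns_all_sorted(self, rng):
        emb = random_embeddings(rng, [6], 4)
        index = ef.build_index(emb, None, ef.SearchConfig(k=3, d=4))
        result = ef.knn(index, rng.normal(size=4), 100)
        assert len(result) == 6
        cosines = [c for _, c in result]
        assert cosines == sorted(cosines, reverse=True)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.choice([4, 16]))
        emb = random_embeddings(rng, rng.integers(3, 40, size=4), d)
        index = ef.build_index(emb, None, ef.SearchConfig(k=5, d=d))
        for _ in range(3):
            q = rng.normal(size=d)
            got = [(r.seq_id, r.pos, c) for r, c in ef.knn(index, q, 5)]
            expected = brute_force_knn(index.vectors, list(index.seq_ids),
                                       list(index.positions), q, 5)
            for (gs, gp, gc), (es, ep, ec) in zip(got, expected):
                assert (gs, gp) == (es, ep)
                np.testing.assert_allclose(gc, ec, atol=1e-12)

    def test_ties_broken_lexicographically(self):
        # identical vectors: deterministic order by (seq_id, pos)
        v = np.ones((3, 4))
        emb = {"b": v[:1], "a": v[1:]}
        index = ef.build_index(emb, None, ef.SearchConfig(k=3, d=4))
        refs = [r for r, _ in ef.knn(index, np.ones(4), 3)]
        assert refs == [ResidueRef("a", 1), ResidueRef("a", 2), ResidueRef("b", 1)]


class TestNoiseGate:
    @pytest.mark.parametrize("cosine,d,delta,expected", [
        (1.0, 256, 3.0, 0.8125),
        (0.0, 256, 3.0, 0.0),
        (0.0, 16, 3.0, 0.0),
        (0.5, 256, 3.0, 0.3125),
    ])
    def test_gated_score_values(self, cosine, d, delta, expected):
        assert ef.noise_gated_score(cosine, d, delta) == pytest.approx(expected)

    def test_gate_never_negative(self, rng):
        for _ in range(100):
            c = rng.uniform(-1, 1)
            assert ef.noise_gated_score(c, 64, 3.0) >= 0.0


class TestAccumulate:
    def _match(self, q, t, gated):
        return Match(ResidueRef(q, 1), ResidueRef(t, 1), gated, gated)

    def test_empty(self):
        assert ef.accumulate([]) == []

    def test_single_match(self):
        hits = ef.accumulate([self._match("q", "t", 0.4)])
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(0.4)
        assert hits[0].n_matches == 1

    def test_sums_per_pair_and_counts_zero_scores(self):
        matches = [self._match("q", "t", g) for g in (0.2, 0.3, 0.0)]
        hits = ef.accumulate(matches)
        assert hits[0].score == pytest.approx(0.5)
        assert hits[0].n_matches == 3


@pytest.fixture(scope="module")
def toy_model():
    cfg = ef.ModelConfig(embed_dim=8, n_blocks=2, kernel_size=3)
    params = ef.init_params(cfg, np.random.default_rng(42))
    return cfg, params


def make_seqs(rng, n, length, prefix):
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    return [ef.Sequence(f"{prefix}{i}", "".join(rng.choice(aas, size=length)))
            for i in range(n)]


class TestSearchEndToEnd:
    def test_identical_sequence_is_top_hit(self, toy_model, rng):
        cfg, params = toy_model
        targets = make_seqs(rng, 5, 30, "t")
        query = ef.Sequence("q", targets[2].seq)
        # with k=1 each query residue's sole neighbor is its own exact copy,
        # so the identical target accumulates every match
        hits = ef.search([query], targets, params, cfg,
                         ef.SearchConfig(k=1, d=cfg.embed_dim))
        assert hits[0].target_id == "t2"

    def test_reversed_orientation_matches_forward_with_exhaustive_k(self, toy_model, rng):
        cfg, params = toy_model
        targets = make_seqs(rng, 1, 25, "t")
        queries = make_seqs(rng, 1, 25, "q")
        fwd = ef.search(queries, targets, params, cfg,
                        ef.SearchConfig(k=1000, d=cfg.embed_dim))
        rev = ef.search(queries, targets, params, cfg,
                        ef.SearchConfig(k=1000, d=cfg.embed_dim, reversed=True))
        assert fwd[0].query_id == rev[0].query_id == "q0"
        assert fwd[0].target_id == rev[0].target_id == "t0"
        np.testing.assert_allclose(fwd[0].score, rev[0].score)

    def test_all_query_residues_masked_gives_empty_hits(self, toy_model, rng):
        cfg, params = toy_model
        targets = make_seqs(rng, 2, 20, "t")
        queries = make_seqs(rng, 1, 20, "q")
        masks = {"q0": RepeatMask("q0", np.zeros(20, dtype=int))}
        hits = ef.search(queries, targets, params, cfg,
                         ef.SearchConfig(k=10, d=cfg.embed_dim), query_masks=masks)
        assert hits == []

    def test_score_monotone_in_k(self, toy_model, rng):
        cfg, params = toy_model
        targets = make_seqs(rng, 4, 30, "t")
        queries = make_seqs(rng, 2, 30, "q")
        scores = {}
        for k in (5, 20, 200):
            hits = ef.search(queries, targets, params, cfg,
                             ef.SearchConfig(k=k, d=cfg.embed_dim))
            scores[k] = {(h.query_id, h.target_id): h.score for h in hits}
        for pair, s5 in scores[5].items():
            assert scores[20].get(pair, 0.0) >= s5 - 1e-12
        for pair, s20 in scores[20].items():
            assert scores[200].get(pair, 0.0) >= s20 - 1e-12

    def test_target_insertion_order_irrelevant(self, toy_model, rng):
        cfg, params = toy_model
        targets = make_seqs(rng, 5, 25, "t")
        queries = make_seqs(rng, 2, 25, "q")
        scfg = ef.SearchConfig(k=30, d=cfg.embed_dim)
        h1 = ef.search(queries, targets, params, cfg, scfg)
        h2 = ef.search(queries, targets[::-1], params, cfg, scfg)
        s1 = {(h.query_id, h.target_id): h.score for h in h1}
        s2 = {(h.query_id, h.target_id): h.score for h in h2}
        assert set(s1) == set(s2)
        for pair in s1:
            np.testing.assert_allclose(s1[pair], s2[pair])

    def test_huge_gate_zeroes_all_scores(self, toy_model, rng):
        cfg, params = toy_model
        targets = make_seqs(rng, 3, 20, "t")
        queries = make_seqs(rng, 1, 20, "q")
        # delta / sqrt(d) >= 1 clamps every gated score to zero
        delta = 2.0 * np.sqrt(cfg.embed_dim)
        hits = ef.search(queries, targets, params, cfg,
                         ef.SearchConfig(k=10, d=cfg.embed_dim, delta=delta))
        assert all(h.score == 0.0 for h in hits)

    def test_hits_sorted_by_query_then_score(self, toy_model, rng):
        cfg, params = toy_model
        targets = make_seqs(rng, 6, 25, "t")
        queries = make_seqs(rng, 3, 25, "q")
        hits = ef.search(queries, targets, params, cfg,
                         ef.SearchConfig(k=50, d=cfg.embed_dim))
        keys = [(h.query_id, -h.score, h.target_id) for h in hits]
        assert keys == sorted(keys)


class TestQuantizedBackend:
    def test_exhaustive_probing_without_pq_equals_exact(self, rng):
        emb = random_embeddings(rng, [20, 20], 8)
        exact = ExactIndex(emb, None, 8)
        quant = QuantizedIndex(emb, None, 8, nlist=4, nprobe=4)
        q = rng.normal(size=(3, 8))
        r_e, c_e = exact.knn_batch(q, 7)
        r_q, c_q = quant.knn_batch(q, 7)
        for row_e, row_q, cos_e, cos_q in zip(r_e, r_q, c_e, c_q):
            assert row_e == row_q
            np.testing.assert_allclose(cos_e, cos_q, atol=1e-12)

    def test_partial_probing_recall_is_measured_not_assumed(self, rng):
        emb = random_embeddings(rng, [60, 60], 8)
        exact = ExactIndex(emb, None, 8)
        quant = QuantizedIndex(emb, None, 8, nlist=8, nprobe=2)
        hits = total = 0
        for _ in range(10):
            q = rng.normal(size=8)
            true_refs = {(r.seq_id, r.pos) for r, _ in exact.knn(q, 10)}
            approx_refs = {(r.seq_id, r.pos) for r, _ in quant.knn(q, 10)}
            hits += len(true_refs & approx_refs)
            total += len(true_refs)
        recall = hits / total
        assert 0.0 <= recall <= 1.0
        assert recall > 0.0  # probing the nearest cells finds some true neighbors

    def test_pq_codes_give_valid_neighbors(self, rng):
        emb = random_embeddings(rng, [40, 40], 8)
        quant = QuantizedIndex(emb, None, 8, nlist=4, nprobe=4, pq_subspaces=2)
        result = quant.knn(rng.normal(size=8), 5)
        assert len(result) == 5
        assert all(isinstance(r, ResidueRef) for r, _ in result)
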