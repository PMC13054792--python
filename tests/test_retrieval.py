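"""Exact ranking, inverse-distance scores, pairwise tables, HNSW, persistence."""

import numpy as np
import pytest

from cbmir.dicom_io import UIDGenerator
from cbmir.retrieval import (
    SCORE_CAP,
    FeatureVector,
    VectorIndex,
    ann_query,
    euclidean_distance,
    precompute_pairwise,
    query_topk,
    similarity_score,
)


def _make_vectors(n, dim, seed, labels=None):
    rng = np.random.default_rng(seed)
    gen = UIDGenerator(seed)
    return [
        FeatureVector(
            values=rng.normal(size=dim).astype(np.float32),
            uids=gen.triple(),
            label=None if labels is None else labels[i],
        )
        for i in range(n)
    ]


class TestDistanceAndScore:
    def test_identity_is_zero(self):
        v = _make_vectors(1, 8, 0)[0]
        assert euclidean_distance(v, v) == 0.0

    def test_three_four_five(self):
        p = np.zeros(16)
        q = np.zeros(16)
        q[3], q[7] = 3.0, 4.0
        assert euclidean_distance(p, q) == pytest.approx(5.0)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p, q = rng.normal(size=(2, 16))
            d = euclidean_distance(p, q)
            assert d == euclidean_distance(q, p)
            assert d == pytest.approx(float(np.linalg.norm(p - q)), rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance(np.zeros(4), np.zeros(5))

    def test_score_is_reciprocal(self):
        assert similarity_score(0.5) == pytest.approx(2.0)

    def test_zero_distance_hits_documented_cap(self):
        assert similarity_score(0.0) == SCORE_CAP
        assert similarity_score(1e-9) == SCORE_CAP

    def test_score_strictly_decreasing_in_distance(self):
        grid = np.linspace(1e-3, 10, 100)
        scores = [similarity_score(d) for d in grid]
        assert all(b < a for a, b in zip(scores, scores[1:]))

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            similarity_score(-0.1)


class TestExactQuery:
    def test_known_order(self):
        gen = UIDGenerator(0)
        base = np.zeros(4, dtype=np.float32)
        entries = [
            FeatureVector(values=base + off, uids=gen.triple())
            for off in (0.3, 0.1, 0.2)
        ]
        q = FeatureVector(values=base, uids=gen.triple())
        ranked = query_topk(q, VectorIndex(entries), k=3)
        assert ranked.distances() == pytest.approx([0.2, 0.4, 0.6])

    @pytest.mark.parametrize("k", [1, 10, 50])
    def test_matches_brute_force_oracle(self, k):
        entries = _make_vectors(200, 256, 2)
        index = VectorIndex(entries)
        queries = _make_vectors(5, 256, 3)
        for q in queries:
            ranked = query_topk(q, index, k=k)
            # independent O(N^2)-style oracle: full sort of all distances
            oracle = sorted(
                ((float(np.linalg.norm(e.values.astype(np.float64) - q.values.astype(np.float64))), e.uids.sop_uid)
                 for e in entries),
            )[:k]
            assert ranked.sop_uids() == [s for _, s in oracle]
            assert ranked.distances() == pytest.approx([d for d, _ in oracle], rel=1e-6)

    def test_truncation_to_index_size(self):
        index = VectorIndex(_make_vectors(10, 8, 4))
        q = _make_vectors(1, 8, 5)[0]
        assert len(query_topk(q, index, k=50)) == 10

    def test_indexed_query_excludes_itself(self):
        entries = _make_vectors(20, 8, 6)
        index = VectorIndex(entries)
        ranked = query_topk(entries[0], index, k=20)
        assert entries[0].uids.sop_uid not in ranked.sop_uids()
        assert len(ranked) == 19

    def test_scores_mirror_distances(self):
        index = VectorIndex(_make_vectors(30, 16, 7))
        ranked = query_topk(_make_vectors(1, 16, 8)[0], index, k=30)
        d = ranked.distances()
        s = np.array([r.score for r in ranked.results])
        assert np.all(np.diff(d) >= 0)
        assert np.all(np.diff(s) <= 0)

    def test_dimension_mismatch(self):
        index = VectorIndex(_make_vectors(5, 8, 9))
        with pytest.raises(ValueError):
            query_topk(_make_vectors(1, 9, 10)[0], index, k=1)


class TestPairwiseTables:
    def test_lookup_consistent_with_exact_query(self):
        entries = _make_vectors(100, 32, 11)
        index = precompute_pairwise(VectorIndex(entries))
        for e in index.entries:
            table = index.lookup(e.uids.sop_uid, k=10)
            fresh = query_topk(e, index, k=10)
            assert table.sop_uids() == fresh.sop_uids()
            assert table.distances() == pytest.approx(fresh.distances(), rel=1e-6)

    def test_stored_distances_symmetric(self):
        entries = _make_vectors(40, 16, 12)
        index = precompute_pairwise(VectorIndex(entries))
        d = {}
        for i, e in enumerate(index.entries):
            for row, dist in zip(index.neighbor_tables[i], index.neighbor_distances[i]):
                d[(i, int(row))] = dist
        for (i, j), dist in d.items():
            assert d[(j, i)] == pytest.approx(dist, rel=1e-12)

    def test_self_never_in_own_table(self):
        entries = _make_vectors(25, 8, 13)
        index = precompute_pairwise(VectorIndex(entries))
        for i in range(len(index)):
            assert i not in index.neighbor_tables[i]

    def test_singleton_index_rejected(self):
        with pytest.raises(ValueError):
            precompute_pairwise(VectorIndex(_make_vectors(1, 8, 14)))


class TestHNSW:
    def test_recall_against_exact_oracle(self):
        entries = _make_vectors(1000, 64, 15)
        index = VectorIndex(entries)
        index.build_ann(seed=1)
        queries = _make_vectors(100, 64, 16)
        recalls = []
        for q in queries:
            exact = set(query_topk(q, index, k=10).sop_uids())
            approx = set(ann_query(q, index, k=10).sop_uids())
            recalls.append(len(exact & approx) / 10)
        assert np.mean(recalls) >= 0.95

    def test_search_on_frozen_graph_is_deterministic(self):
        index = VectorIndex(_make_vectors(200, 16, 17))
        index.build_ann(seed=2)
        q = _make_vectors(1, 16, 18)[0]
        a = ann_query(q, index, k=10)
        b = ann_query(q, index, k=10)
        assert a.sop_uids() == b.sop_uids()
        assert np.array_equal(a.distances(), b.distances())

    def test_dimension_mismatch_and_missing_graph(self):
        index = VectorIndex(_make_vectors(10, 8, 19))
        with pytest.raises(RuntimeError):
            ann_query(_make_vectors(1, 8, 20)[0], index, k=3)
        index.build_ann()
        with pytest.raises(ValueError):
            ann_query(_make_vectors(1, 9, 21)[0], index, k=3)


class TestPersistence:
    def test_round_trip_is_bit_exact(self, tmp_path):
        labels = ["glioma"] * 20
        entries = _make_vectors(20, 32, 22, labels=labels)
        index = precompute_pairwise(VectorIndex(entries))
        path = index.save(tmp_path / "idx.npz")
        back = VectorIndex.load(path)
        assert np.array_equal(back.matrix, index.matrix)
        assert [e.uids for e in back.entries] == [e.uids for e in index.entries]
        assert [e.label for e in back.entries] == [e.label for e in index.entries]
        for a, b in zip(back.neighbor_tables, index.neighbor_tables):
            assert np.array_equal(a, b)
        # orderings are preserved: same lookups after reload
        sop = index.entries[3].uids.sop_uid
        assert back.lookup(sop, 5).sop_uids() == index.lookup(sop, 5).sop_uids()

    def test_text_export_written(self, tmp_path):
        index = VectorIndex(_make_vectors(5, 4, 23))
        p = index.export_text(tmp_path / "idx.tsv")
        lines = p.read_text().splitlines()
        assert len(lines) == 2 + 5  # header comment + columns + entries

    def test_duplicate_sops_rejected(self):
        entries = _make_vectors(3, 4, 24)
        entries[1] = FeatureVector(values=entries[1].values, uids=entries[0].uids)
        with pytest.raises(ValueError):
            VectorIndex(entries)
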