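"""Hierarchical Navigable Small World (HNSW) approximate nearest-neighbor graph.

A native implementation of the HNSW algorithm (Malkov & Yashunin): each
point is inserted at a geometrically distributed maximum layer; upper
layers form progressively sparser "express" graphs that greedy search
descends before a beam search (width ``ef``) over the bottom layer collects
the candidate set.  Search over a frozen graph is deterministic — the only
randomness is the seeded layer assignment at build time.

This serves unseen-query retrieval; the exact brute-force ranking in
:mod:`cbmir.retrieval` is the reference oracle against which recall is
measured (regression contract: recall@10 ≥ 0.95 at the default parameters
M = 16, ef_construction = 200, ef_search = 100).
"""

from __future__ import annotations

import heapq
import math

import numpy as np

__all__ = ["HNSWGraph"]


class HNSWGraph:
    def __init__(
        self,
        vectors: np.ndarray,
        M: int = 16,
        ef_construction: int = 200,
        ef_search: int = 100,
        seed: int = 0,
    ):
        vectors = np.ascontiguousarray(vectors, dtype=np.float32)
        if vectors.ndim != 2 or vectors.shape[0] == 0:
            raise ValueError("vectors must be a non-empty (n, dim) array")
        self.vectors = vectors
        self.M = M
        self.Mmax0 = 2 * M
        self.ef_construction = ef_construction
        self.ef_search = ef_search
        self._ml = 1.0 / math.log(M)
        rng = np.random.default_rng(seed)

        n = vectors.shape[0]
        self.levels = np.minimum(
            (-np.log(rng.uniform(1e-12, 1.0, size=n)) * self._ml).astype(np.int64), 32
        )
        # links[node][level] -> list[int]
        self.links: list[list[list[int]]] = [
            [[] for _ in range(self.levels[i] + 1)] for i in range(n)
        ]
        self.entry_point = 0
        self.max_level = int(self.levels[0])
        for i in range(1, n):
            self._insert(i)

    # ---- distance helpers ----
    def _dist_one(self, q: np.ndarray, i: int) -> float:
        d = self.vectors[i] - q
        return float(np.dot(d, d))  # squared L2; monotone in true distance

    def _dist_many(self, q: np.ndarray, ids: list[int]) -> np.ndarray:
        d = self.vectors[np.asarray(ids)] - q
        return (d * d).sum(axis=1)

    # ---- core search ----
    def _search_layer(self, q: np.ndarray, entry: int, entry_dist: float, ef: int, level: int):
        """Beam search on one layer; returns [(dist, id)] sorted ascending."""
        visited = {entry}
        candidates = [(entry_dist, entry)]  # min-heap
        results = [(-entry_dist, entry)]  # max-heap on dist
        while candidates:
            d_c, c = heapq.heappop(candidates)
            if d_c > -results[0][0] and len(results) >= ef:
                break
            neigh = [u for u in self.links[c][level] if u not in visited]
            if not neigh:
                continue
            visited.update(neigh)
            dists = self._dist_many(q, neigh)
            worst = -results[0][0]
            for u, d_u in zip(neigh, dists):
                d_u = float(d_u)
                if len(results) < ef or d_u < worst:
                    heapq.heappush(candidates, (d_u, u))
                    heapq.heappush(results, (-d_u, u))
                    if len(results) > ef:
                        heapq.heappop(results)
                    worst = -results[0][0]
        out = sorted((-d, u) for d, u in results)
        return out

    def _greedy_descent(self, q: np.ndarray, node: int, dist: float, from_level: int, to_level: int):
        """ef=1 greedy walk from ``from_level`` down to ``to_level`` (exclusive)."""
        for level in range(from_level, to_level, -1):
            improved = True
            while improved:
                improved = False
                neigh = self.links[node][level]
                if not neigh:
                    continue
                dists = self._dist_many(q, neigh)
                j = int(np.argmin(dists))
                if dists[j] < dist:
                    node, dist = neigh[j], float(dists[j])
                    improved = True
        return node, dist

    # ---- construction ----
    def _select_neighbors(self, cands: list[tuple[float, int]], m: int) -> list[int]:
        """Heuristic neighbor selection: prefer candidates closer to the new
        point than to any already-selected neighbor (keeps the graph navigable
        in clustered data)."""
        selected: list[int] = []
        for d_c, c in cands:
            if len(selected) == m:
                break
            ok = True
            for s in selected:
                if self._dist_one(self.vectors[c], s) < d_c:
                    ok = False
                    break
            if ok:
                selected.append(c)
        if len(selected) < m:  # backfill with closest remaining
            chosen = set(selected)
            for d_c, c in cands:
                if len(selected) == m:
                    break
                if c not in chosen:
                    selected.append(c)
        return selected

    def _insert(self, i: int) -> None:
        q = self.vectors[i]
        l_new = int(self.levels[i])
        ep, d_ep = self.entry_point, self._dist_one(q, self.entry_point)
        if l_new < self.max_level:
            ep, d_ep = self._greedy_descent(q, ep, d_ep, self.max_level, l_new)
        for level in range(min(l_new, self.max_level), -1, -1):
            cands = self._search_layer(q, ep, d_ep, self.ef_construction, level)
            m_max = self.Mmax0 if level == 0 else self.M
            neighbors = self._select_neighbors(cands, self.M)
            self.links[i][level] = list(neighbors)
            for u in neighbors:
                lu = self.links[u][level]
                lu.append(i)
                if len(lu) > m_max:
                    du = self._dist_many(self.vectors[u], lu)
                    keep = np.argsort(du, kind="stable")[:m_max]
                    self.links[u][level] = [lu[j] for j in keep]
            ep, d_ep = cands[0][1], cands[0][0]
        if l_new > self.max_level:
            self.max_level = l_new
            self.entry_point = i

    # ---- public search ----
    def search(self, query: np.ndarray, k: int, ef: int | None = None):
        """Return (row_ids, distances) of the approximate k nearest neighbors,
        sorted by ascending true (non-squared) Euclidean distance."""
        q = np.ascontiguousarray(query, dtype=np.float32).ravel()
        if q.size != self.vectors.shape[1]:
            raise ValueError(f"query dimension {q.size} != index dimension {self.vectors.shape[1]}")
        ef = max(ef or self.ef_search, k)
        ep, d_ep = self.entry_point, self._dist_one(q, self.entry_point)
        ep, d_ep = self._greedy_descent(q, ep, d_ep, self.max_level, 0)
        found = self._search_layer(q, ep, d_ep, ef, 0)[:k]
        rows = np.array([u for _, u in found], dtype=np.int64)
        dists = np.sqrt(np.array([d for d, _ in found], dtype=np.float64))
        return rows, dists
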