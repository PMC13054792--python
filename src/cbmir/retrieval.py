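"""UID-keyed vector index: exact ranking, score mapping, pairwise tables, ANN.

An index holds one L2-normalized embedding per image instance, keyed by the
DICOM UID triple.  Similarity between a query vector p and an indexed
vector q is the Euclidean distance ``D(p, q) = sqrt(Σ (p_i − q_i)²)``;
results are ranked by ascending D and displayed with the inverse-distance
similarity score ``1 / D`` (capped for near-duplicates so exact copies do
not produce an infinity).

Three query paths are provided, mirroring how a deployed system serves
different situations:

* :func:`query_topk` — exact brute-force ranking; the reference path.
* :meth:`VectorIndex.lookup` — precomputed per-entry neighbor tables for
  images already in the index (intra-database browsing), equivalent to the
  exact path with the entry itself excluded.
* :func:`ann_query` — approximate search over an HNSW graph for unseen
  query images, with the exact path as its recall oracle.

Ties in distance are broken by SOP Instance UID lexicographic order so that
every ranking is deterministic.  The index round-trips through a single
``.npz`` container (documented in :meth:`VectorIndex.save`) bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dicom_io import UIDTriple
from .hnsw import HNSWGraph

__all__ = [
    "FeatureVector",
    "RankedResult",
    "RankedRetrieval",
    "VectorIndex",
    "euclidean_distance",
    "similarity_score",
    "query_topk",
    "precompute_pairwise",
    "ann_query",
    "SCORE_CAP",
    "SCORE_MIN_DISTANCE",
]

SCORE_MIN_DISTANCE = 1e-6
SCORE_CAP = 1e6


@dataclass
class FeatureVector:
    """An embedding with its instance identity; ``label`` is optional at query time."""

    values: np.ndarray
    uids: Optional[UIDTriple] = None
    label: Optional[str] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float32).ravel()
        if v.size == 0 or not np.all(np.isfinite(v)):
            raise ValueError("feature vector must be non-empty and finite")
        self.values = v

    @property
    def dim(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class RankedResult:
    uids: UIDTriple
    distance: float
    score: float
    label: Optional[str]
    relevant: Optional[bool] = None


@dataclass
class RankedRetrieval:
    """Ordered neighbor list for one query."""

    query_uids: Optional[UIDTriple]
    results: list[RankedResult]

    def __post_init__(self):
        d = [r.distance for r in self.results]
        if any(b < a - 1e-9 for a, b in zip(d, d[1:])):
            raise ValueError("distances must be non-decreasing")

    def __len__(self):
        return len(self.results)

    def distances(self) -> np.ndarray:
        return np.array([r.distance for r in self.results])

    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.results]

    def sop_uids(self) -> list[str]:
        return [r.uids.sop_uid for r in self.results]


def euclidean_distance(p: FeatureVector | np.ndarray, q: FeatureVector | np.ndarray) -> float:
    """Standard L2 distance between two equal-dimension feature vectors."""
    pv = p.values if isinstance(p, FeatureVector) else np.asarray(p).ravel()
    qv = q.values if isinstance(q, FeatureVector) else np.asarray(q).ravel()
    if pv.shape != qv.shape:
        raise ValueError(f"dimension mismatch: {pv.shape} vs {qv.shape}")
    return float(np.linalg.norm(pv.astype(np.float64) - qv.astype(np.float64)))


def similarity_score(distance: float) -> float:
    """Inverse-distance display score: ``1 / D``, capped at 1e6 below D = 1e-6.

    The cap is a documented sentinel for exact (or near-exact) duplicates,
    where the reciprocal would diverge.
    """
    if distance < 0:
        raise ValueError(f"distance must be non-negative, got {distance}")
    if distance < SCORE_MIN_DISTANCE:
        return SCORE_CAP
    return 1.0 / distance


class VectorIndex:
    """Set of UID-keyed feature vectors with optional neighbor tables and ANN graph."""

    def __init__(self, entries: Sequence[FeatureVector]):
        if not entries:
            raise ValueError("index requires at least one entry")
        dims = {e.dim for e in entries}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions in index: {sorted(dims)}")
        sops = [e.uids.sop_uid for e in entries]
        if len(set(sops)) != len(sops):
            raise ValueError("duplicate SOP Instance UIDs in index")
        # store in SOP-UID order so the layout itself is deterministic
        order = np.argsort(np.array(sops))
        self.entries: list[FeatureVector] = [entries[i] for i in order]
        self.matrix = np.stack([e.values for e in self.entries]).astype(np.float32)
        self._sop_to_row = {e.uids.sop_uid: i for i, e in enumerate(self.entries)}
        self.neighbor_tables: Optional[list[np.ndarray]] = None  # row ids sorted by distance
        self.neighbor_distances: Optional[list[np.ndarray]] = None
        self.graph: Optional[HNSWGraph] = None

    def __len__(self):
        return len(self.entries)

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, sop_uid: str) -> bool:
        return sop_uid in self._sop_to_row

    def row_of(self, sop_uid: str) -> int:
        return self._sop_to_row[sop_uid]

    # ---- exact ranking ----
    def _ranked_rows(self, qv: np.ndarray, exclude_row: Optional[int] = None) -> tuple[np.ndarray, np.ndarray]:
        diff = self.matrix.astype(np.float64) - qv.astype(np.float64)
        dist = np.sqrt((diff * diff).sum(axis=1))
        rows = np.arange(len(self.entries))
        if exclude_row is not None:
            keep = rows != exclude_row
            rows, dist = rows[keep], dist[keep]
        # stable sort on distance; rows are already in SOP-UID order, so a
        # stable sort breaks exact ties lexicographically by SOP UID
        order = np.argsort(dist, kind="stable")
        return rows[order], dist[order]

    def _to_retrieval(self, query_uids, rows, dists, k: int) -> RankedRetrieval:
        k = min(k, len(rows))
        results = [
            RankedResult(
                uids=self.entries[r].uids,
                distance=float(d),
                score=similarity_score(float(d)),
                label=self.entries[r].label,
            )
            for r, d in zip(rows[:k], dists[:k])
        ]
        return RankedRetrieval(query_uids=query_uids, results=results)

    # ---- pairwise tables ----
    def lookup(self, sop_uid: str, k: int) -> RankedRetrieval:
        """Serve a query for an *indexed* image from the precomputed table."""
        if self.neighbor_tables is None:
            raise RuntimeError("pairwise tables not built; call precompute_pairwise first")
        row = self._sop_to_row[sop_uid]
        rows = self.neighbor_tables[row]
        dists = self.neighbor_distances[row]
        return self._to_retrieval(self.entries[row].uids, rows, dists, k)

    # ---- ANN ----
    def build_ann(self, M: int = 16, ef_construction: int = 200, ef_search: int = 100, seed: int = 0) -> None:
        self.graph = HNSWGraph(self.matrix, M=M, ef_construction=ef_construction, ef_search=ef_search, seed=seed)

    # ---- persistence ----
    def save(self, path: str | Path) -> Path:
        """Write the index as one ``.npz``: dimension, entry count, UID table,
        vectors and (if built) neighbor tables.  The ANN graph is rebuilt on
        load rather than stored."""
        path = Path(path)
        uid_table = np.array(
            [[e.uids.study_uid, e.uids.series_uid, e.uids.sop_uid] for e in self.entries], dtype="U64"
        )
        labels = np.array([e.label or "" for e in self.entries], dtype="U64")
        arrs = dict(
            format=np.array(["cbmir-index-v1"]),
            dim=np.array([self.dim]),
            count=np.array([len(self)]),
            uid_table=uid_table,
            labels=labels,
            vectors=self.matrix,
        )
        if self.neighbor_tables is not None:
            arrs["neighbor_rows"] = np.stack(self.neighbor_tables)
            arrs["neighbor_dists"] = np.stack(self.neighbor_distances)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **arrs)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "VectorIndex":
        with np.load(Path(path)) as z:
            if str(z["format"][0]) != "cbmir-index-v1":
                raise ValueError("not a cbmir index file")
            uid_table, labels, vectors = z["uid_table"], z["labels"], z["vectors"]
            entries = [
                FeatureVector(
                    values=vectors[i],
                    uids=UIDTriple(*[str(u) for u in uid_table[i]]),
                    label=str(labels[i]) or None,
                )
                for i in range(vectors.shape[0])
            ]
            idx = cls(entries)
            if "neighbor_rows" in z:
                idx.neighbor_tables = [r for r in z["neighbor_rows"]]
                idx.neighbor_distances = [d for d in z["neighbor_dists"]]
        return idx

    def export_text(self, path: str | Path) -> Path:
        """Human-inspectable TSV export of the UID table and vectors."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# cbmir index text export; dim={self.dim} count={len(self)}\n")
            fh.write("study_uid\tseries_uid\tsop_uid\tlabel\tvector\n")
            for e in self.entries:
                vec = ",".join(f"{v:.8g}" for v in e.values)
                fh.write(f"{e.uids.study_uid}\t{e.uids.series_uid}\t{e.uids.sop_uid}\t{e.label or ''}\t{vec}\n")
        return path


def query_topk(query: FeatureVector, index: VectorIndex, k: int, exclude_self: bool = True) -> RankedRetrieval:
    """Exact k-nearest neighbors of ``query`` by Euclidean distance.

    If the query itself is an indexed image (same SOP UID) it is excluded
    from its own result list, matching the evaluation design where held-out
    queries are ranked against a disjoint index.  Returns ``min(k, |index|)``
    results.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if query.dim != index.dim:
        raise ValueError(f"query dimension {query.dim} != index dimension {index.dim}")
    exclude_row = None
    if exclude_self and query.uids is not None and query.uids.sop_uid in index:
        exclude_row = index.row_of(query.uids.sop_uid)
    rows, dists = index._ranked_rows(query.values, exclude_row=exclude_row)
    return index._to_retrieval(query.uids, rows, dists, k)


def precompute_pairwise(index: VectorIndex, depth: Optional[int] = None) -> VectorIndex:
    """Precompute per-entry sorted neighbor tables (self excluded).

    Equivalent to storing the full pairwise distance table, but kept as one
    sorted neighbor list per entry so lookups need no recomputation and no
    sorting.  ``depth`` truncates the stored lists (default: full).
    """
    n = len(index)
    if n < 2:
        raise ValueError("pairwise tables require at least 2 entries")
    m = index.matrix.astype(np.float64)
    sq = (m * m).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (m @ m.T)
    np.clip(d2, 0.0, None, out=d2)
    dist = np.sqrt(d2)
    tables, dists = [], []
    keep = depth if depth is not None else n - 1
    for i in range(n):
        rows = np.concatenate([np.arange(0, i), np.arange(i + 1, n)])
        di = dist[i, rows]
        order = np.argsort(di, kind="stable")[:keep]
        tables.append(rows[order].astype(np.int32))
        dists.append(di[order])
    index.neighbor_tables = tables
    index.neighbor_distances = dists
    return index


def ann_query(query: FeatureVector, index: VectorIndex, k: int) -> RankedRetrieval:
    """Approximate k-nearest neighbors via the index's HNSW graph."""
    if index.graph is None:
        raise RuntimeError("ANN graph not built; call index.build_ann() first")
    if query.dim != index.dim:
        raise ValueError(f"query dimension {query.dim} != index dimension {index.dim}")
    rows, dists = index.graph.search(query.values, k)
    return index._to_retrieval(query.uids, rows, dists, k)
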