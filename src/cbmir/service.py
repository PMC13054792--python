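"""Query service and filesystem-backed mock PACS.

The retrieval workflow a radiologist triggers is: the viewer sends one
query request holding the three DICOM UIDs of a displayed instance; the
service fetches that instance from the PACS (WADO-style retrieve),
preprocesses it, embeds it, searches the vector index, and returns the
top-k most similar indexed images with distances and inverse-distance
scores.  Because a single slice rarely tells the whole story, each hit
carries its Study/Series reference so the whole series can be pulled, plus
a note when other slices of that series carry tumor labels.

:class:`MockPacs` is a filesystem-backed stand-in for a DICOMweb server: it
answers QIDO-style instance searches and WADO-style instance retrieval over
the phantom archive (directory of DICOM files + manifest).  It honors the
DICOMweb path shapes (``/studies/{s}/instances``,
``/studies/{s}/series/{r}/instances/{i}``) through :meth:`MockPacs.get`,
and :func:`serve_mock` exposes the same contract over HTTP for manual use.

Indexed query images are served from the precomputed neighbor table when
one is built; unseen images are embedded on the fly and searched with HNSW
when the graph exists (exact search otherwise).  Both paths return the same
hit set for an indexed image, self excluded.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pydicom

from .dicom_io import ImageRecord, UIDTriple, validate_uid
from .phantom import TUMOR_CLASSES, PhantomDataset
from .preprocess import to_model_input
from .retrieval import RankedRetrieval, VectorIndex, ann_query, query_topk

__all__ = [
    "QueryRequest",
    "QueryHit",
    "QueryResponse",
    "NotFoundError",
    "PacsError",
    "MockPacs",
    "retrieve_series",
    "handle_query",
    "serve_mock",
]


class NotFoundError(KeyError):
    """A requested study/series/instance does not exist."""


class PacsError(RuntimeError):
    """The PACS endpoint failed or is unreachable."""


@dataclass(frozen=True)
class QueryRequest:
    uids: UIDTriple
    k: int = 10

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class QueryHit:
    uids: UIDTriple
    distance: float
    score: float
    label: Optional[str]
    series_has_tumor_elsewhere: bool


@dataclass
class QueryResponse:
    status: str
    query_uids: UIDTriple
    hits: list[QueryHit] = field(default_factory=list)

    def __post_init__(self):
        scores = [h.score for h in self.hits]
        if any(b > a + 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("hit scores must be non-increasing")

    def to_json(self) -> str:
        return json.dumps(
            {
                "status": self.status,
                "query": self.query_uids.as_tuple(),
                "hits": [
                    {
                        "study_uid": h.uids.study_uid,
                        "series_uid": h.uids.series_uid,
                        "sop_uid": h.uids.sop_uid,
                        "distance": h.distance,
                        "score": h.score,
                        "label": h.label,
                        "series_has_tumor_elsewhere": h.series_has_tumor_elsewhere,
                    }
                    for h in self.hits
                ],
            },
            indent=2,
        )


class MockPacs:
    """Filesystem-backed PACS honoring QIDO-style search and WADO-style retrieve."""

    def __init__(self, dataset_dir: str | Path):
        self.root = Path(dataset_dir)
        manifest_path = self.root / "manifest.tsv"
        if not manifest_path.exists():
            raise PacsError(f"no manifest at {manifest_path}")
        self.manifest = PhantomDataset.load_manifest(manifest_path)
        self._by_sop = {r.sop_uid: r for r in self.manifest.itertuples()}
        self._series_labels = self.manifest.groupby("series_uid")["label"].agg(set).to_dict()

    # ---- QIDO-style search ----
    def qido_instances(self, study_uid: str, series_uid: Optional[str] = None) -> list[dict]:
        """List instance records of a study (optionally one series).

        Unknown study → empty list (a search with no matches, not an error).
        """
        sel = self.manifest[self.manifest["study_uid"] == study_uid]
        if series_uid is not None:
            sel = sel[sel["series_uid"] == series_uid]
        sel = sel.sort_values("slice_index")
        return [
            dict(
                StudyInstanceUID=r.study_uid,
                SeriesInstanceUID=r.series_uid,
                SOPInstanceUID=r.sop_uid,
                InstanceNumber=int(r.slice_index) + 1,
                PatientID=r.patient_id,
            )
            for r in sel.itertuples()
        ]

    # ---- WADO-style retrieve ----
    def wado_instance(self, uids: UIDTriple) -> bytes:
        row = self._by_sop.get(uids.sop_uid)
        if row is None or row.study_uid != uids.study_uid or row.series_uid != uids.series_uid:
            raise NotFoundError(f"instance not found: {uids}")
        p = Path(row.path)
        if not p.is_absolute():
            p = self.root / p
        if not p.exists():
            raise PacsError(f"manifest references missing file {p}")
        return p.read_bytes()

    # ---- DICOMweb-style path dispatch ----
    def get(self, path: str):
        """Dispatch a DICOMweb-style GET path to search or retrieve."""
        parts = [p for p in path.strip("/").split("/") if p]
        if len(parts) == 3 and parts[0] == "studies" and parts[2] == "instances":
            return self.qido_instances(parts[1])
        if len(parts) == 5 and parts[0] == "studies" and parts[2] == "series" and parts[4] == "instances":
            return self.qido_instances(parts[1], parts[3])
        if len(parts) == 6 and parts[0] == "studies" and parts[2] == "series" and parts[4] == "instances":
            return self.wado_instance(UIDTriple(parts[1], parts[3], parts[5]))
        raise NotFoundError(f"unsupported path: {path}")

    def series_has_tumor_elsewhere(self, series_uid: str, sop_uid: str) -> bool:
        """True when other slices of the series carry a tumor-class label."""
        rows = self.manifest[
            (self.manifest["series_uid"] == series_uid) & (self.manifest["sop_uid"] != sop_uid)
        ]
        return bool(rows["label"].isin(TUMOR_CLASSES).any())


def retrieve_series(study_uid: str, series_uid: str, pacs: MockPacs) -> list[dict]:
    """All SOP instances of a series, ordered by instance number."""
    instances = pacs.qido_instances(study_uid, series_uid)
    if not instances:
        raise NotFoundError(f"series not found: {study_uid}/{series_uid}")
    return sorted(instances, key=lambda r: r["InstanceNumber"])


def _read_record_bytes(blob: bytes) -> ImageRecord:
    ds = pydicom.dcmread(io.BytesIO(blob))
    return ImageRecord(
        pixels=ds.pixel_array.astype(np.uint16, casting="safe"),
        uids=UIDTriple(str(ds.StudyInstanceUID), str(ds.SeriesInstanceUID), str(ds.SOPInstanceUID)),
        patient_id=str(ds.get("PatientID", "")),
    )


def handle_query(
    request: QueryRequest,
    pacs: MockPacs,
    index: VectorIndex,
    model,
) -> QueryResponse:
    """Serve one retrieval query end to end (fetch → embed → search → respond).

    Raises :class:`NotFoundError` for unknown UIDs, :class:`PacsError` when
    the endpoint fails, and :class:`~cbmir.dicom_io.UIDError` for malformed
    UIDs (validated by :class:`QueryRequest` construction).
    """
    for uid in request.uids.as_tuple():
        validate_uid(uid)
    blob = pacs.wado_instance(request.uids)  # NotFoundError propagates, no partial response
    record = _read_record_bytes(blob)

    sop = request.uids.sop_uid
    if sop in index and index.neighbor_tables is not None:
        ranked = index.lookup(sop, request.k)
    else:
        x = to_model_input(record.pixels)
        from .model import extract_feature  # local import avoids a cycle

        feat = extract_feature(model, x, uids=request.uids)
        if sop not in index and index.graph is not None:
            ranked = ann_query(feat, index, request.k)
        else:
            ranked = query_topk(feat, index, request.k, exclude_self=True)

    hits = [
        QueryHit(
            uids=r.uids,
            distance=r.distance,
            score=r.score,
            label=r.label,
            series_has_tumor_elsewhere=pacs.series_has_tumor_elsewhere(r.uids.series_uid, r.uids.sop_uid),
        )
        for r in ranked.results
    ]
    return QueryResponse(status="ok", query_uids=request.uids, hits=hits)


def serve_mock(
    dataset_dir: str | Path,
    port: int = 8042,
    index: Optional[VectorIndex] = None,
    model=None,
    started_callback=None,
):
    """Serve the mock PACS (and, when an index+model are given, the query
    endpoint) over HTTP.

    Routes: GET DICOMweb-style paths as in :meth:`MockPacs.get`; POST
    ``/cbmir/query`` with JSON ``{study_uid, series_uid, sop_uid, k}``.
    Blocks until interrupted; ``started_callback(server)`` fires once bound.
    """
    from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

    pacs = MockPacs(dataset_dir)

    class Handler(BaseHTTPRequestHandler):
        def log_message(self, fmt, *args):  # quiet by default
            pass

        def _send(self, code: int, body: bytes, ctype: str):
            self.send_response(code)
            self.send_header("Content-Type", ctype)
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def do_GET(self):
            try:
                result = pacs.get(self.path)
            except NotFoundError as exc:
                self._send(404, json.dumps({"error": str(exc)}).encode(), "application/json")
                return
            if isinstance(result, bytes):
                self._send(200, result, "application/dicom")
            else:
                self._send(200, json.dumps(result).encode(), "application/json")

        def do_POST(self):
            if self.path != "/cbmir/query" or index is None or model is None:
                self._send(404, b'{"error": "query endpoint not available"}', "application/json")
                return
            length = int(self.headers.get("Content-Length", 0))
            try:
                payload = json.loads(self.rfile.read(length) or b"{}")
                request = QueryRequest(
                    uids=UIDTriple(payload["study_uid"], payload["series_uid"], payload["sop_uid"]),
                    k=int(payload.get("k", 10)),
                )
                response = handle_query(request, pacs, index, model)
            except NotFoundError as exc:
                self._send(404, json.dumps({"error": str(exc)}).encode(), "application/json")
                return
            except (KeyError, ValueError) as exc:
                self._send(400, json.dumps({"error": str(exc)}).encode(), "application/json")
                return
            self._send(200, response.to_json().encode(), "application/json")

    server = ThreadingHTTPServer(("127.0.0.1", port), Handler)
    if started_callback is not None:
        started_callback(server)
    try:
        server.serve_forever()
    finally:
        server.server_close()
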