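"""End-to-end pipeline: generate → split → train → extract → index → evaluate.

This is the orchestration layer the CLI and the reproduction script drive.
The desk-scale study conditions are a phantom archive of 7 classes × 10
patients × ~15 slices (≈ 1,050 images), a patient-disjoint 70/30 split, and
the tiny backbone trained for at most 2,000 iterations on CPU — a scaled
stand-in for the full-size conditions (inception backbone, 150k iterations)
that no desk machine could run.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dicom_io import UIDTriple, read_dicom
from .evaluation import EvalConfig, EvalReport, evaluate_retrieval
from .model import FeatureExtractor, TrainConfig, extract_features, train_model
from .phantom import (
    DEFAULT_CLASS_NAMES,
    PhantomConfig,
    PhantomDataset,
    generate_phantom_dataset,
    split_patients,
)
from .preprocess import to_model_input
from .retrieval import FeatureVector, VectorIndex, ann_query, precompute_pairwise, query_topk

__all__ = [
    "SplitArrays",
    "PipelineResult",
    "prepare_split_arrays",
    "run_end_to_end",
    "ann_recall_at_k",
    "run_dimension_sweep",
]


@dataclass
class SplitArrays:
    """Preprocessed single-plane images plus identifiers for one split."""

    images: np.ndarray  # (N, 224, 224) float32 in [0, 1]
    label_ids: np.ndarray  # int ids into class_names
    labels_text: list[str]
    uids: list[UIDTriple]
    patients: list[str]
    class_names: tuple[str, ...]


def prepare_split_arrays(
    manifest: pd.DataFrame,
    split: str,
    dataset: Optional[PhantomDataset] = None,
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES,
) -> SplitArrays:
    """Load and preprocess every image of one split.

    Pixels come from the in-memory dataset when available, otherwise from
    the DICOM files referenced by the manifest.
    """
    sel = manifest[manifest["split"] == split]
    if sel.empty:
        raise ValueError(f"no rows with split={split!r}")
    by_sop = {}
    if dataset is not None and dataset.records:
        by_sop = {r.uids.sop_uid: r.pixels for r in dataset.records}
    label_to_id = {c: i for i, c in enumerate(class_names)}

    n = len(sel)
    images = np.empty((n, 224, 224), dtype=np.float32)
    label_ids = np.empty(n, dtype=np.int64)
    labels_text, uids, patients = [], [], []
    for i, row in enumerate(sel.itertuples()):
        px = by_sop.get(row.sop_uid)
        if px is None:
            px = read_dicom(row.path).pixels
        images[i] = to_model_input(px)[0]  # channels identical; keep one plane
        label_ids[i] = label_to_id[row.label]
        labels_text.append(row.label)
        uids.append(UIDTriple(row.study_uid, row.series_uid, row.sop_uid))
        patients.append(row.patient_id)
    return SplitArrays(images, label_ids, labels_text, uids, patients, class_names)


@dataclass
class PipelineResult:
    report: EvalReport
    model: FeatureExtractor
    index: VectorIndex
    manifest: pd.DataFrame
    loss_trace: np.ndarray
    test_features: list[FeatureVector] = field(default_factory=list)
    timings: dict = field(default_factory=dict)
    ann_recall: Optional[float] = None

    def summary(self) -> dict:
        out = {
            "overall_mAP": self.report.overall("mAP"),
            "overall_P@10": self.report.overall("P@10"),
            "n_train": len(self.index),
            "n_test": len(self.report.per_query),
            "final_loss": float(np.mean(self.loss_trace[-50:])),
            "initial_loss": float(np.mean(self.loss_trace[:50])),
        }
        if self.ann_recall is not None:
            out["ann_recall@10"] = self.ann_recall
        return out


def ann_recall_at_k(index: VectorIndex, queries: list[FeatureVector], k: int = 10) -> float:
    """Mean fraction of the exact top-k that the HNSW search also returns."""
    if index.graph is None:
        index.build_ann()
    recalls = []
    for q in queries:
        exact = set(query_topk(q, index, k).sop_uids())
        approx = set(ann_query(q, index, k).sop_uids())
        recalls.append(len(exact & approx) / max(len(exact), 1))
    return float(np.mean(recalls))


def run_end_to_end(
    seed: int,
    phantom_config: Optional[PhantomConfig] = None,
    train_config: Optional[TrainConfig] = None,
    eval_config: Optional[EvalConfig] = None,
    train_fraction: float = 0.7,
    out_dir: Optional[str | Path] = None,
    compute_ann_recall: bool = False,
    log_every: int = 0,
) -> PipelineResult:
    """Run the whole pipeline at the desk-scale study conditions.

    ``seed`` drives the phantom, the split, model initialization, batch
    sampling and augmentation; two runs with the same seed are identical.
    """
    timings: dict[str, float] = {}
    t0 = time.time()
    pc = phantom_config or PhantomConfig(seed=seed)
    if pc.seed != seed:
        pc = PhantomConfig(**{**{k: getattr(pc, k) for k in pc.__dataclass_fields__}, "seed": seed})
    write = out_dir is not None
    dataset = generate_phantom_dataset(pc, out_dir=out_dir, write_files=write, keep_pixels=True)
    manifest = split_patients(dataset.manifest, train_fraction, seed=seed + 1)
    timings["generate"] = time.time() - t0

    t0 = time.time()
    train_arrays = prepare_split_arrays(manifest, "train", dataset, pc.class_names)
    test_arrays = prepare_split_arrays(manifest, "test", dataset, pc.class_names)
    dataset.records = []  # free raw pixels
    timings["preprocess"] = time.time() - t0

    t0 = time.time()
    tc = train_config or TrainConfig.desk(seed=seed)
    model, losses = train_model(train_arrays.images, train_arrays.label_ids, tc, log_every=log_every)
    timings["train"] = time.time() - t0

    t0 = time.time()
    train_feats = extract_features(model, train_arrays.images, train_arrays.uids, train_arrays.labels_text)
    test_feats = extract_features(model, test_arrays.images, test_arrays.uids, test_arrays.labels_text)
    index = VectorIndex(train_feats)
    timings["extract"] = time.time() - t0

    t0 = time.time()
    report = evaluate_retrieval(
        test_feats,
        index,
        eval_config or EvalConfig(bootstrap_seed=seed),
        query_patients=test_arrays.patients,
        index_patients=train_arrays.patients,
    )
    timings["evaluate"] = time.time() - t0

    recall = None
    if compute_ann_recall:
        t0 = time.time()
        index.build_ann(seed=seed + 2)
        recall = ann_recall_at_k(index, test_feats, k=10)
        timings["ann"] = time.time() - t0

    return PipelineResult(
        report=report,
        model=model,
        index=index,
        manifest=manifest,
        loss_trace=losses,
        test_features=test_feats,
        timings=timings,
        ann_recall=recall,
    )


def run_dimension_sweep(
    dims: tuple[int, ...] = (64, 128, 256, 512),
    seed: int = 0,
    phantom_config: Optional[PhantomConfig] = None,
    base_train_config: Optional[TrainConfig] = None,
) -> pd.DataFrame:
    """Train and evaluate one model per embedding dimensionality.

    The harness mirrors the embedding-size experiment design: identical data
    and schedule, only the embedding width varies; reports overall mAP and
    P@10 per dimension.
    """
    rows = []
    for dim in dims:
        tc = base_train_config or TrainConfig.desk(seed=seed)
        tc = TrainConfig.from_json(tc.to_json())  # defensive copy
        tc = TrainConfig(**{**tc.__dict__, "embedding_dim": dim, "augment": tc.augment})
        result = run_end_to_end(seed=seed, phantom_config=phantom_config, train_config=tc)
        rows.append(
            dict(embedding_dim=dim, overall_mAP=result.report.overall("mAP"), overall_P10=result.report.overall("P@10"))
        )
    return pd.DataFrame(rows)
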