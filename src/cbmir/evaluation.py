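"""Retrieval and classification evaluation with bootstrap confidence intervals.

Relevance is class-based: a retrieved image is relevant (rel(k) = 1) iff its
class label equals the query's.  The metrics are the standard retrieval
trio:

* ``Precision@k`` — relevant results in the top k, divided by k;
* ``AP`` (average precision) for one query —
  ``Σ_k Precision(k)·rel(k) / R`` over ranks 1..n, where R is the total
  number of relevant images in the index (queries with R = 0 carry no AP
  and are excluded but counted);
* ``mAP`` — the arithmetic mean of AP over all Q queries.

Reports follow the layout of a per-class benchmark table: one row per class
plus an "overall" row, each with a percentile-bootstrap 95% CI over
per-query values.  The evaluation protocol ranks every held-out query
against the full training index (patient-disjoint by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

from .retrieval import FeatureVector, VectorIndex, query_topk

__all__ = [
    "RelevanceJudgment",
    "EvalConfig",
    "EvalReport",
    "precision_at_k",
    "average_precision",
    "mean_average_precision",
    "bootstrap_ci",
    "evaluate_retrieval",
    "classification_report",
    "project_features",
]


@dataclass
class RelevanceJudgment:
    """The binary relevance sequence of one query's ranked results."""

    query_label: str
    result_labels: list[str]

    @property
    def rel(self) -> np.ndarray:
        return np.array([1 if l == self.query_label else 0 for l in self.result_labels], dtype=np.int64)


@dataclass(frozen=True)
class EvalConfig:
    k_list: tuple[int, ...] = (10,)
    depth: Optional[int] = None  # ranking depth n; None = full index
    bootstrap_replicates: int = 2000
    bootstrap_seed: int = 0
    overall_mode: str = "per_query"  # "per_query" | "macro"

    def __post_init__(self):
        if self.bootstrap_replicates < 100:
            raise ValueError("bootstrap_replicates must be >= 100")
        if self.depth is not None and self.depth < max(self.k_list):
            raise ValueError("depth must be >= max(k_list)")
        if self.overall_mode not in ("per_query", "macro"):
            raise ValueError("overall_mode must be 'per_query' or 'macro'")


def precision_at_k(judgment: RelevanceJudgment | np.ndarray, k: int) -> float:
    """Fraction of the top-k results that are relevant."""
    rel = judgment.rel if isinstance(judgment, RelevanceJudgment) else np.asarray(judgment)
    if k < 1 or k > rel.size:
        raise ValueError(f"k={k} outside ranked list of length {rel.size}")
    return float(rel[:k].sum()) / k


def average_precision(
    judgment: RelevanceJudgment | np.ndarray,
    total_relevant: Optional[int] = None,
    depth: Optional[int] = None,
) -> Optional[float]:
    """Average precision of one ranked list.

    ``total_relevant`` (R) defaults to the number of relevant items in the
    list; when the list is a truncation of a larger index, pass the index-wide
    count.  Returns ``None`` for R = 0 (the excluded-query signal).
    """
    rel = judgment.rel if isinstance(judgment, RelevanceJudgment) else np.asarray(judgment)
    if depth is not None:
        rel = rel[:depth]
    R = int(total_relevant) if total_relevant is not None else int(rel.sum())
    if R < 0:
        raise ValueError("total_relevant must be non-negative")
    if R == 0:
        return None
    ranks = np.arange(1, rel.size + 1)
    prec = np.cumsum(rel) / ranks
    return float((prec * rel).sum() / R)


def mean_average_precision(aps: Sequence[float]) -> float:
    """Arithmetic mean of per-query average precisions."""
    aps = [a for a in aps]
    if not aps:
        raise ValueError("mAP requires at least one query")
    return float(np.mean(aps))


def bootstrap_ci(
    values: Sequence[float], replicates: int = 2000, seed: int = 0, level: float = 0.95
) -> tuple[float, float, float]:
    """Percentile bootstrap over per-query values: (low, mean, high)."""
    v = np.asarray(list(values), dtype=np.float64)
    if v.size < 2:
        raise ValueError("bootstrap CI requires at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(replicates, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(v.mean()), float(hi)


@dataclass
class EvalReport:
    """Per-class + overall retrieval metrics with bootstrap CIs."""

    table: pd.DataFrame  # rows: 7 classes + "overall"
    per_query: pd.DataFrame  # query-level label, AP, P@k columns
    excluded_queries: int
    config: EvalConfig

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# cbmir retrieval evaluation; metrics in [0,1]; 95% bootstrap CIs\n")
            self.table.to_csv(fh, sep="\t", index=False)

    def overall(self, metric: str = "mAP") -> float:
        row = self.table[self.table["class"] == "overall"]
        return float(row[metric].iloc[0])


def _ci_cols(values: np.ndarray, replicates: int, seed: int) -> tuple[float, float, float]:
    if values.size >= 2:
        return bootstrap_ci(values, replicates=replicates, seed=seed)
    v = float(values.mean()) if values.size else float("nan")
    return v, v, v


def evaluate_retrieval(
    test_features: Sequence[FeatureVector],
    index: VectorIndex,
    config: EvalConfig = EvalConfig(),
    query_patients: Optional[Sequence[str]] = None,
    index_patients: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Rank every held-out query against the index and aggregate the metrics.

    Each test feature vector is compared with every index vector (exact
    ranking, full depth unless capped) and judged by class-label match.
    Patient identifiers, when given, are asserted disjoint between query and
    index sides — the split-leakage guard.
    """
    if query_patients is not None and index_patients is not None:
        overlap = set(query_patients) & set(index_patients)
        if overlap:
            raise ValueError(f"query and index patient sets overlap: {sorted(overlap)[:5]}")
    if not test_features:
        raise ValueError("no test queries")
    index_labels = np.array([e.label for e in index.entries])
    class_counts = pd.Series(index_labels).value_counts().to_dict()

    depth = config.depth if config.depth is not None else len(index)
    kmax = max(max(config.k_list), 1)
    rows = []
    excluded = 0
    for q in test_features:
        if q.label is None:
            raise ValueError("test features must carry class labels")
        R = class_counts.get(q.label, 0)
        if R == 0:
            excluded += 1
            continue
        ranked = query_topk(q, index, k=depth)
        rel = np.array([1 if r.label == q.label else 0 for r in ranked.results])
        row = {"label": q.label, "AP": average_precision(rel, total_relevant=min(R, depth))}
        for k in config.k_list:
            row[f"P@{k}"] = precision_at_k(rel, min(k, rel.size))
        rows.append(row)
    if not rows:
        raise ValueError("every query class was absent from the index")
    per_query = pd.DataFrame(rows)

    metric_cols = ["AP"] + [f"P@{k}" for k in config.k_list]
    out_rows = []
    classes = sorted(set(index_labels) | set(per_query["label"]))
    for ci, cls in enumerate(classes + ["overall"]):
        if cls == "overall":
            sub = per_query
            if config.overall_mode == "macro":
                sub = per_query.groupby("label")[metric_cols].mean().reset_index()
        else:
            sub = per_query[per_query["label"] == cls]
        row = {"class": cls, "n_queries": int(len(sub)) if cls != "overall" else int(len(per_query))}
        for j, col in enumerate(metric_cols):
            lo, mean, hi = _ci_cols(
                sub[col].to_numpy(dtype=np.float64),
                config.bootstrap_replicates,
                config.bootstrap_seed + 1000 * ci + j,
            )
            name = "mAP" if col == "AP" else col
            row[name], row[f"{name}_lo"], row[f"{name}_hi"] = mean, lo, hi
        out_rows.append(row)
    table = pd.DataFrame(out_rows)
    return EvalReport(table=table, per_query=per_query, excluded_queries=excluded, config=config)


def classification_report(
    predicted: Sequence[str], true: Sequence[str], class_names: Optional[Sequence[str]] = None
) -> dict:
    """Confusion matrix plus one-vs-rest precision / recall / F1 per class.

    The overall row is the per-query (micro-style weighted) mean, matching
    how the retrieval report aggregates.
    """
    predicted, true = list(predicted), list(true)
    if len(predicted) != len(true):
        raise ValueError("predicted and true label sequences differ in length")
    names = list(class_names) if class_names is not None else sorted(set(true) | set(predicted))
    unseen = (set(true) | set(predicted)) - set(names)
    if unseen:
        raise ValueError(f"labels outside the class vocabulary: {sorted(unseen)}")
    cm = _sk_confusion(true, predicted, labels=names)
    prec, rec, f1, support = precision_recall_fscore_support(
        true, predicted, labels=names, zero_division=0.0
    )
    per_class = pd.DataFrame(
        {"class": names, "precision": prec, "recall": rec, "f1": f1, "support": support}
    )
    w = support / max(support.sum(), 1)
    overall = {"precision": float((prec * w).sum()), "recall": float((rec * w).sum()), "f1": float((f1 * w).sum())}
    return {
        "confusion_matrix": pd.DataFrame(cm, index=names, columns=names),
        "per_class": per_class,
        "overall": overall,
    }


def project_features(
    features: np.ndarray | Sequence[FeatureVector],
    perplexity: float = 30.0,
    iterations: int = 1000,
    components: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """t-SNE projection of feature vectors for qualitative inspection only.

    Defaults: 3 components, perplexity 30, 1000 iterations, Euclidean metric.
    """
    from sklearn.manifold import TSNE

    if not isinstance(features, np.ndarray):
        features = np.stack([f.values for f in features])
    n = features.shape[0]
    if n < components + 2:
        raise ValueError(f"need at least {components + 2} points for a {components}-D projection")
    perplexity = min(perplexity, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=components,
        perplexity=perplexity,
        max_iter=iterations,
        metric="euclidean",
        random_state=seed,
        init="random",
    )
    return tsne.fit_transform(features.astype(np.float64))
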