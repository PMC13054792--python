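# cbmir — content-based retrieval for brain-MR slices

`cbmir` is a self-contained content-based medical image retrieval (CBMIR)
stack for axial brain-MR slices, built for people who work on retrieval
inside PACS-like environments: given one DICOM instance (identified by its
Study / Series / SOP Instance UID triple), find the most visually similar
images in an archive, with per-class retrieval quality measured the way
retrieval systems are benchmarked (mAP, Precision@k).

Because clinical brain-MR archives with the relevant class structure are
not publicly distributable, the package ships a **phantom generator** that
emits a realistic-shaped archive as real DICOM files: five tumor classes
(metastasis, glioma, meningioma, pituitary adenoma, vestibular schwannoma),
lesion-free slices from tumor patients ("no tumor contour"), and normal
brains — patients owning multi-slice series, with patient-disjoint
train/test splits.

## The model

An image `x` is embedded by a CNN backbone, generalized-mean pooling and an
embedding head:

* **GeM pooling** over the final W×H×K activation map:
  `f_k = ( 1/|X_k| · Σ_{x∈X_k} x^p )^{1/p}` with fixed `p = 3`
  (p = 1 is average pooling, p → ∞ approaches max pooling);
* **embedding head** FC–BatchNorm–PReLU mapping the K-d descriptor to a
  256-d, L2-normalized retrieval feature;
* training with the **ArcFace** loss — cross-entropy over logits
  `s·cos(θ_j)` with the true class re-margined to `s·cos(θ_y + m)`
  (scale s = 64, additive angular margin m = 38°) — so same-class
  embeddings cluster tightly on the hypersphere and classes separate.

Retrieval ranks indexed features by Euclidean distance
`D(p, q) = √Σ(p_i − q_i)²` and displays the inverse-distance similarity
score `1/D`. Indexed images are served from precomputed neighbor tables;
unseen queries go through a native HNSW approximate search whose recall is
checked against the exact ranking. Everything — phantom, training, search —
is driven by explicit seeds and is bit-reproducible.

The neural-network layers (convolution, BatchNorm, PReLU, GeM, ArcFace)
and the HNSW graph are implemented in numpy inside the package
(`cbmir.nn`, `cbmir.hnsw`), with backward passes verified against finite
differences in the test suite.

## Worked example

Run the whole pipeline — generate a ~1,050-image phantom archive, split it
70/30 by patient, train the CPU-scale backbone, embed both splits, rank
every held-out query against the training index — in one call:

```python
from cbmir.model import TrainConfig
from cbmir.workflow import run_end_to_end

result = run_end_to_end(seed=0, train_config=TrainConfig.desk(seed=0))
print(result.report.table[["class", "mAP", "P@10"]].to_string(index=False))
```

which prints (seed 0, ~4–5 minutes on one CPU):

```
                class      mAP     P@10
               glioma 0.788347 0.818519
           meningioma 0.922952 1.000000
           metastasis 0.880874 0.996154
     no_tumor_contour 0.902774 1.000000
         normal_brain 0.830510 0.970000
    pituitary_adenoma 0.933916 0.971429
vestibular_schwannoma 0.864165 0.972414
              overall 0.882799 0.975000
```

Each row is one image class; `mAP` is the mean over that class's held-out
queries of the average precision of the full ranking (a retrieved image is
relevant iff its class matches the query's), and `P@10` is the fraction of
the top-10 results with the query's class. The `overall` row averages over
all 312 held-out queries. The full report (`result.report.table`) also
carries 95% bootstrap confidence bounds per row.

The same flow is available as a CLI for shell use:

```bash
cbmir generate --out archive/ --patients-per-class 10 --seed 0
cbmir split --manifest archive/manifest.tsv --train-fraction 0.7 --seed 1 --out tagged.tsv
cbmir train --manifest tagged.tsv --preset desk --seed 0 --out model.npz
cbmir extract --checkpoint model.npz --manifest tagged.tsv --split train --out train_feats.npz
cbmir index --features train_feats.npz --out index.npz
cbmir query --data-root archive/ --index index.npz --checkpoint model.npz \
            --study-uid ... --series-uid ... --sop-uid ... -k 10
cbmir serve-mock --data-root archive/ --port 8042   # QIDO/WADO-style mock PACS
```

`cbmir query` returns the top-k hits with raw distances, inverse-distance
scores, class labels, and a note whenever a hit's series contains
tumor-labeled slices elsewhere (a single lesion-free slice of a tumor
patient is not a negative finding — the whole series can be pulled with
`retrieve_series`).

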