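# Methods

`cbmir` implements a content-based image retrieval stack for axial brain-MR
slices: a DICOM phantom archive generator, a deep metric-learning feature
extractor (GeM pooling + ArcFace loss), a UID-keyed vector index with exact
and approximate search, retrieval evaluation with bootstrap confidence
intervals, pairwise similarity heatmaps, and a DICOMweb-style query service
backed by a mock PACS. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic data can and cannot
show.

## Retrieval model

An image is embedded by a convolutional backbone, generalized-mean (GeM)
pooling, and an embedding head, then L2-normalized:

* **Backbone.** Two presets. `googlenet` is a compact inception-style CNN
  (parallel 1×1 / 3×3 / 5×5 branches per block) whose final feature map has
  K = 1024 channels at 7×7 — the configuration the full-scale system targets.
  `tiny` is a 4-block plain CNN (K = 64 by default) for CPU-scale runs;
  every experiment in the test suite uses it. The framework underneath is a
  small numpy layer library with hand-derived backward passes
  (`cbmir.nn`), verified against finite differences in the test suite.
  No pretrained weights are used anywhere; training is always from a seeded
  random initialization.
* **GeM pooling.** Channel k of the pooled descriptor is
  `f_k = (mean_{x in X_k} x^p)^(1/p)` with `p = 3`, fixed and shared across
  channels. `p = 1` recovers average pooling; as `p → ∞` GeM approaches max
  pooling at the power-mean rate `max·ln|X|/p`. Activations are clamped at
  `1e-6` before the power (post-ReLU maps are non-negative; the clamp guards
  fractional powers of numerical noise), and no gradient flows through
  clamped positions.
* **Embedding head.** FC → BatchNorm → PReLU mapping K to 256 dimensions
  (configurable to 64/128/256/512; `run_dimension_sweep` runs the width
  comparison end to end). The *retrieval feature* is the L2-normalized
  256-d output of this head.
* **ArcFace loss.** Cross-entropy over re-margined cosine logits: the
  true-class logit is `s·cos(θ_y + m)`, others `s·cos θ_j`, with scale
  `s = 64` and additive angular margin `m = 38°` (0.6632 rad; the margin is
  specified as a bare number in the source system and is interpreted here
  as degrees, which lands in the conventional ArcFace range). Cosines are
  clamped to `±(1 − 1e-7)` before any arccos; where `θ_y + m` would exceed
  π — the regime where the margined logit stops being monotone — the
  standard easy-margin surrogate `cos θ_y − m·sin m` is used. Class-weight
  rows are re-projected to unit norm after every optimizer step.

Training is single-stage SGD with momentum 0.9. The learning rate ramps
linearly over the first 150 iterations — a margin loss at scale 64 produces
very large early gradients from a random initialization, and the warmup
visibly reduces run-to-run variance — then follows cosine decay to zero.
Defaults: base learning rate 0.01 with the full preset; the desk preset
uses 0.015, weight decay 1e-4, batch 24, 1,100 iterations. Batches are
class-balanced (each slot draws a class uniformly, then an image of that
class) so the large lesion-free class cannot starve the tumor classes.
Augmentation (training split only): horizontal flip p = 0.5, rotation
±15°, isotropic scale 0.9–1.1 — mild, conventional magnitudes; the held-out
split is never augmented. All randomness flows from one integer seed, and
runs are bit-reproducible on a fixed platform.

## Preprocessing

16-bit slices are min–max scaled per image to [0, 1], resized to 224×224
with bilinear interpolation, and stacked into 3 identical channels.
Per-image min–max is used because raw DICOM intensity ranges vary per
acquisition and no windowing metadata is modeled; it makes the input
invariant to positive affine intensity maps. A constant image maps to all
zeros rather than dividing by zero. Optional per-channel standardization
(ImageNet constants) exists for compatibility with pretrained backbones and
is off by default.

## Retrieval and indexing

Similarity is Euclidean distance between embeddings; displayed scores are
the inverse distance `1/D`, capped at `1e6` below `D = 1e-6` (a documented
sentinel for exact duplicates). Three query paths:

* exact brute-force ranking (the reference path; ties broken by SOP
  Instance UID so rankings are deterministic);
* precomputed per-entry sorted neighbor tables for images already indexed
  (equivalent to the full pairwise-distance table, stored as one sorted
  list per entry, self excluded);
* a native HNSW graph for unseen queries (defaults M = 16,
  efConstruction = 200, efSearch = 100; seeded layer assignment, so builds
  are reproducible and searches on a frozen graph deterministic). The exact
  path is the oracle: the regression contract is recall@10 ≥ 0.95.

The index persists as a single `.npz` container (dimension, entry count,
UID table, labels, vectors, optional neighbor tables) and round-trips
bit-exactly; a TSV export exists for inspection.

## Evaluation

A retrieved image is relevant iff its class label equals the query's.
Per query: Precision@k and average precision
`AP = Σ_k P(k)·rel(k) / R` over the full ranking of the index, with R the
index-wide count of same-class images (the ranking depth is configurable;
full depth is the default because the protocol ranks each held-out query
against the entire training index). mAP is the arithmetic mean of AP over
queries. The "overall" row aggregates per-query by default (macro over
classes is available — the choice matters when classes are imbalanced).
Queries whose class is absent from the index carry no AP; they are excluded
and counted. Confidence intervals are percentile bootstrap over per-query
values, 2,000 replicates, seeded. Classification metrics (confusion matrix,
one-vs-rest precision/recall/F1) use the standard definitions via
scikit-learn. t-SNE projection (3 components, perplexity 30, 1,000
iterations, Euclidean) is exposed for qualitative inspection only.

## Similarity heatmaps

For final-layer feature maps A and B, the contribution of position u of A
is `raw_A(u) = ⟨a_u, Σ_v b_v⟩` — the pairwise dot-product decomposition of
the average-pooled descriptor similarity. Its defining identity,
`Σ_u raw_A(u) = W·H·W'·H'·⟨avgpool A, avgpool B⟩`, holds exactly and is
asserted in tests. Negative contributions are clipped and maps are
max-normalized for display; upsampling to image resolution is bilinear and
presentation-only. The decomposition uses average-pooling algebra although
retrieval embeddings are GeM-pooled: the exactness of the testable identity
was preferred over a GeM-weighted variant with no closed-form check. The
maps are qualitative attributions, not gradients of the retrieval distance.

## Phantom archive

No public archive has the seven-class structure this system targets
(five tumor classes, "no tumor contour" slices from tumor patients, and
normal brains, owned by patients with multi-slice series), so the package
generates one as real DICOM Secondary Capture files (16-bit, 512×512,
Modality MR) plus a TSV manifest. Labels and split tags live in the
manifest, never in private DICOM tags.

Class-distinguishing generative rules (chosen once, as the package's
design): pituitary adenomas midline-inferior; vestibular schwannomas at the
lateral-posterior angle; meningiomas against the inner skull table with a
bright rim; gliomas large, irregular, heterogeneous, lateral; metastases
small, sharply rimmed, anywhere, and the only class allowed multiple
lesions (p = 0.5). Lesion-visible slices form a contiguous block (~60% of a
patient's slices), emulating a 3-D lesion sampled by 2-D slices; every
tumor patient has at least one slice with and one without a visible lesion.
Tumor patients additionally carry patient-level cues on *all* their slices:
a mass-effect ventricle displacement away from the lesion side and a faint
diffuse halo (amplitude well below lesion contrast). These cues are what
make "no tumor contour" slices learnably different from normal brains — on
real data the two classes are largely separable for analogous reasons
(mass effect, treatment changes, acquisition context) while remaining the
hardest pair, and the phantom reproduces that ordering. Per-patient
independent random streams are spawned from one master seed, so adding
patients never perturbs earlier ones, and the whole archive is a pure
function of its config.

What the phantom does **not** emulate: MR physics (no k-space, T1/T2
contrast, bias fields), anatomy beyond ellipses-plus-texture, scanner or
protocol variation, or registration errors. Passing the end-to-end test
therefore shows the pipeline is correct and can learn class structure of
this difficulty — not that the model reaches any particular accuracy on
clinical data.

## Study conditions and problem sizes

The desk-scale conditions used by the end-to-end test and the reproduction
script: 7 classes × 10 patients × 13–17 slices (≈ 1,050 images),
patient-disjoint 70/30 split stratified by patient class, tiny backbone,
1,100 training iterations (within the ≤ 2,000-iteration desk budget) at
batch 24. The contract is overall mAP ≥ 0.80 and Precision@10 ≥ 0.85 averaged
over 3 seeds — a property-level stand-in for the full-scale system's
behavior, not a reproduction of any published figure, since the clinical
archive the full-scale numbers come from is private. Unit and property
tests run on smaller phantoms (128 px, 2 patients/class).

## Degenerate inputs and edge rules

* constant image → all-zero model input (documented min–max rule);
* duplicate embeddings → distance 0, score capped at 1e6;
* singleton index → pairwise tables refused; empty index refused;
* a class with a single patient → split refused, naming the class;
* all-zero feature maps → all-zero heatmaps (normalization skipped);
* queries with no relevant image in the index → excluded and counted;
* 8-bit DICOM input → accepted, upcast to 16-bit, original depth recorded.

## Known limitations

* The numpy framework trains small CNNs at useful speed but is not suited
  to the full-size inception preset at 150k iterations; that preset exists
  as configuration and architecture, and is exercised at small iteration
  counts in tests.
* HNSW deletion/re-indexing under concurrent writes is out of scope; the
  graph is rebuilt, not persisted.
* The mock PACS honors QIDO/WADO-style paths for this package's archive
  layout; it is not a general DICOMweb server (no multipart encoding, no
  authentication, no query semantics beyond UID matching).
* Heatmap attribution is average-pool algebra applied to a GeM-pooled
  model; treat the maps as qualitative.
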