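"""Synthetic brain-MR phantom dataset with the structure of a clinical archive.

The retrieval system is designed for a seven-class brain-MR collection:
five tumor classes (metastasis, glioma, meningioma, pituitary adenoma,
vestibular schwannoma), a "no tumor contour" class for slices from tumor
patients on which no lesion is visible, and normal brain scans.  No public
dataset with this exact structure exists, so this module generates one:
real DICOM files, multi-slice series owned by patients, and patient-disjoint
splits, deterministic down to the pixel bytes given a seed.

The generative rules are chosen so that a small CNN has class-separable
structure to learn, qualitatively emulating how the classes differ on real
images:

* **Location priors** — pituitary adenomas sit midline-inferior (sellar
  region), vestibular schwannomas at the lateral-posterior cerebellopontine
  angle, meningiomas against the inner skull table (extra-axial), gliomas
  lateral intra-axial, metastases anywhere.
* **Size, rim and texture** — gliomas are large with irregular margins and
  heterogeneous interiors; meningiomas and metastases are sharply rimmed;
  schwannomas and adenomas are small and round.
* **Multiplicity** — only metastasis patients may carry multiple lesions.
* **Patient-level cues** — tumor patients carry a subtle mass-effect
  ventricle asymmetry and a faint diffuse halo on *all* their slices, so
  their lesion-free slices ("no tumor contour") are distinguishable from
  normal brains while remaining the hardest class to separate — the same
  ordering the class shows in clinical retrieval benchmarks.

A slice is rendered as: smooth head/skull/brain background (per-patient
texture field) + ventricles + class-conditioned lesions + additive Gaussian
noise, in 16-bit intensity units.  The renderer's lesion mask is retained
in memory so tests can verify label consistency against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dicom_io import ImageRecord, UIDGenerator, UIDTriple, write_dicom

__all__ = [
    "PhantomConfig",
    "LesionSpec",
    "PatientProfile",
    "PhantomDataset",
    "TUMOR_CLASSES",
    "NO_CONTOUR",
    "NORMAL",
    "DEFAULT_CLASS_NAMES",
    "plan_patient",
    "render_slice",
    "generate_phantom_dataset",
    "split_patients",
]

TUMOR_CLASSES = (
    "metastasis",
    "glioma",
    "meningioma",
    "pituitary_adenoma",
    "vestibular_schwannoma",
)
NO_CONTOUR = "no_tumor_contour"
NORMAL = "normal_brain"
DEFAULT_CLASS_NAMES = TUMOR_CLASSES + (NO_CONTOUR, NORMAL)

# Intensity layout (16-bit units). Chosen so lesions are bright against brain
# but everything stays far from the uint16 ceiling even with noise.
_I_AIR = 1000.0
_I_SKULL = 22000.0
_I_BRAIN = 12000.0
_I_VENTRICLE = 6500.0
_TEXTURE_AMP = 800.0
_HALO_AMP = 1100.0  # faint tumor-patient cue, well below lesion contrast

# Per-class lesion geometry: radius range as a fraction of the brain
# half-width, intensity contrast, rim contrast, interior heterogeneity.
_CLASS_RULES = {
    "metastasis": dict(rfrac=(0.05, 0.11), contrast=8000.0, rim=2500.0, hetero=0.0),
    "glioma": dict(rfrac=(0.18, 0.28), contrast=4500.0, rim=0.0, hetero=1800.0),
    "meningioma": dict(rfrac=(0.12, 0.20), contrast=7000.0, rim=2800.0, hetero=0.0),
    "pituitary_adenoma": dict(rfrac=(0.08, 0.14), contrast=7000.0, rim=0.0, hetero=0.0),
    "vestibular_schwannoma": dict(rfrac=(0.07, 0.12), contrast=7500.0, rim=0.0, hetero=0.0),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Study-condition knobs for the generated archive."""

    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    patients_per_class: int = 10
    slices_per_patient: tuple[int, int] = (13, 17)
    image_size: int = 512
    bit_depth: int = 16
    lesion_size_range: tuple[int, int] = (10, 60)
    multi_lesion_probability: float = 0.5
    noise_sd: float = 350.0
    lesion_visible_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patients_per_class < 1:
            raise ValueError("patients_per_class must be >= 1")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if not (0.0 <= self.multi_lesion_probability <= 1.0):
            raise ValueError("multi_lesion_probability must be in [0, 1]")
        if not (0.0 < self.lesion_visible_fraction < 1.0):
            raise ValueError("lesion_visible_fraction must be in (0, 1)")
        if self.slices_per_patient[0] < 2 or self.slices_per_patient[0] > self.slices_per_patient[1]:
            raise ValueError("slices_per_patient range must be 2 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.bit_depth != 16:
            raise ValueError("only 16-bit output is supported")

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["class_names"] = list(d["class_names"])
        d["slices_per_patient"] = list(d["slices_per_patient"])
        d["lesion_size_range"] = list(d["lesion_size_range"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomConfig":
        d = json.loads(text)
        d["class_names"] = tuple(d["class_names"])
        d["slices_per_patient"] = tuple(d["slices_per_patient"])
        d["lesion_size_range"] = tuple(d["lesion_size_range"])
        return cls(**d)


@dataclass(frozen=True)
class LesionSpec:
    """One lesion: center in normalized brain coordinates, radius in pixels."""

    center: tuple[float, float]  # (x, y), brain-relative, |.| < 1
    radius: float  # pixels at the configured image size
    contrast: float  # added intensity at lesion core
    rim_contrast: float
    hetero_amp: float
    texture_seed: int
    laterality: str  # "L" | "R" | "C"
    irregularity: float = 0.0  # angular boundary perturbation (gliomas)


@dataclass
class PatientProfile:
    """Everything needed to render every slice of one patient deterministically."""

    patient_id: str
    tumor_class: str  # one of DEFAULT_CLASS_NAMES
    lesion_specs: list[LesionSpec]
    slice_plan: list[bool]  # lesion visibility per slice
    brain_scale: float  # patient head size factor
    ventricle_shift: tuple[float, float]  # mass-effect cue (tumor patients)
    texture_seed: int
    noise_key: int  # per-patient key for per-slice noise streams

    @property
    def n_slices(self) -> int:
        return len(self.slice_plan)

    def slice_label(self, slice_index: int) -> str:
        if self.tumor_class == NORMAL:
            return NORMAL
        if self.tumor_class == NO_CONTOUR:
            return NO_CONTOUR
        return self.tumor_class if self.slice_plan[slice_index] else NO_CONTOUR


def _sample_lesion(tumor_class: str, rng: np.random.Generator, config: PhantomConfig) -> LesionSpec:
    rules = _CLASS_RULES[tumor_class]
    half_width = 0.40 * config.image_size  # brain ellipse semi-axis, roughly
    lo = max(rules["rfrac"][0] * half_width, config.lesion_size_range[0])
    hi = min(rules["rfrac"][1] * half_width, config.lesion_size_range[1])
    hi = max(hi, lo + 1.0)
    radius = float(rng.uniform(lo, hi))
    side = rng.choice([-1.0, 1.0])

    if tumor_class == "pituitary_adenoma":
        center = (float(rng.normal(0.0, 0.03)), float(rng.uniform(0.52, 0.66)))
        laterality = "C"
    elif tumor_class == "vestibular_schwannoma":
        center = (float(side * rng.uniform(0.38, 0.52)), float(rng.uniform(0.25, 0.42)))
        laterality = "L" if side < 0 else "R"
    elif tumor_class == "meningioma":
        theta = float(rng.uniform(0, 2 * np.pi))
        rho = float(rng.uniform(0.72, 0.82))  # hugging the inner skull table
        center = (rho * np.cos(theta), rho * np.sin(theta))
        laterality = "C" if abs(center[0]) < 0.1 else ("L" if center[0] < 0 else "R")
    elif tumor_class == "glioma":
        center = (float(side * rng.uniform(0.25, 0.45)), float(rng.uniform(-0.35, 0.25)))
        laterality = "L" if side < 0 else "R"
    else:  # metastasis: anywhere in the brain
        theta = float(rng.uniform(0, 2 * np.pi))
        rho = float(0.65 * np.sqrt(rng.uniform(0, 1)))
        center = (rho * np.cos(theta), rho * np.sin(theta))
        laterality = "C" if abs(center[0]) < 0.1 else ("L" if center[0] < 0 else "R")

    return LesionSpec(
        center=center,
        radius=radius,
        contrast=rules["contrast"],
        rim_contrast=rules["rim"],
        hetero_amp=rules["hetero"],
        texture_seed=int(rng.integers(0, 2**31 - 1)),
        laterality=laterality,
        irregularity=0.35 if tumor_class == "glioma" else 0.08,
    )


def plan_patient(
    patient_id: str,
    tumor_class: str,
    config: PhantomConfig,
    rng: np.random.Generator,
    n_slices: Optional[int] = None,
) -> PatientProfile:
    """Sample a patient's lesions, per-slice visibility plan and nuisance params.

    Tumor-class patients get a contiguous block of lesion-visible slices
    (a 3-D lesion sampled by 2-D slices) with at least one visible and at
    least one lesion-free slice.  "No tumor contour" patients are tumor
    patients imaged away from their lesion: they carry the tumor-patient
    cues but no slice shows a lesion.  Normal patients have no lesions and
    no cues.
    """
    if n_slices is None:
        n_slices = int(rng.integers(config.slices_per_patient[0], config.slices_per_patient[1] + 1))

    is_tumor_patient = tumor_class != NORMAL
    lesions: list[LesionSpec] = []
    if tumor_class in TUMOR_CLASSES:
        n_lesions = 1
        if tumor_class == "metastasis" and rng.uniform() < config.multi_lesion_probability:
            n_lesions = int(rng.integers(2, 5))
        lesions = [_sample_lesion(tumor_class, rng, config) for _ in range(n_lesions)]
        n_visible = int(np.clip(round(config.lesion_visible_fraction * n_slices), 1, n_slices - 1))
        start = int(rng.integers(0, n_slices - n_visible + 1))
        plan = [start <= i < start + n_visible for i in range(n_slices)]
    else:
        plan = [False] * n_slices
        if tumor_class == NO_CONTOUR:
            # an off-slice lesion drives the halo cue but is never rendered
            proxy_class = str(rng.choice(TUMOR_CLASSES))
            lesions = [_sample_lesion(proxy_class, rng, config)]

    if is_tumor_patient:
        shift = (float(rng.uniform(-0.07, 0.07)), float(rng.uniform(-0.05, 0.05)))
        # mass effect pushes ventricles away from the lesion side
        if lesions and abs(lesions[0].center[0]) > 0.05:
            shift = (-np.sign(lesions[0].center[0]) * abs(shift[0]) - 0.03, shift[1])
    else:
        shift = (float(rng.uniform(-0.01, 0.01)), float(rng.uniform(-0.01, 0.01)))

    return PatientProfile(
        patient_id=patient_id,
        tumor_class=tumor_class,
        lesion_specs=lesions,
        slice_plan=plan,
        brain_scale=float(rng.uniform(0.92, 1.05)),
        ventricle_shift=shift,
        texture_seed=int(rng.integers(0, 2**31 - 1)),
        noise_key=int(rng.integers(0, 2**31 - 1)),
    )


def _coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    ax = np.linspace(-1.0, 1.0, n, dtype=np.float32)
    return np.meshgrid(ax, ax)  # X (columns), Y (rows; +y is inferior/down)


def _patient_texture(profile: PatientProfile, n: int) -> np.ndarray:
    """Smooth per-patient intensity texture (cortical/white-matter variation)."""
    rng = np.random.default_rng(profile.texture_seed)
    m = -(-n // 8)  # ceil
    small = rng.normal(0.0, 1.0, size=(m, m))
    tex = gaussian_filter(small, sigma=2.0)
    tex = np.kron(tex, np.ones((8, 8)))[:n, :n]  # cheap upsample; re-smooth below
    tex = gaussian_filter(tex, sigma=4.0)
    tex /= max(np.abs(tex).max(), 1e-9)
    return (_TEXTURE_AMP * tex).astype(np.float32)


from functools import lru_cache


@lru_cache(maxsize=64)
def _lesion_texture(seed: int, n: int) -> np.ndarray:
    """Smooth intra-lesion heterogeneity field (pure function of seed, cached)."""
    rng = np.random.default_rng(seed)
    het = gaussian_filter(rng.normal(0, 1, size=(n, n)).astype(np.float32), 6.0)
    het /= max(np.abs(het).max(), 1e-9)
    return het


@dataclass
class RenderedSlice:
    image: np.ndarray  # uint16, (n, n)
    lesion_mask: np.ndarray  # bool, (n, n); True where a lesion was drawn


def render_slice(
    profile: PatientProfile,
    slice_index: int,
    config: PhantomConfig,
    rng: Optional[np.random.Generator] = None,
    texture: Optional[np.ndarray] = None,
) -> RenderedSlice:
    """Render one axial slice of a patient as a 16-bit image plus lesion mask.

    Deterministic: the per-slice noise stream is derived from the patient's
    ``noise_key`` and the slice index unless an explicit ``rng`` is given.
    """
    if not (0 <= slice_index < profile.n_slices):
        raise IndexError(f"slice_index {slice_index} outside plan of {profile.n_slices}")
    n = config.image_size
    if rng is None:
        rng = np.random.default_rng([profile.noise_key, slice_index])
    X, Y = _coords(n)

    # superior-inferior position modulates head cross-section size
    t = slice_index / max(profile.n_slices - 1, 1)
    depth = 0.78 + 0.22 * np.sin(np.pi * (0.2 + 0.6 * t))
    a = 0.80 * profile.brain_scale * depth  # lateral semi-axis
    b = 0.92 * profile.brain_scale * depth  # anterior-posterior semi-axis

    r2 = (X / a) ** 2 + (Y / b) ** 2
    head = r2 <= 1.0
    brain = r2 <= 0.88**2

    img = np.full((n, n), _I_AIR, dtype=np.float32)
    img[head] = _I_SKULL
    img[brain] = _I_BRAIN
    tex = texture if texture is not None else _patient_texture(profile, n)
    img[brain] += tex[brain]

    # lateral ventricles: two dark slanted ellipses near midline, shifted by
    # the patient's mass-effect cue
    vx, vy = profile.ventricle_shift
    for sx in (-1.0, 1.0):
        cx, cy = sx * 0.14 + vx, -0.05 + vy
        vr = ((X - cx) / (0.085 * depth)) ** 2 + ((Y - cy) / (0.26 * depth)) ** 2
        vent = (vr <= 1.0) & brain
        img[vent] = _I_VENTRICLE

    mask = np.zeros((n, n), dtype=bool)
    half_width = a  # brain semi-axis in normalized units
    for spec in profile.lesion_specs:
        cx = spec.center[0] * half_width * 0.88
        cy = spec.center[1] * b * 0.88
        rad = spec.radius / (n / 2)  # pixels -> normalized units
        dist = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
        if spec.irregularity > 0:
            ang = np.arctan2(Y - cy, X - cx)
            lrng = np.random.default_rng(spec.texture_seed)
            ph = lrng.uniform(0, 2 * np.pi, size=3)
            wob = 1.0 + spec.irregularity * (
                0.6 * np.sin(3 * ang + ph[0]) + 0.3 * np.sin(5 * ang + ph[1]) + 0.2 * np.sin(7 * ang + ph[2])
            )
        else:
            wob = 1.0
        eff_rad = rad * wob

        # faint halo on every slice of a tumor patient (edema / treatment cue)
        halo = _HALO_AMP * np.exp(-(dist**2) / (2 * (1.8 * rad) ** 2))
        img[brain] += halo[brain]

        if profile.slice_plan[slice_index]:
            core = (dist <= eff_rad) & brain
            img[core] += spec.contrast
            if spec.hetero_amp > 0:
                het = _lesion_texture(spec.texture_seed + 1, n)
                img[core] += spec.hetero_amp * het[core]
            if spec.rim_contrast > 0:
                rim = (dist <= eff_rad * 1.18) & (dist > eff_rad * 0.92) & brain
                img[rim] += spec.rim_contrast
                core = core | rim
            mask |= core

    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=(n, n)).astype(np.float32)

    np.clip(img, 0, 2**16 - 1, out=img)
    return RenderedSlice(image=img.astype(np.uint16), lesion_mask=mask)


MANIFEST_COLUMNS = [
    "patient_id",
    "study_uid",
    "series_uid",
    "sop_uid",
    "path",
    "label",
    "split",
    "slice_index",
    "patient_class",
]


@dataclass
class PhantomDataset:
    """A generated archive: manifest + profiles + (optionally) in-memory records.

    ``lesion_masks`` maps SOP Instance UID to the renderer's boolean lesion
    mask (bit-packed) for every slice on which a lesion was drawn; tests use
    it as ground truth for label consistency and heatmap localization.
    """

    config: PhantomConfig
    manifest: pd.DataFrame
    profiles: dict[str, PatientProfile]
    records: list[ImageRecord] = field(default_factory=list)
    lesion_masks: dict[str, np.ndarray] = field(default_factory=dict)  # packed bits

    def lesion_mask(self, sop_uid: str) -> Optional[np.ndarray]:
        packed = self.lesion_masks.get(sop_uid)
        if packed is None:
            return None
        n = self.config.image_size
        return np.unpackbits(packed)[: n * n].reshape(n, n).astype(bool)

    def save_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# cbmir phantom manifest v1; tab-separated\n")
            fh.write("# label vocabulary: " + ",".join(self.config.class_names) + "\n")
            self.manifest.to_csv(fh, sep="\t", index=False)
        return path

    @staticmethod
    def load_manifest(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", comment="#", dtype={"patient_id": str})


def generate_phantom_dataset(
    config: PhantomConfig,
    out_dir: Optional[str | Path] = None,
    write_files: bool = True,
    keep_pixels: bool = False,
    keep_masks: bool = True,
) -> PhantomDataset:
    """Generate the full phantom archive.

    One patient per (class, index) pair, one study/series per patient, one
    DICOM file per slice.  Per-slice labels: the patient's tumor class when
    the lesion is visible on that slice, "no tumor contour" when the patient
    has a tumor but the slice shows none, "normal brain" for normal patients.
    Deterministic given ``config.seed``: each patient has an independent
    random stream spawned from the master seed, so adding patients does not
    perturb earlier ones.
    """
    if write_files and out_dir is None:
        raise ValueError("out_dir is required when write_files=True")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    patient_classes = [c for c in config.class_names]
    n_patients = len(patient_classes) * config.patients_per_class
    master = np.random.SeedSequence(config.seed)
    patient_seeds = master.spawn(n_patients)
    uid_gen = UIDGenerator(seed=int(master.generate_state(1)[0] % (2**31)))

    rows = []
    profiles: dict[str, PatientProfile] = {}
    records: list[ImageRecord] = []
    masks: dict[str, np.ndarray] = {}

    idx = 0
    for cls in patient_classes:
        for p in range(config.patients_per_class):
            rng = np.random.default_rng(patient_seeds[idx])
            patient_id = f"PH{idx:04d}"
            profile = plan_patient(patient_id, cls, config, rng)
            profiles[patient_id] = profile
            study_uid = uid_gen()
            series_uid = uid_gen()
            texture = _patient_texture(profile, config.image_size)

            for s in range(profile.n_slices):
                rendered = render_slice(profile, s, config, texture=texture)
                uids = UIDTriple(study_uid, series_uid, uid_gen())
                label = profile.slice_label(s)
                record = ImageRecord(
                    pixels=rendered.image,
                    uids=uids,
                    patient_id=patient_id,
                    label=label,
                    split="unassigned",
                    instance_number=s + 1,
                )
                fpath = ""
                if write_files and out_dir is not None:
                    fpath = str(out_dir / patient_id / f"slice_{s:03d}.dcm")
                    write_dicom(record, fpath)
                if keep_pixels:
                    records.append(record)
                if keep_masks and rendered.lesion_mask.any():
                    masks[uids.sop_uid] = np.packbits(rendered.lesion_mask)
                rows.append(
                    dict(
                        patient_id=patient_id,
                        study_uid=study_uid,
                        series_uid=series_uid,
                        sop_uid=uids.sop_uid,
                        path=fpath,
                        label=label,
                        split="unassigned",
                        slice_index=s,
                        patient_class=cls,
                    )
                )
            idx += 1

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if manifest["sop_uid"].duplicated().any():
        raise RuntimeError("UID collision in generated manifest")  # pragma: no cover
    ds = PhantomDataset(config=config, manifest=manifest, profiles=profiles, records=records, lesion_masks=masks)
    if out_dir is not None:
        ds.save_manifest(out_dir / "manifest.tsv")
        (out_dir / "phantom_config.json").write_text(config.to_json())
    return ds


def split_patients(manifest: pd.DataFrame, train_fraction: float, seed: int) -> pd.DataFrame:
    """Assign patient-disjoint train/test tags, stratified by patient class.

    All of a patient's images share one tag; per-class patient counts follow
    the fraction up to rounding, with both splits guaranteed non-empty per
    class.  Returns a new manifest; the input is not modified.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = "unassigned"

    pat = manifest[["patient_id", "patient_class"]].drop_duplicates()
    for cls, grp in pat.groupby("patient_class", sort=True):
        pids = sorted(grp["patient_id"].tolist())
        if len(pids) < 2:
            raise ValueError(
                f"class {cls!r} has {len(pids)} patient(s); at least 2 are needed "
                "for a patient-disjoint train/test split"
            )
        n_train = int(round(train_fraction * len(pids)))
        n_train = min(max(n_train, 1), len(pids) - 1)
        perm = rng.permutation(len(pids))
        train_ids = {pids[i] for i in perm[:n_train]}
        sel = out["patient_id"].isin(pids)
        out.loc[sel, "split"] = [
            "train" if pid in train_ids else "test" for pid in out.loc[sel, "patient_id"]
        ]
    return out
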