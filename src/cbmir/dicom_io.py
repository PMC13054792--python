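"""Reading and writing single-frame grayscale DICOM files, plus UID handling.

Every image instance in a PACS is identified by a *UID triple* — Study
Instance UID, Series Instance UID and SOP Instance UID — and the retrieval
system keys everything (feature vectors, index entries, query requests) by
that triple.  This module provides a minimal, standards-correct layer on top
of :mod:`pydicom`:

* :func:`write_dicom` produces DICOM Part 10 files using the Secondary
  Capture SOP class with Explicit VR Little Endian transfer syntax,
  MONOCHROME2 photometric interpretation and 16 bits allocated.  Secondary
  Capture is used instead of MR Image Storage so that files stay conformant
  without fabricating MR acquisition modules the phantom cannot honestly
  populate; the Modality tag is still ``MR``.
* :func:`read_dicom` reads such a file back into an :class:`ImageRecord`.
* :class:`UIDGenerator` draws well-formed, collision-free UIDs from a seeded
  stream so that a generated dataset is bit-reproducible.

Class labels and train/test split tags deliberately do **not** live inside
the DICOM files; they travel in the dataset manifest (see
:mod:`cbmir.phantom`), keeping the files standard and the label schema
versionable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

__all__ = [
    "UIDTriple",
    "ImageRecord",
    "UIDGenerator",
    "validate_uid",
    "write_dicom",
    "read_dicom",
]

# DICOM PS3.5: UID components are non-negative integers, dot separated,
# no leading zeros (a lone "0" component is allowed), 64 chars max.
_UID_RE = re.compile(r"^(0|[1-9][0-9]*)(\.(0|[1-9][0-9]*))*$")

#: Organisational root used for generated UIDs (pydicom's registered root).
DEFAULT_UID_ROOT = "1.2.826.0.1.3680043.8.498"


class UIDError(ValueError):
    """Raised for malformed DICOM UIDs."""


def validate_uid(uid: str) -> str:
    """Return ``uid`` if it is a well-formed DICOM UID, else raise UIDError."""
    if not isinstance(uid, str) or not uid:
        raise UIDError(f"UID must be a non-empty string, got {uid!r}")
    if len(uid) > 64:
        raise UIDError(f"UID exceeds 64 characters ({len(uid)}): {uid!r}")
    if not _UID_RE.match(uid):
        raise UIDError(f"UID is not dot-decimal with no leading zeros: {uid!r}")
    return uid


@dataclass(frozen=True, order=True)
class UIDTriple:
    """Study / Series / SOP Instance UIDs jointly identifying one image."""

    study_uid: str
    series_uid: str
    sop_uid: str

    def __post_init__(self) -> None:
        for uid in (self.study_uid, self.series_uid, self.sop_uid):
            validate_uid(uid)

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.study_uid, self.series_uid, self.sop_uid)

    def __str__(self) -> str:  # compact, log-friendly
        return f"{self.study_uid}/{self.series_uid}/{self.sop_uid}"


@dataclass
class ImageRecord:
    """One DICOM slice: pixel array plus the identifiers the system keys on.

    ``label`` and ``split`` come from the dataset manifest, never from the
    DICOM file itself; records read from disk have them unassigned.
    """

    pixels: np.ndarray
    uids: UIDTriple
    patient_id: str
    label: Optional[str] = None
    split: str = "unassigned"
    instance_number: int = 1
    source_bit_depth: int = 16
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        self.pixels = px

    def with_label(self, label: str, split: str) -> "ImageRecord":
        return replace(self, label=label, split=split)


class UIDGenerator:
    """Deterministic DICOM UID factory.

    Draws dot-decimal UIDs under :data:`DEFAULT_UID_ROOT` from a seeded
    counter + random-suffix scheme; the same seed always yields the same
    sequence, and uniqueness holds for the generator's lifetime because the
    counter is strictly increasing.
    """

    def __init__(self, seed: int, root: str = DEFAULT_UID_ROOT):
        validate_uid(root)
        self._rng = np.random.default_rng(seed)
        self._root = root
        self._counter = 0

    def __call__(self) -> str:
        self._counter += 1
        suffix = int(self._rng.integers(1, 10**9))
        uid = f"{self._root}.{self._counter}.{suffix}"
        # root is 25 chars; counter+suffix keep us well under 64
        return validate_uid(uid)

    def triple(self, study_uid: Optional[str] = None, series_uid: Optional[str] = None) -> UIDTriple:
        """Draw a triple, optionally reusing an existing study/series UID."""
        return UIDTriple(
            study_uid=study_uid or self(),
            series_uid=series_uid or self(),
            sop_uid=self(),
        )


def write_dicom(record: ImageRecord, path: str | Path) -> Path:
    """Write ``record`` as a DICOM Part 10 Secondary Capture file.

    The pixel array must be unsigned 16-bit (or safely castable); values are
    stored bit-exactly with Explicit VR Little Endian transfer syntax.
    """
    path = Path(path)
    for uid in record.uids.as_tuple():
        validate_uid(uid)

    px = np.asarray(record.pixels)
    if px.dtype != np.uint16:
        if not np.issubdtype(px.dtype, np.integer):
            raise TypeError(f"pixel dtype must be integer, got {px.dtype}")
        if px.min() < 0 or px.max() > 0xFFFF:
            raise ValueError("pixel values out of uint16 range")
        px = px.astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = record.uids.sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = record.uids.sop_uid
    ds.StudyInstanceUID = record.uids.study_uid
    ds.SeriesInstanceUID = record.uids.series_uid
    ds.PatientID = record.patient_id
    ds.PatientName = record.patient_id
    ds.Modality = "MR"
    ds.ConversionType = "SYN"  # synthesized image (Secondary Capture attribute)
    ds.InstanceNumber = int(record.instance_number)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = px.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0  # unsigned
    ds.PixelData = px.tobytes()

    path.parent.mkdir(parents=True, exist_ok=True)
    ds.save_as(path, enforce_file_format=True)
    return path


def read_dicom(path: str | Path) -> ImageRecord:
    """Read a single-frame grayscale DICOM file into an :class:`ImageRecord`.

    8-bit files are accepted and upcast to uint16 (a pure dtype widening —
    stored values are preserved, so intensity statistics are unchanged); the
    original bit depth is recorded in ``source_bit_depth``.  Label and split
    are left unassigned, as they belong to the manifest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ds = pydicom.dcmread(path)  # raises InvalidDicomError on non-DICOM input

    missing = [t for t in ("StudyInstanceUID", "SeriesInstanceUID", "SOPInstanceUID") if t not in ds]
    if missing:
        raise KeyError(f"DICOM file {path} lacks required UID tags: {missing}")

    px = ds.pixel_array
    if px.ndim != 2:
        raise ValueError(f"expected a single-frame 2-D image, got shape {px.shape}")
    source_bits = int(ds.get("BitsAllocated", 16))
    px = px.astype(np.uint16, casting="safe") if px.dtype != np.uint16 else px

    return ImageRecord(
        pixels=px,
        uids=UIDTriple(str(ds.StudyInstanceUID), str(ds.SeriesInstanceUID), str(ds.SOPInstanceUID)),
        patient_id=str(ds.get("PatientID", "")),
        instance_number=int(ds.get("InstanceNumber", 1) or 1),
        source_bit_depth=source_bits,
    )
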