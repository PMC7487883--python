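"""Image and manifest I/O plus the shared domain types used by every stage.

IHC images are 8-bit RGB brightfield micrographs of antibody-stained tissue:
the target protein appears brown (DAB) and nuclear DNA purple (hematoxylin).
Datasets are described by a CSV manifest with one row per image carrying the
protein identity, the tissue state (normal or cancer) and, when known, the
subcellular location label:

    i   — nucleus
    ii  — cytoplasm and plasma membrane
    iii — nucleus and cytoplasm and plasma membrane

All pixel coordinates in the package are 0-based, row-major; square windows
are half-open, ``[r0, r0+s) x [c0, c0+s)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

VALID_STATES = ("normal", "cancer")
VALID_LABELS = ("i", "ii", "iii", "unknown")
#: manifest label -> integer class index (order fixed: i, ii, iii)
LABEL_TO_INT = {"i": 0, "ii": 1, "iii": 2}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}

MANIFEST_COLUMNS = ("protein_id", "image_path", "tissue_state", "label")


class ManifestFormatError(ValueError):
    """Raised when a manifest CSV is malformed (missing column, bad value)."""


class ManifestValidationError(ValueError):
    """Raised when manifest contents violate dataset invariants."""


class ImageFormatError(ValueError):
    """Raised when an image file cannot be used as an RGB IHC image."""


@dataclass
class IHCImage:
    """An 8-bit RGB IHC image with its manifest metadata."""

    pixels: np.ndarray
    protein_id: str = ""
    tissue_state: str = ""
    label: str = "unknown"
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageFormatError(
                f"IHCImage requires an HxWx3 RGB array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ImageFormatError("empty image")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ImageFormatError("pixel values outside [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.label not in VALID_LABELS:
            raise ManifestValidationError(f"invalid label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class ManifestRecord:
    protein_id: str
    image_path: str
    tissue_state: str
    label: str


@dataclass
class DatasetManifest:
    """Ordered image records grouped by protein.

    A protein may (and, for biomarker screening, must) have images in both
    tissue states; typically a handful of normal images and more cancer
    images per protein.
    """

    records: list[ManifestRecord] = field(default_factory=list)
    groups: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups and self.records:
            self.rebuild_groups()

    def rebuild_groups(self) -> None:
        self.groups = {}
        for idx, rec in enumerate(self.records):
            self.groups.setdefault(rec.protein_id, []).append(idx)

    def validate(self) -> None:
        paths = [r.image_path for r in self.records]
        if len(set(paths)) != len(paths):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ManifestValidationError(f"duplicate image_path entries: {dupes}")
        for rec in self.records:
            if not rec.protein_id:
                raise ManifestValidationError("empty protein_id")
            if rec.tissue_state not in VALID_STATES:
                raise ManifestValidationError(
                    f"invalid tissue_state {rec.tissue_state!r} (expected normal|cancer)"
                )
            if rec.label not in VALID_LABELS:
                raise ManifestValidationError(
                    f"invalid label {rec.label!r} (expected i|ii|iii|unknown)"
                )

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, indices) -> "DatasetManifest":
        m = DatasetManifest(records=[self.records[i] for i in indices])
        m.rebuild_groups()
        return m


@dataclass
class StainBasis:
    """2x3 matrix of unit-norm stain color vectors in optical-density space.

    Row order is fixed: row 0 = hematoxylin (DNA), row 1 = DAB (protein).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"stain basis must be 2x3, got {m.shape}")
        if (m < 0).any():
            raise ValueError("stain basis entries must be non-negative")
        norms = np.linalg.norm(m, axis=1)
        if (norms == 0).any():
            raise ValueError("stain basis rows must be nonzero")
        m = m / norms[:, None]
        gram = m @ m.T
        if abs(np.linalg.det(gram)) < 1e-12:
            raise ValueError("stain basis rows are linearly dependent")
        self.matrix = m

    @property
    def dna_row(self) -> np.ndarray:
        return self.matrix[0]

    @property
    def protein_row(self) -> np.ndarray:
        return self.matrix[1]

    @classmethod
    def from_csv(cls, path) -> "StainBasis":
        m = np.loadtxt(path, delimiter=",")
        return cls(matrix=m)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter=",", fmt="%.10f")


def load_manifest(path) -> DatasetManifest:
    """Read a dataset manifest CSV.

    Expected header: ``protein_id,image_path,tissue_state,label``. The
    tissue_state and label columns are case-folded; label may be empty
    (stored as ``unknown``). Relative image paths are kept as written.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in MANIFEST_COLUMNS:
            if col not in header:
                raise ManifestFormatError(f"manifest missing required column {col!r}")
        records = []
        for row in reader:
            label = (row["label"] or "unknown").strip().lower() or "unknown"
            records.append(
                ManifestRecord(
                    protein_id=row["protein_id"].strip(),
                    image_path=row["image_path"].strip(),
                    tissue_state=row["tissue_state"].strip().lower(),
                    label=label,
                )
            )
    manifest = DatasetManifest(records=records)
    manifest.validate()
    manifest.rebuild_groups()
    return manifest


def write_manifest(manifest: DatasetManifest, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for rec in manifest.records:
            writer.writerow([rec.protein_id, rec.image_path, rec.tissue_state, rec.label])


def read_image(path, *, protein_id: str = "", tissue_state: str = "",
               label: str = "unknown") -> IHCImage:
    """Read a PNG/TIFF/JPEG file as an 8-bit RGB :class:`IHCImage`.

    Grayscale files are rejected: stain unmixing needs three color channels.
    16-bit inputs are rescaled to 8-bit by division by the dtype maximum.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        # tifffile preserves bit depth; PIL silently truncates 16-bit RGB
        import tifffile

        try:
            arr = tifffile.imread(path)
        except Exception as exc:
            raise OSError(f"cannot read image {path}: {exc}") from exc
        if arr.ndim == 2:
            raise ImageFormatError(
                f"{path.name}: grayscale image; stain unmixing needs 3 channels")
        return _finalize_image(arr, path, protein_id, tissue_state, label)
    try:
        with Image.open(path) as im:
            if im.mode in ("1", "L", "LA", "I", "I;16", "F"):
                raise ImageFormatError(
                    f"{path.name}: grayscale image; stain unmixing needs 3 channels"
                )
            if im.mode == "P":  # palette images decode to RGB
                im = im.convert("RGB")
            arr = np.asarray(im)
    except ImageFormatError:
        raise
    except Exception as exc:  # pillow raises several unrelated types
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:
        raise ImageFormatError(f"{path.name}: single-channel image")
    return _finalize_image(arr, path, protein_id, tissue_state, label)


def _finalize_image(arr: np.ndarray, path, protein_id, tissue_state, label) -> IHCImage:
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise ImageFormatError(f"{path.name}: expected 3 channels, got {arr.shape[2]}")
    if arr.dtype == np.uint16:
        arr = (arr.astype(np.float64) / 65535.0 * 255.0).round().astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return IHCImage(pixels=arr, protein_id=protein_id, tissue_state=tissue_state,
                    label=label, source_path=str(path))


def write_image(pixels: np.ndarray, path) -> None:
    """Write an 8-bit RGB array losslessly (PNG recommended)."""
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)
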