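"""Image and case-metadata input/output.

Images are handled as 8-bit grayscale rasters (2-D ``numpy.uint8`` arrays,
row-major, origin top-left, 0-based indices).  Case metadata travels in small
per-case XML files carrying the sonographic descriptors and the TI-RADS risk
category; the category is mapped onto the binary benign/malignant label that
the classifiers consume (TI-RADS 2-3 benign, 4a-5 malignant).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from lxml import etree
from PIL import Image

__all__ = [
    "TIRADS_CATEGORIES",
    "BENIGN",
    "MALIGNANT",
    "CaseMetadata",
    "LabeledCase",
    "Dataset",
    "read_image",
    "write_image",
    "read_case_xml",
    "write_case_xml",
    "tirads_to_label",
    "load_dataset",
]

#: Accepted TI-RADS risk categories, in increasing order of suspicion.
TIRADS_CATEGORIES = ("2", "3", "4a", "4b", "4c", "5")
_BENIGN_TIRADS = frozenset({"2", "3"})

BENIGN = "benign"
MALIGNANT = "malignant"

_IMAGE_EXTENSIONS = (".png", ".tif", ".tiff", ".jpg", ".jpeg")


@dataclass
class CaseMetadata:
    """Per-case sonographic descriptors and risk category.

    All fields except ``case_id`` are optional; unknown elements in the XML
    source are ignored so that externally produced files can be adapted with
    at most a field-name mapping.
    """

    case_id: str = ""
    age: Optional[int] = None
    sex: Optional[str] = None
    composition: Optional[str] = None
    shape: Optional[str] = None
    margin: Optional[str] = None
    calcifications: Optional[str] = None
    tirads: Optional[str] = None
    diagnosis: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tirads is not None and self.tirads not in TIRADS_CATEGORIES:
            raise ValueError(
                f"unknown TI-RADS category {self.tirads!r}; "
                f"accepted: {', '.join(TIRADS_CATEGORIES)}"
            )


@dataclass
class LabeledCase:
    """One classification instance: an image plus its ground-truth label."""

    case_id: str
    image: np.ndarray
    label: str
    metadata: Optional[CaseMetadata] = None

    def __post_init__(self) -> None:
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"label must be {BENIGN!r} or {MALIGNANT!r}, got {self.label!r}")


@dataclass
class Dataset:
    """Ordered collection of labeled cases with per-label tallies."""

    cases: list[LabeledCase] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        tally = {BENIGN: 0, MALIGNANT: 0}
        for case in self.cases:
            tally[case.label] += 1
        return tally

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as an 8-bit grayscale raster.

    Color inputs are converted to luminance (ITU-R 601 weights); bit depths
    above 8 are rescaled linearly onto [0, 255].
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            if img.mode in ("I", "I;16", "I;16B", "I;16L"):
                arr = np.asarray(img, dtype=np.float64)
                top = float(arr.max())
                scale = 255.0 / 65535.0 if top > 255 else 1.0
                arr = np.rint(arr * scale)
                return np.clip(arr, 0, 255).astype(np.uint8)
            if img.mode != "L":
                img = img.convert("L")
            arr = np.asarray(img, dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim != 2:
        raise OSError(f"cannot read image {path}: not a single-channel raster")
    return arr


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an 8-bit grayscale raster to ``path`` (format from extension)."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    Image.fromarray(arr.astype(np.uint8), mode="L").save(Path(path))


_XML_FIELDS = {
    "case_id": str,
    "age": int,
    "sex": str,
    "composition": str,
    "shape": str,
    "margin": str,
    "calcifications": str,
    "tirads": str,
    "diagnosis": str,
}


def read_case_xml(path: str | Path) -> CaseMetadata:
    """Parse a per-case XML metadata file.

    Recognized elements: case_id, age, sex, composition, shape, margin,
    calcifications, tirads, diagnosis.  Extra elements are ignored; missing
    optional elements stay empty.  An unknown TI-RADS token raises
    ``ValueError`` naming the accepted categories.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    values: dict[str, object] = {}
    for element in root.iter():
        tag = etree.QName(element).localname.lower()
        if tag in _XML_FIELDS and element.text and element.text.strip():
            text = element.text.strip()
            values[tag] = _XML_FIELDS[tag](text)
    if "case_id" not in values:
        values["case_id"] = path.stem
    return CaseMetadata(**values)


def write_case_xml(path: str | Path, metadata: CaseMetadata) -> None:
    """Serialize :class:`CaseMetadata` to the documented XML element set."""
    root = etree.Element("case")
    for name in _XML_FIELDS:
        value = getattr(metadata, name)
        if value is not None and value != "":
            child = etree.SubElement(root, name)
            child.text = str(value)
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def tirads_to_label(tirads: str) -> str:
    """Map a TI-RADS category onto the binary label.

    Categories 2 and 3 are benign; 4a, 4b, 4c and 5 are malignant.
    """
    token = str(tirads).strip().lower()
    if token not in TIRADS_CATEGORIES:
        raise ValueError(
            f"unknown TI-RADS category {tirads!r}; accepted: {', '.join(TIRADS_CATEGORIES)}"
        )
    return BENIGN if token in _BENIGN_TIRADS else MALIGNANT


def _case_label(metadata: Optional[CaseMetadata], sidecar: Optional[str]) -> Optional[str]:
    # Label priority: explicit diagnosis, then TI-RADS mapping, then sidecar CSV.
    if metadata is not None:
        if metadata.diagnosis in (BENIGN, MALIGNANT):
            return metadata.diagnosis
        if metadata.tirads is not None:
            return tirads_to_label(metadata.tirads)
    if sidecar in (BENIGN, MALIGNANT):
        return sidecar
    return None


def _read_label_csv(path: Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            labels[row["case_id"].strip()] = row["label"].strip().lower()
    return labels


def load_dataset(
    image_dir: str | Path,
    metadata_dir: str | Path | None = None,
    label_file: str | Path | None = None,
) -> Dataset:
    """Assemble a labeled dataset from an image directory.

    Images pair with XML metadata by shared basename; cases without metadata
    are kept only when ``label_file`` (CSV with columns ``case_id,label``)
    supplies their label.  Ordering is deterministic: sorted by case id,
    independent of directory-listing order.
    """
    image_dir = Path(image_dir)
    if not image_dir.is_dir():
        raise OSError(f"image directory not found: {image_dir}")

    by_stem: dict[str, list[Path]] = {}
    for p in sorted(image_dir.iterdir()):
        if p.suffix.lower() in _IMAGE_EXTENSIONS:
            by_stem.setdefault(p.stem, []).append(p)
    if not by_stem:
        raise OSError(f"no images found in {image_dir}")
    collisions = {stem: paths for stem, paths in by_stem.items() if len(paths) > 1}
    if collisions:
        offenders = "; ".join(
            f"{stem}: {', '.join(p.name for p in paths)}" for stem, paths in sorted(collisions.items())
        )
        raise OSError(f"ambiguous image basenames: {offenders}")

    metadata_dir = Path(metadata_dir) if metadata_dir is not None else None
    sidecar = _read_label_csv(Path(label_file)) if label_file is not None else {}

    cases: list[LabeledCase] = []
    for stem in sorted(by_stem):
        image = read_image(by_stem[stem][0])
        metadata = None
        if metadata_dir is not None:
            xml_path = metadata_dir / f"{stem}.xml"
            if xml_path.exists():
                metadata = read_case_xml(xml_path)
        label = _case_label(metadata, sidecar.get(stem))
        if label is None:
            continue
        cases.append(LabeledCase(case_id=stem, image=image, label=label, metadata=metadata))
    if not cases:
        raise OSError(f"no labelable cases found in {image_dir}")
    return Dataset(cases=cases)
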