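"""Bounding boxes, label vocabularies and Pascal-VOC (LabelImg) annotation I/O.

Coordinate conventions
----------------------
Internally every box is 0-based and half-open on both axes, i.e. the box
``(x_min, y_min, x_max, y_max)`` covers pixel columns ``x_min .. x_max-1``
and rows ``y_min .. y_max-1``; its width is simply ``x_max - x_min``.
Pascal-VOC XML files as written by LabelImg store 1-based *inclusive*
coordinates.  The two conventions are bridged exactly once, at the file
boundary: reading subtracts 1 from ``xmin``/``ymin``, writing adds it back.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree
from PIL import Image

__all__ = [
    "BoundingBox",
    "NucleusClass",
    "SignalClass",
    "AnnotatedObject",
    "AnnotationSet",
    "VocabularyError",
    "AnnotationError",
    "read_voc",
    "write_voc",
    "crop",
    "load_image",
    "save_image",
]


class AnnotationError(ValueError):
    """Malformed annotation file or geometrically invalid annotation."""


class VocabularyError(AnnotationError):
    """A label outside the declared class vocabulary."""


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Axis-aligned pixel rectangle, 0-based half-open on both axes."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise AnnotationError(
                f"box must have positive area, got {self!r}"
            )
        if self.x_min < 0 or self.y_min < 0:
            raise AnnotationError(f"box origin must be non-negative, got {self!r}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        """(x, y) center in continuous pixel coordinates."""
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def contains_point(self, x: float, y: float) -> bool:
        """Half-open containment test for a continuous point."""
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max

    def iou(self, other: "BoundingBox") -> float:
        """Intersection-over-union on half-open boxes."""
        ix = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        iy = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if ix <= 0 or iy <= 0:
            return 0.0
        inter = ix * iy
        return inter / (self.area + other.area - inter)

    def expand(self, margin: int) -> "BoundingBox":
        """Grow by *margin* on all sides, clamped at the image origin."""
        return BoundingBox(
            max(0, self.x_min - margin), max(0, self.y_min - margin),
            self.x_max + margin, self.y_max + margin,
        )

    def clip(self, width: int, height: int) -> "BoundingBox":
        """Clip to an image of the given size; raises if nothing remains."""
        return BoundingBox(
            max(0, self.x_min), max(0, self.y_min),
            min(width, self.x_max), min(height, self.y_max),
        )

    def shift(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.x_min + dx, self.y_min + dy,
                           self.x_max + dx, self.y_max + dy)


class NucleusClass(str, enum.Enum):
    """Per-nucleus HER2 amplification grade assigned by a reader.

    ``normal``/``low``/``high`` form the ordinal "classified" subset; nuclei
    read as ``uncertain`` or ``artifact`` are excluded from ratio denominators.
    """

    NORMAL = "normal"
    LOW = "low"
    HIGH = "high"
    UNCERTAIN = "uncertain"
    ARTIFACT = "artifact"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def is_classified(self) -> bool:
        return self in (NucleusClass.NORMAL, NucleusClass.LOW, NucleusClass.HIGH)


#: Ordinal positions used for agreement weighting: normal < low < high.
NUCLEUS_ORDINAL = {NucleusClass.NORMAL: 0, NucleusClass.LOW: 1, NucleusClass.HIGH: 2}


class SignalClass(str, enum.Enum):
    """Class of an individual FISH signal inside a nucleus."""

    HER2 = "HER2"
    CEN17 = "CEN17"
    HER2_CLUSTER = "HER2_cluster"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Accepted spellings in annotation files, normalised to the canonical labels.
_NUCLEUS_SYNONYMS = {
    "normal": NucleusClass.NORMAL,
    "low": NucleusClass.LOW,
    "low-grade": NucleusClass.LOW,
    "low_grade": NucleusClass.LOW,
    "lowgrade": NucleusClass.LOW,
    "high": NucleusClass.HIGH,
    "high-grade": NucleusClass.HIGH,
    "high_grade": NucleusClass.HIGH,
    "highgrade": NucleusClass.HIGH,
    "uncertain": NucleusClass.UNCERTAIN,
    "artifact": NucleusClass.ARTIFACT,
    "artefact": NucleusClass.ARTIFACT,
}
_SIGNAL_SYNONYMS = {
    "her2": SignalClass.HER2,
    "cen17": SignalClass.CEN17,
    "her2_cluster": SignalClass.HER2_CLUSTER,
    "her2-cluster": SignalClass.HER2_CLUSTER,
    "her2 cluster": SignalClass.HER2_CLUSTER,
    "cluster": SignalClass.HER2_CLUSTER,
}

VOCABULARIES = ("nucleus", "signal")


def parse_label(name: str, vocabulary: str) -> NucleusClass | SignalClass:
    """Normalise a raw label string under the given vocabulary.

    Matching is case-insensitive and tolerant of the hyphen/underscore
    spellings that occur in hand-made annotation files.
    """
    key = name.strip().lower()
    table = _NUCLEUS_SYNONYMS if vocabulary == "nucleus" else _SIGNAL_SYNONYMS
    if vocabulary not in VOCABULARIES:
        raise VocabularyError(f"unknown vocabulary {vocabulary!r}; expected one of {VOCABULARIES}")
    try:
        return table[key]
    except KeyError:
        raise VocabularyError(
            f"label {name!r} is not in the {vocabulary!r} vocabulary "
            f"(admissible: {sorted(set(str(v) for v in table.values()))})"
        ) from None


@dataclass(frozen=True)
class AnnotatedObject:
    """One labelled box, either ground truth or a detector prediction."""

    box: BoundingBox
    label: NucleusClass | SignalClass
    source: str = "ground_truth"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise AnnotationError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class AnnotationSet:
    """All labelled objects of one image (or one nucleus crop)."""

    image_path: str
    image_size: tuple[int, int]  # (width, height)
    objects: tuple[AnnotatedObject, ...]
    vocabulary: str  # "nucleus" or "signal"

    def __post_init__(self) -> None:
        w, h = self.image_size
        for obj in self.objects:
            b = obj.box
            if b.x_max > w or b.y_max > h:
                raise AnnotationError(
                    f"box {b} exceeds image size {self.image_size} in {self.image_path!r}"
                )

    def __len__(self) -> int:
        return len(self.objects)

    def boxes(self) -> list[BoundingBox]:
        return [o.box for o in self.objects]

    def labels(self) -> list[NucleusClass | SignalClass]:
        return [o.label for o in self.objects]

    def with_objects(self, objects: Iterable[AnnotatedObject]) -> "AnnotationSet":
        return replace(self, objects=tuple(objects))


# ---------------------------------------------------------------------------
# Pascal-VOC XML I/O (LabelImg dialect)
# ---------------------------------------------------------------------------

def _text(parent: etree._Element, tag: str, where: str) -> str:
    el = parent.find(tag)
    if el is None or el.text is None:
        raise AnnotationError(f"missing <{tag}> in {where}")
    return el.text.strip()


def read_voc(path: str | Path, vocabulary: str) -> AnnotationSet:
    """Read a LabelImg/Pascal-VOC XML annotation file.

    VOC's 1-based inclusive pixel coordinates are converted to the internal
    0-based half-open convention.  Labels are validated against *vocabulary*
    (``"nucleus"`` or ``"signal"``); an unknown label raises
    :class:`VocabularyError` naming the offending string.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise AnnotationError(f"cannot parse VOC XML {path}: {exc}") from exc
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise AnnotationError(f"missing <size> in {path}")
    width = int(_text(size, "width", str(path)))
    height = int(_text(size, "height", str(path)))
    filename_el = root.find("filename")
    image_path = filename_el.text.strip() if filename_el is not None and filename_el.text else ""

    objects = []
    for obj in root.iterfind("object"):
        name = _text(obj, "name", str(path))
        label = parse_label(name, vocabulary)
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationError(f"<object> without <bndbox> in {path}")
        # VOC stores 1-based inclusive corners; float-valued coordinates
        # (some tools emit them) are rounded to the nearest pixel.
        xmin = round(float(_text(bnd, "xmin", str(path))))
        ymin = round(float(_text(bnd, "ymin", str(path))))
        xmax = round(float(_text(bnd, "xmax", str(path))))
        ymax = round(float(_text(bnd, "ymax", str(path))))
        box = BoundingBox(xmin - 1, ymin - 1, xmax, ymax)
        objects.append(AnnotatedObject(box=box, label=label))
    return AnnotationSet(
        image_path=image_path,
        image_size=(width, height),
        objects=tuple(objects),
        vocabulary=vocabulary,
    )


def write_voc(annotations: AnnotationSet, path: str | Path) -> Path:
    """Write an :class:`AnnotationSet` as LabelImg-compatible VOC XML.

    Inverse of :func:`read_voc`; objects are written in input order so the
    round-trip is the identity.
    """
    path = Path(path)
    root = etree.Element("annotation")
    # constant folder name keeps output byte-identical across directories
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = annotations.image_path or path.stem
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(annotations.image_size[0])
    etree.SubElement(size, "height").text = str(annotations.image_size[1])
    etree.SubElement(size, "depth").text = "3"
    etree.SubElement(root, "segmented").text = "0"
    for obj in annotations.objects:
        el = etree.SubElement(root, "object")
        etree.SubElement(el, "name").text = str(obj.label)
        etree.SubElement(el, "pose").text = "Unspecified"
        etree.SubElement(el, "truncated").text = "0"
        etree.SubElement(el, "difficult").text = "0"
        bnd = etree.SubElement(el, "bndbox")
        b = obj.box
        etree.SubElement(bnd, "xmin").text = str(b.x_min + 1)
        etree.SubElement(bnd, "ymin").text = str(b.y_min + 1)
        etree.SubElement(bnd, "xmax").text = str(b.x_max)
        etree.SubElement(bnd, "ymax").text = str(b.y_max)
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=False, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Raster helpers
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    """Load a JPEG/PNG image as an 8-bit RGB ``(H, W, 3)`` array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def save_image(image: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)
    return path


def crop(
    image: np.ndarray, box: BoundingBox, margin: int = 10
) -> tuple[np.ndarray, tuple[int, int]]:
    """Extract the sub-raster of *box* expanded by *margin*, clipped to the image.

    Returns ``(crop, (x_off, y_off))`` where adding the offset to crop-local
    coordinates recovers image coordinates.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    h, w = image.shape[:2]
    if box.x_max > w or box.y_max > h:
        raise AnnotationError(f"box {box} does not fit image of size {(w, h)}")
    expanded = box.expand(margin).clip(w, h)
    sub = image[expanded.y_min:expanded.y_max, expanded.x_min:expanded.x_max]
    return sub, (expanded.x_min, expanded.y_min)
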