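"""PASCAL VOC annotation I/O, rescaling, and dataset splitting.

Internal box coordinates are 0-based and half-open: a box covers the pixel
columns ``x_min .. x_max-1``, so its width is exactly ``x_max - x_min``.
VOC XML on disk uses the dialect's 1-based inclusive convention; the
conversion happens only in :func:`parse_voc` / :func:`write_voc`, never
inside the numeric pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from lxml import etree

from soyphen.errors import DataValidationError, VocParseError

KNOWN_LABELS = frozenset({"flower", "pod"})


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel rectangle, 0-based half-open coordinates.

    ``confidence`` is present on detector output and absent (``None``) on
    ground truth.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise DataValidationError(
                f"degenerate box ({self.x_min},{self.y_min},{self.x_max},{self.y_max})"
            )
        if not self.label:
            raise DataValidationError("box label must be non-empty")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise DataValidationError(f"confidence {self.confidence} outside [0,1]")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class ImageAnnotation:
    """All ground-truth boxes of one image, with its pixel dimensions."""

    image_id: str
    width: int
    height: int
    boxes: tuple[BoundingBox, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise DataValidationError(
                f"{self.image_id}: non-positive image size {self.width}x{self.height}"
            )
        object.__setattr__(self, "boxes", tuple(self.boxes))
        for b in self.boxes:
            if b.x_min < 0 or b.y_min < 0 or b.x_max > self.width or b.y_max > self.height:
                raise DataValidationError(
                    f"{self.image_id}: box ({b.x_min},{b.y_min},{b.x_max},{b.y_max}) "
                    f"outside image {self.width}x{self.height}"
                )


@dataclass(frozen=True)
class DatasetSplit:
    """Train/val/test partition of image ids, reproducible from ``seed``."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_ids), len(self.val_ids), len(self.test_ids))


def _require(element, parent, tag: str):
    child = element.find(tag)
    if child is None:
        raise VocParseError(f"missing <{tag}> under <{parent}>")
    return child


def _int_text(element, parent, tag: str) -> int:
    child = _require(element, parent, tag)
    try:
        return int(float(child.text))
    except (TypeError, ValueError) as exc:
        raise VocParseError(f"non-numeric <{tag}> under <{parent}>: {child.text!r}") from exc


def parse_voc(xml_text: str | bytes) -> ImageAnnotation:
    """Parse one PASCAL VOC annotation document.

    VOC stores 1-based inclusive pixel coordinates; they are converted to
    the internal 0-based half-open convention
    (``x_min = xmin_voc - 1``, ``x_max = xmax_voc``), so widths/areas come
    out as plain differences/products.

    Raises
    ------
    VocParseError
        On a missing ``<size>`` block, a degenerate box (``xmin >= xmax``),
        or an empty/unknown object label.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode()
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise VocParseError(f"not well-formed XML: {exc}") from exc

    size = root.find("size")
    if size is None:
        raise VocParseError("missing <size> block")
    width = _int_text(size, "size", "width")
    height = _int_text(size, "size", "height")

    fname = root.findtext("filename") or ""
    image_id = fname.rsplit(".", 1)[0] if fname else ""

    boxes: list[BoundingBox] = []
    for i, obj in enumerate(root.iterfind("object")):
        label = (obj.findtext("name") or "").strip()
        if not label:
            raise VocParseError(f"object {i}: empty <name>")
        if label not in KNOWN_LABELS:
            raise VocParseError(f"object {i}: unknown label {label!r}")
        bb = _require(obj, "object", "bndbox")
        xmin = _int_text(bb, "bndbox", "xmin")
        ymin = _int_text(bb, "bndbox", "ymin")
        xmax = _int_text(bb, "bndbox", "xmax")
        ymax = _int_text(bb, "bndbox", "ymax")
        if xmin >= xmax or ymin >= ymax:
            raise VocParseError(
                f"object {i}: degenerate bndbox ({xmin},{ymin},{xmax},{ymax})"
            )
        boxes.append(
            BoundingBox(x_min=xmin - 1, y_min=ymin - 1, x_max=xmax, y_max=ymax, label=label)
        )
    try:
        return ImageAnnotation(image_id=image_id, width=width, height=height, boxes=tuple(boxes))
    except DataValidationError as exc:
        raise VocParseError(str(exc)) from exc


def write_voc(ann: ImageAnnotation) -> str:
    """Serialize an annotation back to VOC XML (inverse of :func:`parse_voc`).

    Internal 0-based half-open coordinates become VOC's 1-based inclusive
    integers; fractional coordinates are refused because the dialect is
    integer-valued.
    """
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = f"{ann.image_id}.jpg"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.width)
    etree.SubElement(size, "height").text = str(ann.height)
    etree.SubElement(size, "depth").text = "3"
    for b in ann.boxes:
        coords = (b.x_min, b.y_min, b.x_max, b.y_max)
        if any(c != int(c) for c in coords):
            raise DataValidationError(
                f"{ann.image_id}: VOC output requires integer coordinates, got {coords}"
            )
        if b.width < 2 or b.height < 2:
            # the dialect's 1-based inclusive coords with xmin < xmax cannot
            # express a 1-pixel extent
            raise DataValidationError(
                f"{ann.image_id}: box thinner than 2 px not representable in VOC"
            )
        if b.x_max > ann.width or b.y_max > ann.height or b.x_min < 0 or b.y_min < 0:
            raise DataValidationError(f"{ann.image_id}: box outside image, refusing to serialize")
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = b.label
        etree.SubElement(obj, "difficult").text = "0"
        bb = etree.SubElement(obj, "bndbox")
        etree.SubElement(bb, "xmin").text = str(int(b.x_min) + 1)
        etree.SubElement(bb, "ymin").text = str(int(b.y_min) + 1)
        etree.SubElement(bb, "xmax").text = str(int(b.x_max))
        etree.SubElement(bb, "ymax").text = str(int(b.y_max))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def rescale_annotation(ann: ImageAnnotation, target_w: int, target_h: int) -> ImageAnnotation:
    """Rescale an annotation to the working resolution (e.g. 640x640).

    Box coordinates are scaled per axis by ``target/source``; the relative
    area of every box is preserved exactly up to float rounding.
    """
    if target_w <= 0 or target_h <= 0:
        raise DataValidationError(f"non-positive target size {target_w}x{target_h}")
    sx = target_w / ann.width
    sy = target_h / ann.height
    boxes = tuple(
        replace(b, x_min=b.x_min * sx, x_max=b.x_max * sx, y_min=b.y_min * sy, y_max=b.y_max * sy)
        for b in ann.boxes
    )
    return ImageAnnotation(image_id=ann.image_id, width=target_w, height=target_h, boxes=boxes)


def split_dataset(
    ids: Sequence[str],
    seed: int,
    test_frac: float = 0.2,
    val_frac_of_trainval: float = 0.1,
) -> DatasetSplit:
    """Random train/val/test split with the floor rounding convention.

    The id set is first split train+val : test at ``(1-test_frac) : test_frac``
    and train+val is then split train : val at
    ``(1-val_frac_of_trainval) : val_frac_of_trainval``.  Sizes follow
    ``n_trainval = floor(n*(1-test_frac))``,
    ``n_train = floor(n_trainval*(1-val_frac_of_trainval))``; remainders go
    to test and val.  For the study's 1,895 flower and 2,693 pod images at
    8:2 then 9:1 this yields (1364, 152, 379) and (1938, 216, 539).

    Ids are lexicographically sorted before the seeded shuffle, so the
    member lists — not just the sizes — are reproducible across platforms.
    """
    ids = list(ids)
    if not ids:
        raise DataValidationError("empty id list")
    if len(set(ids)) != len(ids):
        raise DataValidationError("duplicate ids in input")
    if not (0.0 < test_frac < 1.0 and 0.0 < val_frac_of_trainval < 1.0):
        raise DataValidationError("split fractions must lie in (0,1)")

    n = len(ids)
    # Exact rational arithmetic: floor(1895 * (1 - 0.2)) must be 1516, which
    # naive float 1 - 0.2 = 0.7999... can miss.
    n_trainval = int((1 - Fraction(str(test_frac))) * n)
    n_train = int((1 - Fraction(str(val_frac_of_trainval))) * n_trainval)

    order = sorted(ids)
    rng = np.random.default_rng(seed)
    # Fisher-Yates over the sorted list
    for i in range(n - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        order[i], order[j] = order[j], order[i]

    return DatasetSplit(
        train_ids=tuple(order[:n_train]),
        val_ids=tuple(order[n_train:n_trainval]),
        test_ids=tuple(order[n_trainval:]),
        seed=seed,
    )


def read_split_manifest(text: str) -> list[str]:
    """Read a plain-text id manifest, one id per line, blank lines ignored."""
    return [line.strip() for line in text.splitlines() if line.strip()]


def write_split_manifests(split: DatasetSplit) -> dict[str, str]:
    """Render the three member lists as plain-text manifests."""
    return {
        "train": "\n".join(split.train_ids) + "\n",
        "val": "\n".join(split.val_ids) + "\n",
        "test": "\n".join(split.test_ids) + "\n",
    }
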