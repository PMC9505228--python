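"""Annotated lesion image I/O and geometric preprocessing.

Boxes are stored internally in 0-based, half-open pixel coordinates
(``xmin <= x < xmax``, x to the right, y down).  Pascal VOC XML uses
1-based inclusive pixels, so reading converts ``(xmin, ymin, xmax, ymax)``
to ``(xmin - 1, ymin - 1, xmax, ymax)`` and writing inverts that exactly.
YOLO txt files store one box per line as ``class cx cy w h`` with all four
values normalized to [0, 1] by the image size.

Box order is preserved as read; readers never sort or clamp.  A box outside
the image bounds is a validation error, not a silent fix.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .grading import GradingScheme, SeverityClass, severity_from_count

__all__ = [
    "LesionBox",
    "AnnotatedImage",
    "AnnotationError",
    "read_voc_xml",
    "write_voc_xml",
    "read_yolo_txt",
    "write_yolo_txt",
    "resize_with_boxes",
    "normalize_image",
]


class AnnotationError(ValueError):
    """Malformed or invalid annotation data."""


@dataclass(frozen=True)
class LesionBox:
    """One rectangular lesion annotation or detection.

    Coordinates are 0-based half-open pixels; ``confidence`` is ``None`` for
    ground truth and a value in [0, 1] for detector output.
    """

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    confidence: float | None = None

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise AnnotationError(
                f"degenerate box ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax})"
            )
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise AnnotationError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.xmin + self.xmax), 0.5 * (self.ymin + self.ymax))

    def validate_within(self, width: int, height: int) -> None:
        if self.xmin < 0 or self.ymin < 0 or self.xmax > width or self.ymax > height:
            raise AnnotationError(
                f"box ({self.xmin}, {self.ymin}, {self.xmax}, {self.ymax}) "
                f"outside image bounds {width}x{height}"
            )


def iou(a: LesionBox, b: LesionBox) -> float:
    """Intersection-over-union of two boxes (0 when disjoint)."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    if inter <= 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


@dataclass
class AnnotatedImage:
    """Image + lesion boxes + per-image count and severity.

    ``pixels`` (H, W, 3) uint8 is optional: annotations can exist without
    loaded image data.  ``count`` always equals ``len(boxes)`` when boxes
    are present, and ``severity`` is the grading-scheme image of the count.
    """

    image_id: str
    width: int
    height: int
    boxes: list[LesionBox] = field(default_factory=list)
    pixels: np.ndarray | None = None
    count: int | None = None
    severity: SeverityClass | None = None

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise AnnotationError("image dimensions must be positive")
        for b in self.boxes:
            b.validate_within(self.width, self.height)
        if self.count is None:
            self.count = len(self.boxes)
        elif self.boxes and self.count != len(self.boxes):
            raise AnnotationError(
                f"count {self.count} != number of boxes {len(self.boxes)}"
            )
        if self.pixels is not None:
            self.pixels = np.asarray(self.pixels)
            if self.pixels.shape != (self.height, self.width, 3):
                raise AnnotationError(
                    f"pixels shape {self.pixels.shape} != "
                    f"({self.height}, {self.width}, 3)"
                )

    def with_severity(self, scheme: GradingScheme | None = None) -> "AnnotatedImage":
        self.severity = severity_from_count(self.count, scheme)
        return self


# ---------------------------------------------------------------------------
# Pascal VOC XML
# ---------------------------------------------------------------------------

def read_voc_xml(
    path: str | Path, scheme: GradingScheme | None = None
) -> AnnotatedImage:
    """Read a per-image Pascal VOC annotation file.

    VOC 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention.  Severity is derived from the object count via the
    grading scheme when the count is in its domain.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise AnnotationError(f"malformed VOC XML in {path}: {e}") from e
    root = tree.getroot()
    size = root.find("size")
    if size is None:
        raise AnnotationError(f"{path}: missing <size> element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    objects = root.findall("object")
    if not objects:
        raise AnnotationError(f"{path}: no <object> annotations")
    boxes = []
    for obj in objects:
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationError(f"{path}: <object> without <bndbox>")
        xmin = float(bnd.findtext("xmin")) - 1.0
        ymin = float(bnd.findtext("ymin")) - 1.0
        xmax = float(bnd.findtext("xmax"))
        ymax = float(bnd.findtext("ymax"))
        box = LesionBox(xmin, ymin, xmax, ymax)
        box.validate_within(width, height)
        boxes.append(box)
    image_id = root.findtext("filename") or path.stem
    image_id = Path(image_id).stem
    img = AnnotatedImage(image_id=image_id, width=width, height=height, boxes=boxes)
    scheme = scheme or GradingScheme()
    if 1 <= img.count <= scheme.c_max:
        img.with_severity(scheme)
    return img


def write_voc_xml(img: AnnotatedImage, path: str | Path) -> None:
    """Write a Pascal VOC annotation; round-trips exactly through read_voc_xml."""
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = f"{img.image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(img.width)
    ET.SubElement(size, "height").text = str(img.height)
    ET.SubElement(size, "depth").text = "3"
    for b in img.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = "lesion"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = _fmt(b.xmin + 1.0)
        ET.SubElement(bnd, "ymin").text = _fmt(b.ymin + 1.0)
        ET.SubElement(bnd, "xmax").text = _fmt(b.xmax)
        ET.SubElement(bnd, "ymax").text = _fmt(b.ymax)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


def _fmt(v: float) -> str:
    """Integers without trailing .0; floats with full repr precision."""
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# YOLO txt
# ---------------------------------------------------------------------------

def read_yolo_txt(path: str | Path, width: int, height: int) -> list[LesionBox]:
    """Read YOLO-format boxes (``class cx cy w h``, normalized to [0, 1])."""
    if width <= 0 or height <= 0:
        raise AnnotationError("image dimensions must be positive")
    boxes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise AnnotationError(f"{path}:{lineno}: expected 5 or 6 fields")
        _, cx, cy, w, h = (float(p) for p in parts[:5])
        conf = float(parts[5]) if len(parts) == 6 else None
        for v in (cx, cy, w, h):
            if not 0.0 <= v <= 1.0:
                raise AnnotationError(
                    f"{path}:{lineno}: normalized value {v} outside [0, 1]"
                )
        boxes.append(
            LesionBox(
                xmin=(cx - w / 2) * width,
                ymin=(cy - h / 2) * height,
                xmax=(cx + w / 2) * width,
                ymax=(cy + h / 2) * height,
                confidence=conf,
            )
        )
    return boxes


def write_yolo_txt(
    boxes: Sequence[LesionBox], width: int, height: int, path: str | Path
) -> None:
    """Write boxes in YOLO normalized-center format (single class 0)."""
    if width <= 0 or height <= 0:
        raise AnnotationError("image dimensions must be positive")
    lines = []
    for b in boxes:
        cx = (b.xmin + b.xmax) / 2 / width
        cy = (b.ymin + b.ymax) / 2 / height
        w = b.width / width
        h = b.height / height
        fields = f"0 {cx:.9f} {cy:.9f} {w:.9f} {h:.9f}"
        if b.confidence is not None:
            fields += f" {b.confidence:.9f}"
        lines.append(fields)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Geometric preprocessing
# ---------------------------------------------------------------------------

def resize_with_boxes(
    img: AnnotatedImage, target: tuple[int, int]
) -> AnnotatedImage:
    """Resize an image to ``target=(W, H)`` and rescale its boxes to match.

    Count and severity are unchanged.  A box that would collapse below one
    pixel in either dimension is kept at a minimum size of 1 px and a
    warning is emitted.
    """
    tw, th = target
    if tw <= 0 or th <= 0:
        raise ValueError("target dimensions must be positive")
    sx, sy = tw / img.width, th / img.height
    new_boxes = []
    for b in img.boxes:
        xmin, xmax = b.xmin * sx, b.xmax * sx
        ymin, ymax = b.ymin * sy, b.ymax * sy
        if xmax - xmin < 1.0 or ymax - ymin < 1.0:
            warnings.warn(
                f"box in {img.image_id} degenerate after resize; kept at 1 px",
                stacklevel=2,
            )
            if xmax - xmin < 1.0:
                cx = min(max(0.5, (xmin + xmax) / 2), tw - 0.5)
                xmin, xmax = cx - 0.5, cx + 0.5
            if ymax - ymin < 1.0:
                cy = min(max(0.5, (ymin + ymax) / 2), th - 0.5)
                ymin, ymax = cy - 0.5, cy + 0.5
        new_boxes.append(replace(b, xmin=xmin, ymin=ymin, xmax=xmax, ymax=ymax))
    pixels = None
    if img.pixels is not None:
        pixels = np.asarray(
            Image.fromarray(img.pixels).resize((tw, th), Image.BILINEAR)
        )
    return AnnotatedImage(
        image_id=img.image_id,
        width=tw,
        height=th,
        boxes=new_boxes,
        pixels=pixels,
        count=img.count,
        severity=img.severity,
    )


def load_manifest_dataset(
    root: str | Path, scheme: GradingScheme | None = None, load_pixels: bool = True
) -> list[AnnotatedImage]:
    """Load a dataset directory written by the synthetic generator.

    ``root`` must contain ``manifest.yaml`` listing image/annotation pairs;
    annotations are Pascal VOC XML and images PNG/JPEG.
    """
    import yaml

    root = Path(root)
    manifest = yaml.safe_load((root / "manifest.yaml").read_text())
    out = []
    for item in manifest["items"]:
        img = read_voc_xml(root / item["annotation"], scheme)
        if load_pixels:
            img.pixels = np.asarray(Image.open(root / item["image"]).convert("RGB"))
        out.append(img)
    return out


def normalize_image(
    pixels: np.ndarray,
    mean: Sequence[float] = (0.5, 0.5, 0.5),
    std: Sequence[float] = (0.5, 0.5, 0.5),
) -> np.ndarray:
    """Channelwise ``(pixels / 255 - mean) / std`` as float32."""
    mean = np.asarray(mean, dtype=np.float32).reshape(1, 1, 3)
    std = np.asarray(std, dtype=np.float32).reshape(1, 1, 3)
    if np.any(std <= 0):
        raise ValueError("std components must be positive")
    return (np.asarray(pixels, dtype=np.float32) / 255.0 - mean) / std
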