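"""PASCAL VOC XML annotation I/O.

Internally the package uses 0-based, half-open pixel boxes; VOC files use
1-based inclusive integer corners.  The conversion happens exactly here:
``xmin_voc = round(x1) + 1`` and ``xmax_voc = round(x2)``, so an internal
integer box (10, 20, 50, 80) becomes (11, 21, 50, 80) on disk and
round-trips identically.  Only the two tray classes are accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import xml.etree.ElementTree as ET

from .detector import CLASS_NAMES, GTBox

__all__ = ["VocObject", "VocRecord", "boxes_to_record", "record_to_boxes", "write_voc", "read_voc"]


class VocError(ValueError):
    """Malformed or out-of-dialect VOC annotation."""


@dataclass(frozen=True)
class VocObject:
    name: str
    xmin: int  # 1-based inclusive
    ymin: int
    xmax: int
    ymax: int

    def __post_init__(self) -> None:
        if self.name not in CLASS_NAMES:
            raise VocError(f"unknown class name {self.name!r}; expected one of {CLASS_NAMES}")
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise VocError(f"degenerate bndbox {self}")


@dataclass
class VocRecord:
    filename: str
    width: int
    height: int
    depth: int = 3
    objects: list[VocObject] = field(default_factory=list)


def boxes_to_record(
    boxes: list[GTBox], filename: str, width: int, height: int
) -> VocRecord:
    """Internal 0-based half-open boxes -> 1-based inclusive VOC objects."""
    objs = [
        VocObject(
            name=CLASS_NAMES[b.class_id],
            xmin=int(round(b.x1)) + 1,
            ymin=int(round(b.y1)) + 1,
            xmax=int(round(b.x2)),
            ymax=int(round(b.y2)),
        )
        for b in boxes
    ]
    return VocRecord(filename=filename, width=width, height=height, objects=objs)


def record_to_boxes(record: VocRecord) -> list[GTBox]:
    """Inverse of :func:`boxes_to_record` (exact on integer boxes)."""
    return [
        GTBox(
            class_id=CLASS_NAMES.index(o.name),
            x1=float(o.xmin - 1),
            y1=float(o.ymin - 1),
            x2=float(o.xmax),
            y2=float(o.ymax),
        )
        for o in record.objects
    ]


def write_voc(record: VocRecord, path: str | Path) -> None:
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = record.filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(record.width)
    ET.SubElement(size, "height").text = str(record.height)
    ET.SubElement(size, "depth").text = str(record.depth)
    for o in record.objects:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = o.name
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        for tag, v in (("xmin", o.xmin), ("ymin", o.ymin), ("xmax", o.xmax), ("ymax", o.ymax)):
            ET.SubElement(bb, tag).text = str(v)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(Path(path), encoding="unicode")


def read_voc(path: str | Path) -> VocRecord:
    try:
        root = ET.parse(Path(path)).getroot()
    except ET.ParseError as e:
        raise VocError(f"malformed XML in {path}: {e}") from e
    size = root.find("size")
    if size is None:
        raise VocError(f"{path}: missing <size> element")
    rec = VocRecord(
        filename=_text(root, "filename", path),
        width=int(_text(size, "width", path)),
        height=int(_text(size, "height", path)),
        depth=int(_text(size, "depth", path)),
    )
    for obj in root.findall("object"):
        bb = obj.find("bndbox")
        if bb is None:
            raise VocError(f"{path}: <object> without <bndbox>")
        rec.objects.append(
            VocObject(
                name=_text(obj, "name", path),
                xmin=int(round(float(_text(bb, "xmin", path)))),
                ymin=int(round(float(_text(bb, "ymin", path)))),
                xmax=int(round(float(_text(bb, "xmax", path)))),
                ymax=int(round(float(_text(bb, "ymax", path)))),
            )
        )
    return rec


def _text(elem: ET.Element, tag: str, path) -> str:
    child = elem.find(tag)
    if child is None or child.text is None:
        raise VocError(f"{path}: missing <{tag}> element")
    return child.text.strip()
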