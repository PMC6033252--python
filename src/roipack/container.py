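"""The `.mipp` four-section container format.

A package holds one or more compressed images.  Byte layout (all integers
little-endian):

========  ======================================================
offset    content
========  ======================================================
0         magic ``MIPP`` (4 bytes)
4         format version, u8 (currently 1)
5         u32 tree_size, then the serialized Huffman codebook
..        u32 text_bytes, u32 text_bitcount, then the Huffman-coded
          text payload (zero-padded to text_bytes)
..        u16 image_number
..        per image: u32 roi_size; bbox row0,col0,row1,col1 as 4xu32
          (half-open); frame rows,cols as 2xu32; bits_stored u8;
          then the roi_size-byte JPEG-LS ROI stream
========  ======================================================

The text payload (before Huffman coding) is a deterministic JSON document
carrying, per image, the frame dimensions, the metadata whitelist pairs
and the text runs with anchors and intensity.  One Huffman codebook is
shared by the whole package, built over the concatenated payload.

Every size prefix is validated on read; a package is rejected outright on
bad magic, overrunning sections, or an image count that disagrees with
the per-image records.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field

from . import huffman
from .errors import (
    CompletenessError,
    ConsistencyError,
    FormatError,
    TruncationError,
)
from .ocr import TextRun

__all__ = ["CompressedImage", "write_package", "read_package", "section_map"]

MAGIC = b"MIPP"
VERSION = 1

#: fixed per-image record header: u32 size + 4xu32 bbox + 2xu32 frame + u8 bits
IMAGE_HEADER_BYTES = 4 + 16 + 8 + 1


@dataclass
class CompressedImage:
    """One image of a package: lossless ROI stream + text runs + metadata."""

    roi_stream: bytes
    bbox: tuple[int, int, int, int]
    rows: int
    cols: int
    bits_stored: int
    runs: list[TextRun] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.roi_stream:
            raise CompletenessError("image lacks an ROI stream")
        r0, c0, r1, c1 = self.bbox
        if not (0 <= r0 < r1 <= self.rows and 0 <= c0 < c1 <= self.cols):
            raise CompletenessError(f"bbox {self.bbox} outside {self.rows}x{self.cols} frame")
        if not (8 <= self.bits_stored <= 16):
            raise CompletenessError(f"bits_stored {self.bits_stored} outside [8, 16]")


def _text_payload(entries: list[CompressedImage]) -> bytes:
    doc = {
        "images": [
            {
                "rows": e.rows,
                "cols": e.cols,
                "metadata": dict(sorted(e.metadata.items())),
                "runs": [
                    {
                        "text": t.text,
                        "row": t.anchor[0],
                        "col": t.anchor[1],
                        "intensity": t.intensity,
                        "font_id": t.font_id,
                    }
                    for t in e.runs
                ],
            }
            for e in entries
        ]
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":")).encode()


def write_package(entries: list[CompressedImage]) -> bytes:
    if not entries:
        raise CompletenessError("a package must hold at least one image")
    if len(entries) > 0xFFFF:
        raise CompletenessError("image count exceeds u16")
    for e in entries:
        e.validate()
    payload = _text_payload(entries)
    book = huffman.build_codebook(payload)
    tree = huffman.serialize_codebook(book)
    coded, bitcount = huffman.encode(payload, book)

    out = bytearray()
    out += MAGIC
    out.append(VERSION)
    out += struct.pack("<I", len(tree))
    out += tree
    out += struct.pack("<II", len(coded), bitcount)
    out += coded
    out += struct.pack("<H", len(entries))
    for e in entries:
        r0, c0, r1, c1 = e.bbox
        out += struct.pack(
            "<IIIIIIIB", len(e.roi_stream), r0, c0, r1, c1, e.rows, e.cols, e.bits_stored
        )
        out += e.roi_stream
    return bytes(out)


def _take(data: bytes, pos: int, n: int, section: str) -> tuple[bytes, int]:
    if pos + n > len(data):
        raise TruncationError(f"package truncated in {section} section")
    return data[pos : pos + n], pos + n


def read_package(data: bytes) -> list[CompressedImage]:
    chunk, pos = _take(data, 0, 5, "header")
    if chunk[:4] != MAGIC:
        raise FormatError("bad magic; not a MIPP package")
    if chunk[4] != VERSION:
        raise FormatError(f"unsupported package version {chunk[4]}")

    raw, pos = _take(data, pos, 4, "codebook")
    tree_size = struct.unpack("<I", raw)[0]
    tree, pos = _take(data, pos, tree_size, "codebook")
    book = huffman.deserialize_codebook(tree)

    raw, pos = _take(data, pos, 8, "text")
    text_bytes, bitcount = struct.unpack("<II", raw)
    if text_bytes != (bitcount + 7) // 8:
        raise ConsistencyError(
            f"text section declares {text_bytes} bytes for {bitcount} bits"
        )
    coded, pos = _take(data, pos, text_bytes, "text")
    payload = huffman.decode(coded, bitcount, book)
    try:
        doc = json.loads(payload.decode())
        images_doc = doc["images"]
    except (ValueError, KeyError) as exc:
        raise ConsistencyError(f"text payload is not a valid record set: {exc}") from exc

    raw, pos = _take(data, pos, 2, "image number")
    image_number = struct.unpack("<H", raw)[0]
    if image_number < 1:
        raise ConsistencyError("package declares zero images")
    if image_number != len(images_doc):
        raise ConsistencyError(
            f"image_number {image_number} != {len(images_doc)} text records"
        )

    entries: list[CompressedImage] = []
    for i in range(image_number):
        raw, pos = _take(data, pos, IMAGE_HEADER_BYTES, f"roi[{i}] header")
        roi_size, r0, c0, r1, c1, rows, cols, bits = struct.unpack("<IIIIIIIB", raw)
        stream, pos = _take(data, pos, roi_size, f"roi[{i}] stream")
        rec = images_doc[i]
        if rec["rows"] != rows or rec["cols"] != cols:
            raise ConsistencyError(
                f"image {i}: frame {rows}x{cols} disagrees with text record "
                f"{rec['rows']}x{rec['cols']}"
            )
        runs = [
            TextRun(
                text=r["text"],
                anchor=(r["row"], r["col"]),
                intensity=r["intensity"],
                font_id=r.get("font_id", "roipack-5x7"),
            )
            for r in rec["runs"]
        ]
        entry = CompressedImage(
            roi_stream=stream,
            bbox=(r0, c0, r1, c1),
            rows=rows,
            cols=cols,
            bits_stored=bits,
            runs=runs,
            metadata=dict(rec["metadata"]),
        )
        entry.validate()
        entries.append(entry)
    if pos != len(data):
        raise ConsistencyError(f"{len(data) - pos} trailing bytes after last roi section")
    return entries


def section_map(data: bytes) -> dict[str, tuple[int, int]]:
    """(offset, size) of each section — used by ``roipack inspect``."""
    sections: dict[str, tuple[int, int]] = {"magic+version": (0, 5)}
    pos = 5
    raw, pos2 = _take(data, pos, 4, "codebook")
    tree_size = struct.unpack("<I", raw)[0]
    sections["codebook"] = (pos, 4 + tree_size)
    pos = pos2 + tree_size
    raw, pos2 = _take(data, pos, 8, "text")
    text_bytes = struct.unpack("<II", raw)[0]
    sections["text"] = (pos, 8 + text_bytes)
    pos = pos2 + text_bytes
    raw, pos2 = _take(data, pos, 2, "image number")
    n = struct.unpack("<H", raw)[0]
    sections["image_number"] = (pos, 2)
    pos = pos2
    for i in range(n):
        raw, pos2 = _take(data, pos, IMAGE_HEADER_BYTES, f"roi[{i}]")
        roi_size = struct.unpack("<I", raw[:4])[0]
        sections[f"roi[{i}]"] = (pos, IMAGE_HEADER_BYTES + roi_size)
        pos = pos2 + roi_size
    return sections
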