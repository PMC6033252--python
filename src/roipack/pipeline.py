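"""End-to-end compression, reconstruction and metrics.

``compress_image`` runs the per-image chain: active-contour segmentation,
rectangular ROI crop, lossless JPEG-LS coding of the crop, OCR of the
non-ROI annotations.  Everything outside the crop and the recognised
glyphs is *discarded* — that deletion is where the non-ROI saving comes
from, and it is content-lossless because reconstruction re-renders the
extracted runs onto a black canvas before pasting the decoded crop back.

``compress_package`` is a scatter-gather contract: images are mapped to a
worker pool (any worker count), and the reduce step consolidates results
into one container in deterministic input order, so the package bytes are
independent of parallelism and completion order.

``compression_metrics`` reports both ratio conventions used in practice —
fold ratio S_orig/S_comp and percent saved 100*(1 - S_comp/S_orig) — per
segment (ROI, non-ROI) and in total, plus a per-image breakdown.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np

from . import container, jpegls
from .container import CompressedImage
from .dicom_io import METADATA_WHITELIST, ImageRecord, write_dicom
from .errors import ConsistencyError, RoipackError
from .font import DEFAULT_ATLAS, FontAtlas
from .ocr import extract_runs
from .phantom import render_text
from .segmentation import SegmentationParams, segment_roi

__all__ = [
    "CompressedImage",
    "SegmentMetrics",
    "Metrics",
    "compress_image",
    "compress_package",
    "reconstruct_package",
    "reconstruct_to_dicom",
    "compression_metrics",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentMetrics:
    """Byte accounting for one segment under both ratio conventions."""

    s_orig: float
    s_comp: float

    @property
    def fold_ratio(self) -> float:
        return self.s_orig / self.s_comp if self.s_comp > 0 else float("inf")

    @property
    def percent_saved(self) -> float:
        return 100.0 * (1.0 - self.s_comp / self.s_orig) if self.s_orig > 0 else 0.0


@dataclass(frozen=True)
class Metrics:
    roi: SegmentMetrics
    non_roi: SegmentMetrics
    total: SegmentMetrics
    per_image: list[dict]


def _bytes_per_pixel(bits_stored: int) -> int:
    return 2 if bits_stored > 8 else 1


#: default bbox padding: keeps near-boundary anatomy inside the lossless crop
DEFAULT_BBOX_PAD = 2


def compress_image(
    rec: ImageRecord,
    seg: SegmentationParams | None = None,
    atlas: FontAtlas = DEFAULT_ATLAS,
    whitelist: tuple[str, ...] = METADATA_WHITELIST,
    bbox_pad: int = DEFAULT_BBOX_PAD,
) -> CompressedImage:
    """Segment, crop, losslessly encode the ROI, and OCR the non-ROI.

    OCR runs on the complement of the *stored* region (the padded bbox
    rectangle), not of the raw mask: every pixel inside the bbox survives
    losslessly in the crop, so only pixels that will actually be discarded
    are candidates for annotation ink.
    """
    ident = rec.metadata.get("HIMSID", "<no-HIMSID>")
    try:
        roi = segment_roi(rec, seg, pad=bbox_pad)
        r0, c0, r1, c1 = roi.bbox
        crop = rec.pixels[r0:r1, c0:c1]
        stream = jpegls.encode_plane(crop, rec.bits_stored)
        stored = np.zeros_like(roi.mask)
        stored[r0:r1, c0:c1] = True
        runs = extract_runs(rec, stored, atlas)
    except RoipackError as exc:
        raise type(exc)(f"image {ident}: {exc}") from exc
    log.debug(
        "compressed image %s: bbox=%s roi_stream=%dB runs=%d (%d iters)",
        ident, roi.bbox, len(stream), len(runs), roi.iterations,
    )
    return CompressedImage(
        roi_stream=stream,
        bbox=roi.bbox,
        rows=rec.rows,
        cols=rec.cols,
        bits_stored=rec.bits_stored,
        runs=runs,
        metadata={k: v for k, v in rec.metadata.items() if k in whitelist},
    )


def compress_package(
    recs: list[ImageRecord],
    seg: SegmentationParams | None = None,
    atlas: FontAtlas = DEFAULT_ATLAS,
    workers: int = 1,
    whitelist: tuple[str, ...] = METADATA_WHITELIST,
) -> bytes:
    """Map ``compress_image`` over the records (up to ``workers`` at a time)
    and reduce into one package; output bytes are order-deterministic."""
    if not recs:
        raise ConsistencyError("a package needs at least one image")
    if workers < 1:
        raise ValueError("workers must be >= 1")

    def task(item: tuple[int, ImageRecord]) -> CompressedImage:
        idx, rec = item
        try:
            return compress_image(rec, seg, atlas, whitelist)
        except RoipackError as exc:
            raise type(exc)(f"package image #{idx}: {exc}") from exc

    if workers == 1:
        entries = [task(item) for item in enumerate(recs)]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            entries = list(pool.map(task, enumerate(recs)))
    return container.write_package(entries)


def reconstruct_package(
    package: bytes, atlas: FontAtlas = DEFAULT_ATLAS
) -> list[ImageRecord]:
    """Reverse the preprocessing: black canvas of the original size,
    re-rendered annotation runs, decoded ROI crop pasted at its bbox."""
    entries = container.read_package(package)
    out: list[ImageRecord] = []
    for i, e in enumerate(entries):
        dtype = np.uint16 if e.bits_stored > 8 else np.uint8
        canvas = np.zeros((e.rows, e.cols), dtype=dtype)
        for run in e.runs:
            h, w = run.extent(atlas)
            if run.anchor[0] + h > e.rows or run.anchor[1] + w > e.cols:
                raise ConsistencyError(
                    f"image {i}: run {run.text!r} at {run.anchor} outside frame"
                )
            canvas = render_text(canvas, run, atlas)
        crop = jpegls.decode_plane(e.roi_stream)
        r0, c0, r1, c1 = e.bbox
        if crop.shape != (r1 - r0, c1 - c0):
            raise ConsistencyError(
                f"image {i}: roi stream decodes to {crop.shape}, bbox is {e.bbox}"
            )
        canvas[r0:r1, c0:c1] = crop
        out.append(
            ImageRecord(pixels=canvas, bits_stored=e.bits_stored, metadata=dict(e.metadata))
        )
    return out


def reconstruct_to_dicom(package: bytes, atlas: FontAtlas = DEFAULT_ATLAS) -> list[bytes]:
    """Reconstruct and wrap each image as a DICOM stream."""
    return [write_dicom(rec) for rec in reconstruct_package(package, atlas)]


def compression_metrics(recs: list[ImageRecord], package: bytes) -> Metrics:
    """Byte accounting of a package against the original records.

    ROI original bytes are the bbox crop at raw depth; non-ROI original
    bytes are the complement of the bbox.  Compressed ROI bytes are the
    per-image ROI sections (stream + record header); compressed non-ROI
    bytes are the codebook and coded-text sections, apportioned equally
    per image in the breakdown.  Totals use the whole package length, so
    ROI + non-ROI + fixed framing overhead equals the total exactly.
    """
    entries = container.read_package(package)
    if len(entries) != len(recs):
        raise ConsistencyError(
            f"package holds {len(entries)} images, {len(recs)} originals given"
        )
    sections = container.section_map(package)
    nonroi_comp = sections["codebook"][1] + sections["text"][1]
    n = len(entries)

    roi_orig = 0.0
    roi_comp = 0.0
    nonroi_orig = 0.0
    per_image: list[dict] = []
    for rec, e in zip(recs, entries):
        bpp = _bytes_per_pixel(e.bits_stored)
        r0, c0, r1, c1 = e.bbox
        bbox_px = (r1 - r0) * (c1 - c0)
        frame_px = e.rows * e.cols
        i_roi_orig = bbox_px * bpp
        i_nonroi_orig = (frame_px - bbox_px) * bpp
        i_roi_comp = len(e.roi_stream) + container.IMAGE_HEADER_BYTES
        i_nonroi_comp = nonroi_comp / n
        roi_orig += i_roi_orig
        roi_comp += i_roi_comp
        nonroi_orig += i_nonroi_orig
        per_image.append(
            {
                "hims_id": e.metadata.get("HIMSID"),
                "roi": SegmentMetrics(i_roi_orig, i_roi_comp),
                "non_roi": SegmentMetrics(i_nonroi_orig, i_nonroi_comp),
                "total": SegmentMetrics(
                    i_roi_orig + i_nonroi_orig, i_roi_comp + i_nonroi_comp
                ),
            }
        )
    total_orig = roi_orig + nonroi_orig
    return Metrics(
        roi=SegmentMetrics(roi_orig, roi_comp),
        non_roi=SegmentMetrics(nonroi_orig, nonroi_comp),
        total=SegmentMetrics(total_orig, float(len(package))),
        per_image=per_image,
    )
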