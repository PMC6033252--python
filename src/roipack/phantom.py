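"""Synthetic DICOM-wrapped MR-like phantoms with ground truth.

Every downstream module (segmentation, codec, OCR, pipeline, archive) is
exercised against these phantoms, so the generator records exact ground
truth: the ROI mask, the rendered text runs, and the realised ROI area
fraction.  A phantom is:

* a smooth "anatomy" blob region — a sum of 2-5 random Gaussian bumps
  thresholded at the exact quantile that realises the requested ROI area
  fraction — mapped to bright grey levels (40-85% of range);
* a near-black background at ``background_level``;
* burned-in annotation lines stamped from the shared 5x7 bitmap font in
  the top margin, strictly disjoint from the ROI;
* optional additive Gaussian noise, by default confined to the ROI so the
  background stays exactly clean (``noise_global`` adds it everywhere).

Generation is a pure function of the spec: identical specs give
bit-identical phantoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .dicom_io import ImageRecord, write_dicom
from .errors import CompletenessError, SizingError, UnsupportedCharacterError
from .font import DEFAULT_ATLAS, FontAtlas
from .ocr import TextRun

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "render_text",
    "wrap_dicom",
    "ground_truth_to_json",
    "ground_truth_from_json",
]

_REQUIRED_DICOM_FIELDS = (
    "PatientName",
    "PatientSurname",
    "CitizenshipID",
    "StudyDate",
    "HIMSID",
)

#: line pitch: glyph height 7 + 2 blank rows
_LINE_PITCH = 9
_TEXT_MARGIN = 2

DEFAULT_TEXT_LINES = (
    "PATIENT 12345",
    "STUDY 2016-01-01",
    "MR BRAIN AX T1",
)


@dataclass(frozen=True)
class PhantomSpec:
    rows: int = 256
    cols: int = 256
    bits_stored: int = 16
    roi_fraction: float = 0.3284
    noise_sigma: float = 64.0
    text_lines: tuple[str, ...] = DEFAULT_TEXT_LINES
    text_intensity: int | None = None  # None -> max grey level
    background_level: int = 0
    seed: int = 0
    noise_global: bool = False

    def __post_init__(self) -> None:
        if self.rows < 32 or self.cols < 32:
            raise SizingError("frame must be at least 32x32")
        if not (8 <= self.bits_stored <= 16):
            raise ValueError("bits_stored must lie in [8, 16]")
        if not (0.0 < self.roi_fraction < 1.0):
            raise ValueError("roi_fraction must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        maxval = (1 << self.bits_stored) - 1
        if self.text_intensity is not None and not (0 <= self.text_intensity <= maxval):
            raise ValueError("text_intensity exceeds the bit depth")
        if not (0 <= self.background_level <= maxval):
            raise ValueError("background_level exceeds the bit depth")

    @property
    def maxval(self) -> int:
        return (1 << self.bits_stored) - 1

    @property
    def resolved_text_intensity(self) -> int:
        return self.maxval if self.text_intensity is None else self.text_intensity


@dataclass
class GroundTruth:
    roi_mask: np.ndarray
    text_runs: list[TextRun]
    roi_area_fraction: float


def render_text(image: np.ndarray, run: TextRun, font: FontAtlas = DEFAULT_ATLAS) -> np.ndarray:
    """Stamp the run's glyphs at monospaced advance; returns a modified copy."""
    out = np.array(image, copy=True)
    r0, c0 = run.anchor
    h, w = run.extent(font)
    if r0 + h > out.shape[0] or c0 + w > out.shape[1]:
        raise ValueError(f"run {run.text!r} at {run.anchor} does not fit in frame")
    for j, ch in enumerate(run.text):
        glyph = font.glyph(ch)
        cs = c0 + j * font.advance
        block = out[r0 : r0 + font.height, cs : cs + font.width]
        block[glyph] = run.intensity
    return out


def _blob_field(rng: np.random.Generator, rows: int, cols: int,
                r_lo: int, r_hi: int, c_lo: int, c_hi: int) -> np.ndarray:
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    n_blobs = int(rng.integers(2, 6))
    field_sum = np.zeros((rows, cols))
    span_r = r_hi - r_lo
    span_c = c_hi - c_lo
    for _ in range(n_blobs):
        cy = rng.uniform(r_lo + 0.25 * span_r, r_hi - 0.25 * span_r)
        cx = rng.uniform(c_lo + 0.25 * span_c, c_hi - 0.25 * span_c)
        sy = rng.uniform(span_r / 8.0, span_r / 3.5)
        sx = rng.uniform(span_c / 8.0, span_c / 3.5)
        amp = rng.uniform(0.5, 1.0)
        field_sum += amp * np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2) / 2.0)
    return field_sum


def generate_phantom(spec: PhantomSpec, atlas: FontAtlas = DEFAULT_ATLAS
                     ) -> tuple[ImageRecord, GroundTruth]:
    """Deterministically synthesize one phantom and its ground truth."""
    rows, cols, maxval = spec.rows, spec.cols, spec.maxval
    lines = tuple(line.strip() for line in spec.text_lines)
    for line in lines:
        if line and not atlas.supports(line):
            bad = next(ch for ch in line if ch not in atlas.glyphs)
            raise UnsupportedCharacterError(f"character {bad!r} not in atlas")
    n_lines = len([ln for ln in lines if ln])

    # text band at the top; anatomy restricted to the remaining box
    margin_top = _TEXT_MARGIN + n_lines * _LINE_PITCH + 2
    r_lo, r_hi = margin_top, rows - 3
    c_lo, c_hi = 3, cols - 3
    allowed = (r_hi - r_lo) * (c_hi - c_lo)
    target = int(round(spec.roi_fraction * rows * cols))
    if target > 0.92 * allowed or r_hi - r_lo < 8:
        raise SizingError(
            f"roi_fraction {spec.roi_fraction} cannot fit beside {n_lines} "
            f"text lines in a {rows}x{cols} frame"
        )
    for i, line in enumerate(lines):
        if not line:
            continue
        width = atlas.advance * (len(line) - 1) + atlas.width
        if _TEXT_MARGIN + width > cols:
            raise SizingError(f"text line {line!r} too wide for frame")

    rng = np.random.default_rng(spec.seed)
    field_sum = _blob_field(rng, rows, cols, r_lo, r_hi, c_lo, c_hi)
    window = np.full((rows, cols), -np.inf)
    window[r_lo:r_hi, c_lo:c_hi] = field_sum[r_lo:r_hi, c_lo:c_hi]
    flat = window.ravel()
    thr = np.partition(flat, flat.size - target)[flat.size - target]
    mask = window >= thr

    image = np.full((rows, cols), float(spec.background_level))
    peak = float(window[mask].max())
    rel = (window[mask] - thr) / max(peak - thr, 1e-12)
    lo_level, hi_level = 0.40 * maxval, 0.85 * maxval
    image[mask] = lo_level + rel * (hi_level - lo_level)

    if spec.noise_sigma > 0:
        if spec.noise_global:
            image += rng.normal(0.0, spec.noise_sigma, image.shape)
        else:
            image[mask] += rng.normal(0.0, spec.noise_sigma, int(mask.sum()))
    image = np.clip(np.rint(image), 0, maxval)

    runs: list[TextRun] = []
    row_cursor = _TEXT_MARGIN
    intensity = spec.resolved_text_intensity
    for line in lines:
        if line:
            runs.append(TextRun(text=line, anchor=(row_cursor, _TEXT_MARGIN),
                                intensity=intensity, font_id=atlas.font_id))
        row_cursor += _LINE_PITCH
    for run in runs:
        image = render_text(image, run, atlas)

    rec = ImageRecord(
        pixels=image.astype(np.uint16 if spec.bits_stored > 8 else np.uint8),
        bits_stored=spec.bits_stored,
        metadata={},
    )
    truth = GroundTruth(
        roi_mask=mask,
        text_runs=runs,
        roi_area_fraction=float(mask.sum()) / (rows * cols),
    )
    return rec, truth


def wrap_dicom(rec: ImageRecord, metadata: dict[str, str]) -> bytes:
    """Attach patient metadata and serialize to DICOM bytes.

    Requires the five archival fields (name, surname, citizenship id,
    study date, HIMS ID); pixel data round-trips bit-exactly through
    :mod:`roipack.dicom_io`.
    """
    missing = [k for k in _REQUIRED_DICOM_FIELDS if k not in metadata]
    if missing:
        raise CompletenessError(f"metadata lacks required fields: {missing}")
    merged = dict(rec.metadata)
    merged.update(metadata)
    return write_dicom(replace_metadata(rec, merged))


def replace_metadata(rec: ImageRecord, metadata: dict[str, str]) -> ImageRecord:
    return ImageRecord(pixels=rec.pixels, bits_stored=rec.bits_stored, metadata=metadata)


def _mask_rle(mask: np.ndarray) -> list[int]:
    """Row-major run lengths, starting with a (possibly zero) run of False."""
    flat = np.asarray(mask, dtype=bool).ravel()
    changes = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    lengths = [int(v) for v in np.diff(bounds)]
    return [0] + lengths if flat[0] else lengths


def ground_truth_to_json(truth: GroundTruth) -> str:
    mask = truth.roi_mask
    return json.dumps(
        {
            "shape": list(mask.shape),
            "mask_rle": _mask_rle(mask),
            "roi_area_fraction": truth.roi_area_fraction,
            "runs": [
                {
                    "text": r.text,
                    "row": r.anchor[0],
                    "col": r.anchor[1],
                    "intensity": r.intensity,
                    "font_id": r.font_id,
                }
                for r in truth.text_runs
            ],
        },
        sort_keys=True,
    )


def ground_truth_from_json(text: str) -> GroundTruth:
    obj = json.loads(text)
    shape = tuple(obj["shape"])
    flat = np.zeros(shape[0] * shape[1], dtype=bool)
    pos = 0
    val = False
    for run_len in obj["mask_rle"]:
        if val:
            flat[pos : pos + run_len] = True
        pos += run_len
        val = not val
    runs = [
        TextRun(text=r["text"], anchor=(r["row"], r["col"]),
                intensity=r["intensity"], font_id=r["font_id"])
        for r in obj["runs"]
    ]
    return GroundTruth(
        roi_mask=flat.reshape(shape),
        text_runs=runs,
        roi_area_fraction=obj["roi_area_fraction"],
    )
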