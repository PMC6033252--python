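"""Burned-in annotation extraction from the non-ROI region.

This is deterministic template-matching OCR against a known bitmap font
atlas, not a general OCR engine: the discarded background can only be
regenerated if text recovery is *exactly* invertible, and a font-exact
scheme is the only way to guarantee that.  The extraction pipeline is:

1. binarise the non-ROI pixels (Otsu with an absolute intensity floor,
   both overridable);
2. group connected ink components into horizontal text bands by vertical
   overlap of their bounding boxes;
3. for each band, search the small set of candidate glyph-grid origins and
   keep the one whose cells have the lowest total Hamming distance to the
   atlas (an exact render always scores zero at the true origin);
4. match each cell to its nearest glyph; a blank cell is a space, and a
   cell farther than ``max_distance`` from every glyph flags the run as
   unmatched rather than being dropped.

Runs are returned top-to-bottom, left-to-right with exact anchors and the
median ink intensity, which is what reconstruction re-renders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .font import DEFAULT_ATLAS, FontAtlas

__all__ = ["TextRun", "extract_runs", "match_glyph"]

#: cells farther than this (of height*width bits) from every glyph flag the run
DEFAULT_MAX_DISTANCE = 8

#: absolute binarisation floor as a fraction of the full intensity range
DEFAULT_FLOOR_FRACTION = 0.25


@dataclass(frozen=True)
class TextRun:
    """One annotation string anchored at the top-left pixel of its first glyph."""

    text: str
    anchor: tuple[int, int]
    intensity: int
    font_id: str = DEFAULT_ATLAS.font_id
    unmatched: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("run text must be non-empty")
        if self.anchor[0] < 0 or self.anchor[1] < 0:
            raise ValueError("anchor must lie inside the frame")

    def extent(self, atlas: FontAtlas = DEFAULT_ATLAS) -> tuple[int, int]:
        """(height, width) of the rendered run in pixels."""
        return (atlas.height, atlas.advance * (len(self.text) - 1) + atlas.width)


def match_glyph(cell: np.ndarray, atlas: FontAtlas = DEFAULT_ATLAS) -> tuple[str, int]:
    """Nearest atlas glyph by Hamming distance; ties break on the lower code
    point.  An all-blank cell matches the space glyph at distance 0."""
    cell = np.asarray(cell, dtype=bool)
    if cell.shape != (atlas.height, atlas.width):
        raise ValueError(f"cell shape {cell.shape} != glyph shape")
    best: tuple[int, str] | None = None
    for ch in sorted(atlas.glyphs):
        dist = int(np.count_nonzero(cell != atlas.glyphs[ch]))
        if best is None or dist < best[0]:
            best = (dist, ch)
    assert best is not None
    return best[1], best[0]


def _band_groups(labels: np.ndarray, n: int) -> list[list[int]]:
    """Group component ids into text bands by vertical-interval overlap."""
    objs = ndimage.find_objects(labels)
    spans = []
    for i in range(n):
        sl = objs[i]
        spans.append((sl[0].start, sl[0].stop, i + 1))
    spans.sort()
    bands: list[list[int]] = []
    cur: list[int] = []
    cur_stop = -1
    for top, stop, lab in spans:
        if cur and top >= cur_stop:
            bands.append(cur)
            cur = []
            cur_stop = -1
        cur.append(lab)
        cur_stop = max(cur_stop, stop)
    if cur:
        bands.append(cur)
    return bands


def _decode_band(
    ink: np.ndarray,
    band_mask: np.ndarray,
    atlas: FontAtlas,
    max_distance: int,
) -> tuple[int, int, list[str], list[int]] | None:
    """Best glyph-grid interpretation of one band of ink.

    Returns (row0, col0, characters, per-cell distances)."""
    rows = np.flatnonzero(band_mask.any(axis=1))
    cols = np.flatnonzero(band_mask.any(axis=0))
    top, bottom = int(rows[0]), int(rows[-1])
    left, right = int(cols[0]), int(cols[-1])
    gh, gw, adv = atlas.height, atlas.width, atlas.advance
    frame_r, frame_c = band_mask.shape

    glyph_list = sorted(atlas.glyphs)
    stacks = np.stack([atlas.glyphs[ch] for ch in glyph_list])  # (G, gh, gw)

    best: tuple[int, int, int, list[str], list[int]] | None = None
    for r0 in range(max(0, top - gh + 1), top + 1):
        if r0 + gh > frame_r:
            continue
        for c0 in range(max(0, left - gw + 1), left + 1):
            n_cells = (right - c0) // adv + 1
            if c0 + (n_cells - 1) * adv + gw > frame_c:
                continue
            total = 0
            chars: list[str] = []
            dists: list[int] = []
            for j in range(n_cells):
                cs = c0 + j * adv
                cell = band_mask[r0 : r0 + gh, cs : cs + gw]
                d = np.count_nonzero(cell[None, :, :] != stacks, axis=(1, 2))
                gi = int(np.argmin(d))
                chars.append(glyph_list[gi])
                dists.append(int(d[gi]))
                total += int(d[gi])
            # penalise ink outside all cells (misaligned grid leaves stragglers)
            covered = np.zeros_like(band_mask)
            covered[r0 : r0 + gh, c0 : c0 + n_cells * adv] = True
            total += int(np.count_nonzero(band_mask & ~covered)) * 2
            key = (total, r0, c0)
            if best is None or key < (best[0], best[1], best[2]):
                best = (total, r0, c0, chars, dists)
            if total == 0:
                break
        if best is not None and best[0] == 0:
            break
    if best is None:
        return None
    _, r0, c0, chars, dists = best
    return r0, c0, chars, dists


def extract_runs(
    image,
    roi_mask: np.ndarray,
    atlas: FontAtlas = DEFAULT_ATLAS,
    *,
    threshold: float | None = None,
    floor_fraction: float = DEFAULT_FLOOR_FRACTION,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[TextRun]:
    """Extract annotation runs from the non-ROI region of ``image``.

    ``image`` is an ImageRecord or bare array; ``roi_mask`` pixels are never
    touched, so no ROI content can leak into a run.
    """
    pixels = np.asarray(getattr(image, "pixels", image))
    bits = getattr(image, "bits_stored", None)
    maxrange = (1 << bits) - 1 if bits else max(int(pixels.max()), 1)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != pixels.shape:
        raise ValueError("roi_mask shape does not match image")

    nonroi = pixels[~roi_mask]
    if nonroi.size == 0:
        return []
    if threshold is None:
        floor = floor_fraction * maxrange
        vals = nonroi.astype(np.float64)
        thr = float(threshold_otsu(vals)) if vals.min() != vals.max() else floor
        threshold = max(thr, floor)

    ink = (pixels > threshold) & ~roi_mask
    if not ink.any():
        return []
    # 8-connectivity: glyph rings ('0', 'O') touch only diagonally in places
    labels, n = ndimage.label(ink, structure=np.ones((3, 3), dtype=bool))

    runs: list[TextRun] = []
    for band in _band_groups(labels, n):
        band_mask = np.isin(labels, band)
        decoded = _decode_band(ink, band_mask, atlas, max_distance)
        if decoded is None:
            continue
        r0, c0, chars, dists = decoded
        # trim leading/trailing spaces off the grid
        first = next((i for i, ch in enumerate(chars) if ch != " "), None)
        if first is None:
            continue
        last = max(i for i, ch in enumerate(chars) if ch != " ")
        text = "".join(chars[first : last + 1])
        anchor = (r0, c0 + first * atlas.advance)
        ink_vals = pixels[band_mask]
        intensity = int(np.median(ink_vals))
        unmatched = any(d > max_distance for d in dists[first : last + 1])
        runs.append(
            TextRun(
                text=text,
                anchor=anchor,
                intensity=intensity,
                font_id=atlas.font_id,
                unmatched=unmatched,
            )
        )
    runs.sort(key=lambda r: r.anchor)
    return runs
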