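"""Fixed 5x7 monospaced bitmap font used for burned-in annotations.

The same atlas is used to render annotation text onto phantoms and to
recognise it again by template matching, which is what makes the
text-extraction loop exactly invertible: there is never any doubt about
which glyph produced a given pixel pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UnsupportedCharacterError

GLYPH_HEIGHT = 7
GLYPH_WIDTH = 5
ADVANCE = 6  # glyph width + 1 blank column

# Rows top-to-bottom, 5 bits each, MSB = leftmost column.
_GLYPH_ROWS: dict[str, tuple[int, ...]] = {
    " ": (0x00, 0x00, 0x00, 0x00, 0x00, 0x00, 0x00),
    "A": (0x0E, 0x11, 0x11, 0x1F, 0x11, 0x11, 0x11),
    "B": (0x1E, 0x11, 0x11, 0x1E, 0x11, 0x11, 0x1E),
    "C": (0x0E, 0x11, 0x10, 0x10, 0x10, 0x11, 0x0E),
    "D": (0x1E, 0x11, 0x11, 0x11, 0x11, 0x11, 0x1E),
    "E": (0x1F, 0x10, 0x10, 0x1E, 0x10, 0x10, 0x1F),
    "F": (0x1F, 0x10, 0x10, 0x1E, 0x10, 0x10, 0x10),
    "G": (0x0E, 0x11, 0x10, 0x17, 0x11, 0x11, 0x0F),
    "H": (0x11, 0x11, 0x11, 0x1F, 0x11, 0x11, 0x11),
    "I": (0x0E, 0x04, 0x04, 0x04, 0x04, 0x04, 0x0E),
    "J": (0x07, 0x02, 0x02, 0x02, 0x02, 0x12, 0x0C),
    "K": (0x11, 0x12, 0x14, 0x18, 0x14, 0x12, 0x11),
    "L": (0x10, 0x10, 0x10, 0x10, 0x10, 0x10, 0x1F),
    "M": (0x11, 0x1B, 0x15, 0x15, 0x11, 0x11, 0x11),
    "N": (0x11, 0x19, 0x15, 0x13, 0x11, 0x11, 0x11),
    "O": (0x0E, 0x11, 0x11, 0x11, 0x11, 0x11, 0x0E),
    "P": (0x1E, 0x11, 0x11, 0x1E, 0x10, 0x10, 0x10),
    "Q": (0x0E, 0x11, 0x11, 0x11, 0x15, 0x12, 0x0D),
    "R": (0x1E, 0x11, 0x11, 0x1E, 0x14, 0x12, 0x11),
    "S": (0x0F, 0x10, 0x10, 0x0E, 0x01, 0x01, 0x1E),
    "T": (0x1F, 0x04, 0x04, 0x04, 0x04, 0x04, 0x04),
    "U": (0x11, 0x11, 0x11, 0x11, 0x11, 0x11, 0x0E),
    "V": (0x11, 0x11, 0x11, 0x11, 0x11, 0x0A, 0x04),
    "W": (0x11, 0x11, 0x11, 0x15, 0x15, 0x1B, 0x11),
    "X": (0x11, 0x11, 0x0A, 0x04, 0x0A, 0x11, 0x11),
    "Y": (0x11, 0x11, 0x0A, 0x04, 0x04, 0x04, 0x04),
    "Z": (0x1F, 0x01, 0x02, 0x04, 0x08, 0x10, 0x1F),
    "0": (0x0E, 0x11, 0x13, 0x15, 0x19, 0x11, 0x0E),
    "1": (0x04, 0x0C, 0x04, 0x04, 0x04, 0x04, 0x0E),
    "2": (0x0E, 0x11, 0x01, 0x02, 0x04, 0x08, 0x1F),
    "3": (0x1F, 0x02, 0x04, 0x02, 0x01, 0x11, 0x0E),
    "4": (0x02, 0x06, 0x0A, 0x12, 0x1F, 0x02, 0x02),
    "5": (0x1F, 0x10, 0x1E, 0x01, 0x01, 0x11, 0x0E),
    "6": (0x06, 0x08, 0x10, 0x1E, 0x11, 0x11, 0x0E),
    "7": (0x1F, 0x01, 0x02, 0x04, 0x08, 0x08, 0x08),
    "8": (0x0E, 0x11, 0x11, 0x0E, 0x11, 0x11, 0x0E),
    "9": (0x0E, 0x11, 0x11, 0x0F, 0x01, 0x02, 0x0C),
    "-": (0x00, 0x00, 0x00, 0x0E, 0x00, 0x00, 0x00),
    ".": (0x00, 0x00, 0x00, 0x00, 0x00, 0x0C, 0x0C),
    ":": (0x00, 0x0C, 0x0C, 0x00, 0x0C, 0x0C, 0x00),
    "/": (0x01, 0x01, 0x02, 0x04, 0x08, 0x10, 0x10),
    ",": (0x00, 0x00, 0x00, 0x00, 0x0C, 0x04, 0x08),
}


def _rows_to_bitmap(rows: tuple[int, ...]) -> np.ndarray:
    out = np.zeros((GLYPH_HEIGHT, GLYPH_WIDTH), dtype=bool)
    for r, bits in enumerate(rows):
        for c in range(GLYPH_WIDTH):
            out[r, c] = bool((bits >> (GLYPH_WIDTH - 1 - c)) & 1)
    return out


@dataclass(frozen=True)
class FontAtlas:
    """Monospaced glyph set: every glyph is ``height`` x ``width`` pixels and
    consecutive glyphs are stamped ``advance`` columns apart."""

    font_id: str
    glyphs: dict[str, np.ndarray] = field(repr=False)
    height: int = GLYPH_HEIGHT
    width: int = GLYPH_WIDTH
    advance: int = ADVANCE

    def __post_init__(self) -> None:
        seen: dict[bytes, str] = {}
        for ch, bm in self.glyphs.items():
            if bm.shape != (self.height, self.width):
                raise ValueError(f"glyph {ch!r} has shape {bm.shape}")
            key = bm.tobytes()
            if key in seen and ch != seen[key]:
                raise ValueError(f"glyphs {seen[key]!r} and {ch!r} are identical")
            seen[key] = ch

    def glyph(self, ch: str) -> np.ndarray:
        try:
            return self.glyphs[ch]
        except KeyError:
            raise UnsupportedCharacterError(
                f"character {ch!r} is not in font atlas {self.font_id!r}"
            ) from None

    def supports(self, text: str) -> bool:
        return all(ch in self.glyphs for ch in text)

    @property
    def characters(self) -> str:
        return "".join(sorted(self.glyphs))


DEFAULT_ATLAS = FontAtlas(
    font_id="roipack-5x7",
    glyphs={ch: _rows_to_bitmap(rows) for ch, rows in _GLYPH_ROWS.items()},
)
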