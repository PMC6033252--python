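"""Canonical Huffman codec for the annotation-text payload.

The codebook is built with the classic two-queue/heap construction on byte
frequencies and then *canonicalized*: codes are reassigned from the sorted
(length, symbol) order, so the serialized form only needs to store code
lengths.  Tie-breaking during tree construction is fully deterministic
(lowest total frequency first, then lowest minimum symbol value), so the
same payload always yields byte-identical codebooks and bitstreams.

A single-symbol alphabet is the one case where a Huffman tree degenerates;
that symbol is assigned the 1-bit code ``0`` so the round trip still works
(the Kraft sum is then 1/2 instead of 1, documented exception).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from functools import cached_property

from .errors import CoverageError, EmptyPayloadError, StructureError, TruncationError

__all__ = [
    "HuffmanCodebook",
    "build_codebook",
    "encode",
    "decode",
    "serialize_codebook",
    "deserialize_codebook",
]


@dataclass(frozen=True)
class HuffmanCodebook:
    """Code lengths per byte symbol; canonical codes derive from them."""

    lengths: dict[int, int]

    def __post_init__(self) -> None:
        if not self.lengths:
            raise StructureError("codebook has no symbols")
        for sym, ln in self.lengths.items():
            if not (0 <= sym <= 255):
                raise StructureError(f"symbol {sym} out of byte range")
            if ln < 1:
                raise StructureError(f"symbol {sym} has non-positive length {ln}")

    @property
    def symbol_count(self) -> int:
        return len(self.lengths)

    def kraft_sum(self) -> float:
        return sum(2.0 ** -ln for ln in self.lengths.values())

    @cached_property
    def codes(self) -> dict[int, tuple[int, int]]:
        """symbol -> (code value, code length), canonical order."""
        ordered = sorted(self.lengths.items(), key=lambda kv: (kv[1], kv[0]))
        codes: dict[int, tuple[int, int]] = {}
        code = 0
        prev_len = ordered[0][1]
        for sym, ln in ordered:
            code <<= ln - prev_len
            codes[sym] = (code, ln)
            prev_len = ln
            code += 1
        return codes

    @cached_property
    def _decode_table(self) -> dict[tuple[int, int], int]:
        return {(ln, code): sym for sym, (code, ln) in self.codes.items()}


def build_codebook(payload: bytes) -> HuffmanCodebook:
    """Optimal prefix-code lengths for the byte frequencies of ``payload``."""
    if len(payload) == 0:
        raise EmptyPayloadError("cannot build a codebook from an empty payload")
    freqs: dict[int, int] = {}
    for b in payload:
        freqs[b] = freqs.get(b, 0) + 1
    if len(freqs) == 1:
        return HuffmanCodebook(lengths={next(iter(freqs)): 1})
    # heap items: (frequency, min symbol in subtree, list of (symbol, depth))
    heap: list[tuple[int, int, list[tuple[int, int]]]] = [
        (f, s, [(s, 0)]) for s, f in sorted(freqs.items())
    ]
    heapq.heapify(heap)
    while len(heap) > 1:
        f1, m1, l1 = heapq.heappop(heap)
        f2, m2, l2 = heapq.heappop(heap)
        merged = [(s, d + 1) for s, d in l1] + [(s, d + 1) for s, d in l2]
        heapq.heappush(heap, (f1 + f2, min(m1, m2), merged))
    _, _, leaves = heap[0]
    return HuffmanCodebook(lengths={s: d for s, d in leaves})


def encode(payload: bytes, book: HuffmanCodebook) -> tuple[bytes, int]:
    """Concatenate canonical codes; returns (zero-padded bytes, exact bit count)."""
    codes = book.codes
    acc = 0
    nbits = 0
    for b in payload:
        try:
            code, ln = codes[b]
        except KeyError:
            raise CoverageError(f"symbol {b} not present in codebook") from None
        acc = (acc << ln) | code
        nbits += ln
    nbytes = (nbits + 7) // 8
    acc <<= nbytes * 8 - nbits
    return acc.to_bytes(nbytes, "big"), nbits


def decode(bits: bytes, bit_count: int, book: HuffmanCodebook) -> bytes:
    """Exact inverse of :func:`encode`."""
    if bit_count < 0 or bit_count > len(bits) * 8:
        raise TruncationError(
            f"bit count {bit_count} inconsistent with {len(bits)} payload bytes"
        )
    table = book._decode_table
    max_len = max(book.lengths.values())
    out = bytearray()
    code = 0
    ln = 0
    for i in range(bit_count):
        bit = (bits[i >> 3] >> (7 - (i & 7))) & 1
        code = (code << 1) | bit
        ln += 1
        sym = table.get((ln, code))
        if sym is not None:
            out.append(sym)
            code = 0
            ln = 0
        elif ln > max_len:
            raise TruncationError("bitstream does not align with any code")
    if ln != 0:
        raise TruncationError("bitstream exhausted mid-code")
    return bytes(out)


def serialize_codebook(book: HuffmanCodebook) -> bytes:
    """Layout: one byte holding symbol_count - 1, then (symbol, length) byte
    pairs in ascending symbol order."""
    out = bytearray([book.symbol_count - 1])
    for sym in sorted(book.lengths):
        ln = book.lengths[sym]
        if ln > 255:
            raise StructureError(f"code length {ln} does not fit in one byte")
        out.append(sym)
        out.append(ln)
    return bytes(out)


def deserialize_codebook(data: bytes) -> HuffmanCodebook:
    if len(data) < 1:
        raise StructureError("empty codebook serialization")
    count = data[0] + 1
    if len(data) != 1 + 2 * count:
        raise StructureError(
            f"codebook declares {count} symbols but carries {len(data) - 1} pair bytes"
        )
    lengths: dict[int, int] = {}
    prev_sym = -1
    for i in range(count):
        sym = data[1 + 2 * i]
        ln = data[2 + 2 * i]
        if sym <= prev_sym:
            raise StructureError("codebook symbols not strictly ascending")
        if ln < 1:
            raise StructureError(f"symbol {sym} has zero code length")
        lengths[sym] = ln
        prev_sym = sym
    book = HuffmanCodebook(lengths=lengths)
    kraft = book.kraft_sum()
    if count >= 2 and abs(kraft - 1.0) > 1e-9:
        raise StructureError(f"code lengths violate the Kraft equality (sum {kraft})")
    return book
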