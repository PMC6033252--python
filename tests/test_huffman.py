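"""Canonical Huffman codec: optimality, round trips, serialization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roipack import huffman
from roipack.errors import (
    CoverageError,
    EmptyPayloadError,
    StructureError,
    TruncationError,
)


def exhaustive_optimal_cost(freqs: list[int]) -> int:
    """Brute-force minimum of sum(f*l) over all prefix codes.

    An optimal prefix code can always be taken with lengths monotonically
    non-increasing in frequency and Kraft sum <= 1, so enumerating
    non-decreasing length vectors against descending frequencies is an
    exhaustive search for small alphabets.
    """
    n = len(freqs)
    if n == 1:
        return freqs[0]
    fs = sorted(freqs, reverse=True)
    best = None
    max_len = n - 1
    for lengths in itertools.product(range(1, max_len + 1), repeat=n):
        if any(lengths[i] > lengths[i + 1] for i in range(n - 1)):
            continue
        if sum(2.0 ** -l for l in lengths) > 1.0 + 1e-12:
            continue
        cost = sum(f * l for f, l in zip(fs, lengths))
        if best is None or cost < best:
            best = cost
    return best


def coded_bits(payload: bytes) -> int:
    book = huffman.build_codebook(payload)
    _, nbits = huffman.encode(payload, book)
    return nbits


class TestCodebook:
    def test_known_payload_is_coded_at_the_brute_force_optimum(self):
        # 5 symbols, frequencies 5/2/2/1/1: optimal cost is 23 bits
        payload = b"abracadabra"
        freqs = [payload.count(bytes([s])) for s in set(payload)]
        assert exhaustive_optimal_cost(freqs) == 23
        assert coded_bits(payload) == 23

    def test_single_symbol_degenerates_to_one_bit_codes(self):
        book = huffman.build_codebook(b"aaaa")
        assert book.lengths == {ord("a"): 1}
        coded, nbits = huffman.encode(b"aaaa", book)
        assert nbits == 4
        assert huffman.decode(coded, nbits, book) == b"aaaa"

    def test_uniform_four_symbol_alphabet_gets_flat_two_bit_codes(self):
        book = huffman.build_codebook(b"abcdabcdabcd")
        assert sorted(book.lengths.values()) == [2, 2, 2, 2]

    def test_empty_payload_is_rejected(self):
        with pytest.raises(EmptyPayloadError):
            huffman.build_codebook(b"")

    def test_kraft_equality_holds_for_multi_symbol_books(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_sym = int(rng.integers(2, 30))
            payload = rng.integers(0, n_sym, int(rng.integers(n_sym, 400))).astype(
                np.uint8
            ).tobytes()
            book = huffman.build_codebook(payload)
            if book.symbol_count >= 2:
                assert book.kraft_sum() == pytest.approx(1.0, abs=1e-12)

    def test_codes_are_prefix_free(self):
        book = huffman.build_codebook(b"the quick brown fox jumps over the lazy dog")
        bitstrings = [format(c, f"0{l}b") for c, l in book.codes.values()]
        for a, b in itertools.permutations(bitstrings, 2):
            assert not b.startswith(a)

    def test_randomized_small_alphabets_match_exhaustive_search(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            n_sym = int(rng.integers(1, 7))
            freqs = [int(rng.integers(1, 21)) for _ in range(n_sym)]
            payload = b"".join(bytes([65 + i]) * f for i, f in enumerate(freqs))
            assert coded_bits(payload) == exhaustive_optimal_cost(freqs)


class TestEncodeDecode:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.binary(min_size=1, max_size=300))
    def test_decode_inverts_encode(self, payload):
        book = huffman.build_codebook(payload)
        coded, nbits = huffman.encode(payload, book)
        assert huffman.decode(coded, nbits, book) == payload
        # bit count is exactly sum(f_s * l_s)
        assert nbits == sum(book.lengths[b] for b in payload)
        # never expands past the trivial bound
        assert nbits <= 8 * len(payload)

    def test_encoding_nothing_costs_zero_bits(self):
        book = huffman.build_codebook(b"xy")
        coded, nbits = huffman.encode(b"", book)
        assert (coded, nbits) == (b"", 0)

    def test_symbol_outside_book_is_a_coverage_error(self):
        book = huffman.build_codebook(b"ab")
        with pytest.raises(CoverageError):
            huffman.encode(b"abc", book)

    def test_truncated_bitstream_is_detected(self):
        book = huffman.build_codebook(b"abracadabra")
        coded, nbits = huffman.encode(b"abracadabra", book)
        with pytest.raises(TruncationError):
            huffman.decode(coded, nbits + 3, book)


class TestSerialization:
    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.binary(min_size=1, max_size=200))
    def test_serialization_round_trips(self, payload):
        book = huffman.build_codebook(payload)
        again = huffman.deserialize_codebook(huffman.serialize_codebook(book))
        assert again.lengths == book.lengths
        assert again.codes == book.codes

    def test_five_symbol_book_serializes_to_eleven_bytes(self):
        book = huffman.build_codebook(b"abracadabra")  # 5 distinct symbols
        assert book.symbol_count == 5
        assert len(huffman.serialize_codebook(book)) == 1 + 5 * 2

    @pytest.mark.parametrize(
        "garbage",
        [b"", b"\x05", b"\x01abcd", bytes([1, 66, 3, 65, 3]), bytes([1, 65, 0, 66, 1])],
    )
    def test_garbage_serializations_are_structure_errors(self, garbage):
        with pytest.raises(StructureError):
            huffman.deserialize_codebook(garbage)
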