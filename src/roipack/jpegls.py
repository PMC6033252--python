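"""Lossless plane codec implementing the LOCO-I core of JPEG-LS.

The codec follows the LOCO-I design: median-edge-detector (MED) prediction,
context modelling on the quantized gradients (d-b, b-c, c-a) with 9 levels
per gradient folded by sign into 365 regular contexts, per-context bias
correction, Rice mapping of the prediction error, and limited-length
Golomb-Rice entropy coding with an adaptive per-context parameter k.  Run
mode (entered when all three local gradients vanish) is implemented with
the standard MELCODE-style run-length ramp and the two run-interruption
contexts, so flat regions cost far less than one bit per sample.

The stream is deliberately *not* interchange-conformant JPEG-LS: there are
no JPEG markers and the error mapping omits the k==0 bias special case.
Instead each stream carries its own 13-byte header (magic, rows, cols,
bits) followed by the entropy-coded bits.  Losslessness — the only property
the surrounding pipeline relies on — is covered by round-trip tests across
all bit depths.

Encoder and decoder run the identical context state machine; after coding
sample t both sides hold the same A/B/C/N (and run) counters, which the
test-suite asserts through the ``return_state`` hooks.
"""

from __future__ import annotations

import struct

import numpy as np
from numba import njit

from .errors import FormatError, PixelRangeError, TruncationError

__all__ = [
    "med_predict",
    "golomb_rice_encode",
    "golomb_rice_decode",
    "encode_plane",
    "decode_plane",
]

MAGIC = b"JLS1"
_RESET = 64
_MAX_C = 127
_MIN_C = -128

# Run-length code ramp (MELCODE): 2**J[run_index] samples per 1-bit.
_J = np.array(
    [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3,
     4, 4, 5, 5, 6, 6, 7, 7, 8, 9, 10, 11, 12, 13, 14, 15],
    dtype=np.int64,
)


def med_predict(a: int, b: int, c: int) -> int:
    """Median edge detector: picks min/max of (a, b) at an edge, else the
    plane prediction a + b - c."""
    if c >= max(a, b):
        return min(a, b)
    if c <= min(a, b):
        return max(a, b)
    return a + b - c


def golomb_rice_encode(m: int, k: int, limit: int = 64, qbpp: int = 16) -> np.ndarray:
    """Limited-length Golomb-Rice code of the mapped error ``m``.

    Normal form: (m >> k) one-bits, a zero terminator, then the k low bits of
    m.  When the unary part would reach ``limit - qbpp - 1``, escape: that
    many one-bits, the terminator, then m - 1 in ``qbpp`` bits.
    Returns the bits as a 0/1 uint8 array.
    """
    if m < 0:
        raise ValueError("mapped error must be non-negative")
    lim = limit - qbpp - 1
    bits: list[int] = []
    q = m >> k
    if q < lim:
        bits.extend([1] * q)
        bits.append(0)
        for i in range(k - 1, -1, -1):
            bits.append((m >> i) & 1)
    else:
        bits.extend([1] * lim)
        bits.append(0)
        v = m - 1
        for i in range(qbpp - 1, -1, -1):
            bits.append((v >> i) & 1)
    return np.array(bits, dtype=np.uint8)


def golomb_rice_decode(
    bits: np.ndarray, k: int, limit: int = 64, qbpp: int = 16
) -> tuple[int, int]:
    """Inverse of :func:`golomb_rice_encode`; returns (m, bits consumed)."""
    lim = limit - qbpp - 1
    pos = 0
    n = len(bits)
    ones = 0
    while pos < n and bits[pos] == 1:
        ones += 1
        pos += 1
    if pos >= n:
        raise TruncationError("unary prefix not terminated")
    pos += 1  # the zero terminator
    if ones == lim:
        if pos + qbpp > n:
            raise TruncationError("escape payload truncated")
        v = 0
        for i in range(qbpp):
            v = (v << 1) | int(bits[pos + i])
        return v + 1, pos + qbpp
    if pos + k > n:
        raise TruncationError("remainder bits truncated")
    v = 0
    for i in range(k):
        v = (v << 1) | int(bits[pos + i])
    return (ones << k) | v, pos + k


@njit(cache=True)
def _quantize(d, t1, t2, t3):
    if d <= -t3:
        return -4
    if d <= -t2:
        return -3
    if d <= -t1:
        return -2
    if d < 0:
        return -1
    if d == 0:
        return 0
    if d < t1:
        return 1
    if d < t2:
        return 2
    if d < t3:
        return 3
    return 4


@njit(cache=True)
def _neighbors(x, r, c, cols):
    b = x[r - 1, c] if r > 0 else 0
    a = x[r, c - 1] if c > 0 else b
    if r > 0 and c > 0:
        cc = x[r - 1, c - 1]
    elif c == 0 and r >= 2:
        cc = x[r - 2, 0]
    else:
        cc = 0
    if r > 0:
        d = x[r - 1, c + 1] if c + 1 < cols else b
    else:
        d = 0
    return a, b, cc, d


@njit(cache=True)
def _emit_golomb(bits, pos, value, k, lim, qbpp):
    q = value >> k
    if q < lim:
        for _ in range(q):
            bits[pos] = 1
            pos += 1
        bits[pos] = 0
        pos += 1
        for i in range(k - 1, -1, -1):
            bits[pos] = (value >> i) & 1
            pos += 1
    else:
        for _ in range(lim):
            bits[pos] = 1
            pos += 1
        bits[pos] = 0
        pos += 1
        v = value - 1
        for i in range(qbpp - 1, -1, -1):
            bits[pos] = (v >> i) & 1
            pos += 1
    return pos


@njit(cache=True)
def _encode_core(x, maxval, bpp, limit, t1, t2, t3, A, B, C, N, Nn, bits):
    rows, cols = x.shape
    rng = maxval + 1
    half = (rng + 1) // 2
    reg_lim = limit - bpp - 1
    runindex = 0
    pos = 0
    for r in range(rows):
        c = 0
        while c < cols:
            a, b, cc, d = _neighbors(x, r, c, cols)
            d1 = d - b
            d2 = b - cc
            d3 = cc - a
            if d1 == 0 and d2 == 0 and d3 == 0:
                # ---- run mode ----
                runval = a
                runcnt = 0
                while c < cols and x[r, c] == runval:
                    runcnt += 1
                    c += 1
                while runcnt >= (1 << _J[runindex]):
                    bits[pos] = 1
                    pos += 1
                    runcnt -= 1 << _J[runindex]
                    if runindex < 31:
                        runindex += 1
                if c < cols:
                    # interrupted by a different sample
                    bits[pos] = 0
                    pos += 1
                    for i in range(_J[runindex] - 1, -1, -1):
                        bits[pos] = (runcnt >> i) & 1
                        pos += 1
                    xx = x[r, c]
                    b2 = x[r - 1, c] if r > 0 else 0
                    a2 = runval
                    ritype = 1 if a2 == b2 else 0
                    px = a2 if ritype == 1 else b2
                    err = xx - px
                    if ritype == 0 and a2 > b2:
                        err = -err
                    if err < 0:
                        err += rng
                    if err >= half:
                        err -= rng
                    q = 365 + ritype
                    temp = A[q] + (N[q] >> 1 if ritype == 1 else 0)
                    k = 0
                    while (N[q] << k) < temp:
                        k += 1
                    if k == 0 and err > 0 and 2 * Nn[ritype] < N[q]:
                        mp = 1
                    elif err < 0 and 2 * Nn[ritype] >= N[q]:
                        mp = 1
                    elif err < 0 and k != 0:
                        mp = 1
                    else:
                        mp = 0
                    em = 2 * abs(err) - ritype - mp
                    pos = _emit_golomb(bits, pos, em, k, limit - _J[runindex] - 1, bpp)
                    if err < 0:
                        Nn[ritype] += 1
                    A[q] += (em + 1 - ritype) >> 1
                    if N[q] == _RESET:
                        A[q] >>= 1
                        N[q] >>= 1
                        Nn[ritype] >>= 1
                    N[q] += 1
                    if runindex > 0:
                        runindex -= 1
                    c += 1
                else:
                    # run ran to end of line
                    if runcnt > 0:
                        bits[pos] = 1
                        pos += 1
                continue
            # ---- regular mode ----
            q1 = _quantize(d1, t1, t2, t3)
            q2 = _quantize(d2, t1, t2, t3)
            q3 = _quantize(d3, t1, t2, t3)
            idx = 81 * q1 + 9 * q2 + q3
            sign = 1
            if idx < 0:
                sign = -1
                idx = -idx
            # MED prediction
            if cc >= max(a, b):
                px = min(a, b)
            elif cc <= min(a, b):
                px = max(a, b)
            else:
                px = a + b - cc
            px += sign * C[idx]
            if px < 0:
                px = 0
            elif px > maxval:
                px = maxval
            err = x[r, c] - px
            if sign < 0:
                err = -err
            if err < 0:
                err += rng
            if err >= half:
                err -= rng
            k = 0
            while (N[idx] << k) < A[idx]:
                k += 1
            m = 2 * err if err >= 0 else -2 * err - 1
            pos = _emit_golomb(bits, pos, m, k, reg_lim, bpp)
            B[idx] += err
            A[idx] += abs(err)
            if N[idx] == _RESET:
                A[idx] >>= 1
                B[idx] = B[idx] >> 1 if B[idx] >= 0 else -((1 - B[idx]) >> 1)
                N[idx] >>= 1
            N[idx] += 1
            if B[idx] <= -N[idx]:
                if C[idx] > _MIN_C:
                    C[idx] -= 1
                B[idx] += N[idx]
                if B[idx] <= -N[idx]:
                    B[idx] = -N[idx] + 1
            elif B[idx] > 0:
                if C[idx] < _MAX_C:
                    C[idx] += 1
                B[idx] -= N[idx]
                if B[idx] > 0:
                    B[idx] = 0
            c += 1
    return pos


@njit(cache=True)
def _read_golomb(bits, pos, nbits, k, lim, qbpp):
    ones = 0
    while pos < nbits and bits[pos] == 1:
        ones += 1
        pos += 1
    if pos >= nbits:
        return -1, pos
    pos += 1
    if ones == lim:
        if pos + qbpp > nbits:
            return -1, pos
        v = 0
        for i in range(qbpp):
            v = (v << 1) | bits[pos + i]
        return v + 1, pos + qbpp
    if pos + k > nbits:
        return -1, pos
    v = 0
    for i in range(k):
        v = (v << 1) | bits[pos + i]
    return (ones << k) | v, pos + k


@njit(cache=True)
def _decode_core(bits, nbits, rows, cols, maxval, bpp, limit, t1, t2, t3,
                 A, B, C, N, Nn, x):
    rng = maxval + 1
    half = (rng + 1) // 2
    runindex = 0
    pos = 0
    for r in range(rows):
        c = 0
        while c < cols:
            a, b, cc, d = _neighbors(x, r, c, cols)
            d1 = d - b
            d2 = b - cc
            d3 = cc - a
            if d1 == 0 and d2 == 0 and d3 == 0:
                # ---- run mode ----
                runval = a
                interrupted = False
                while c < cols:
                    if pos >= nbits:
                        return 1, pos
                    bit = bits[pos]
                    pos += 1
                    if bit == 1:
                        seg = 1 << _J[runindex]
                        n = seg if seg < cols - c else cols - c
                        for _ in range(n):
                            x[r, c] = runval
                            c += 1
                        # a full segment always bumps the ramp (the encoder's
                        # while-loop did); a partial one is the final line-end
                        # fill and does not
                        if n == seg and runindex < 31:
                            runindex += 1
                    else:
                        runcnt = 0
                        if pos + _J[runindex] > nbits:
                            return 1, pos
                        for i in range(_J[runindex]):
                            runcnt = (runcnt << 1) | bits[pos + i]
                        pos += _J[runindex]
                        for _ in range(runcnt):
                            x[r, c] = runval
                            c += 1
                        interrupted = True
                        break
                if interrupted:
                    # run-interruption sample
                    b2 = x[r - 1, c] if r > 0 else 0
                    a2 = runval
                    ritype = 1 if a2 == b2 else 0
                    px = a2 if ritype == 1 else b2
                    q = 365 + ritype
                    temp = A[q] + (N[q] >> 1 if ritype == 1 else 0)
                    k = 0
                    while (N[q] << k) < temp:
                        k += 1
                    em, pos = _read_golomb(bits, pos, nbits, k,
                                           limit - _J[runindex] - 1, bpp)
                    if em < 0:
                        return 1, pos
                    if ritype == 0 and em == 0:
                        err = 0
                    else:
                        mp = (em + ritype) & 1
                        mag = (em + ritype + mp) >> 1
                        if k == 0 and 2 * Nn[ritype] < N[q]:
                            err = mag if mp == 1 else -mag
                        else:
                            err = -mag if mp == 1 else mag
                    # update state with the coded (sign-folded) error
                    if err < 0:
                        Nn[ritype] += 1
                    em_chk = em
                    A[q] += (em_chk + 1 - ritype) >> 1
                    if N[q] == _RESET:
                        A[q] >>= 1
                        N[q] >>= 1
                        Nn[ritype] >>= 1
                    N[q] += 1
                    e2 = err
                    if ritype == 0 and a2 > b2:
                        e2 = -e2
                    val = px + e2
                    if val < 0:
                        val += rng
                    elif val > maxval:
                        val -= rng
                    x[r, c] = val
                    if runindex > 0:
                        runindex -= 1
                    c += 1
                continue
            # ---- regular mode ----
            q1 = _quantize(d1, t1, t2, t3)
            q2 = _quantize(d2, t1, t2, t3)
            q3 = _quantize(d3, t1, t2, t3)
            idx = 81 * q1 + 9 * q2 + q3
            sign = 1
            if idx < 0:
                sign = -1
                idx = -idx
            if cc >= max(a, b):
                px = min(a, b)
            elif cc <= min(a, b):
                px = max(a, b)
            else:
                px = a + b - cc
            px += sign * C[idx]
            if px < 0:
                px = 0
            elif px > maxval:
                px = maxval
            k = 0
            while (N[idx] << k) < A[idx]:
                k += 1
            m, pos = _read_golomb(bits, pos, nbits, k, limit - bpp - 1, bpp)
            if m < 0:
                return 1, pos
            err = m >> 1 if (m & 1) == 0 else -((m + 1) >> 1)
            B[idx] += err
            A[idx] += abs(err)
            if N[idx] == _RESET:
                A[idx] >>= 1
                B[idx] = B[idx] >> 1 if B[idx] >= 0 else -((1 - B[idx]) >> 1)
                N[idx] >>= 1
            N[idx] += 1
            if B[idx] <= -N[idx]:
                if C[idx] > _MIN_C:
                    C[idx] -= 1
                B[idx] += N[idx]
                if B[idx] <= -N[idx]:
                    B[idx] = -N[idx] + 1
            elif B[idx] > 0:
                if C[idx] < _MAX_C:
                    C[idx] += 1
                B[idx] -= N[idx]
                if B[idx] > 0:
                    B[idx] = 0
            e2 = err
            if sign < 0:
                e2 = -e2
            val = px + e2
            if val < 0:
                val += rng
            elif val > maxval:
                val -= rng
            x[r, c] = val
            c += 1
    return 0, pos


def _params(bits_stored: int):
    maxval = (1 << bits_stored) - 1
    bpp = max(2, bits_stored)
    limit = 2 * (bpp + max(8, bpp))
    factor = (min(maxval, 4095) + 128) >> 8
    t1 = factor + 2
    t2 = 4 * factor + 3
    t3 = 17 * factor + 4
    if maxval < 128:
        # low dynamic range fallback (not used for 8..16 bit planes)
        t1, t2, t3 = 3, 7, 21
    return maxval, bpp, limit, t1, t2, t3


def _init_state(maxval: int):
    a0 = max(2, (maxval + 1 + 32) >> 6)
    A = np.full(367, a0, dtype=np.int64)
    B = np.zeros(367, dtype=np.int64)
    C = np.zeros(367, dtype=np.int64)
    N = np.ones(367, dtype=np.int64)
    Nn = np.zeros(2, dtype=np.int64)
    return A, B, C, N, Nn


def encode_plane(
    crop: np.ndarray, bits_stored: int, *, return_state: bool = False
) -> bytes | tuple[bytes, dict]:
    """Encode a 2-D unsigned-integer plane losslessly.

    The stream is the 13-byte header (magic, rows, cols u32 LE, bits u8)
    followed by the packed entropy-coded bits.
    """
    crop = np.asarray(crop)
    if crop.ndim != 2 or crop.size == 0:
        raise ValueError("crop must be a non-empty 2-D array")
    if not (8 <= bits_stored <= 16):
        raise PixelRangeError(f"bits_stored {bits_stored} outside [8, 16]")
    maxval, bpp, limit, t1, t2, t3 = _params(bits_stored)
    x = crop.astype(np.int64)
    if x.min() < 0 or x.max() > maxval:
        raise PixelRangeError(
            f"plane values outside [0, {maxval}] for bits_stored={bits_stored}"
        )
    rows, cols = x.shape
    A, B, C, N, Nn = _init_state(maxval)
    # worst case per sample: limit bits; plus per-line run bookkeeping slack
    bits = np.zeros(rows * cols * (limit + 2) + rows * 64 + 64, dtype=np.uint8)
    nbits = _encode_core(x, maxval, bpp, limit, t1, t2, t3, A, B, C, N, Nn, bits)
    payload = np.packbits(bits[:nbits]).tobytes()
    header = MAGIC + struct.pack("<IIB", rows, cols, bits_stored)
    stream = header + payload
    if return_state:
        return stream, {"A": A, "B": B, "C": C, "N": N, "Nn": Nn, "nbits": nbits}
    return stream


def decode_plane(
    stream: bytes, *, return_state: bool = False
) -> np.ndarray | tuple[np.ndarray, dict]:
    """Exact inverse of :func:`encode_plane`."""
    if len(stream) < 13:
        raise FormatError("stream shorter than the 13-byte header")
    if stream[:4] != MAGIC:
        raise FormatError("bad magic; not a roipack JPEG-LS stream")
    rows, cols, bits_stored = struct.unpack("<IIB", stream[4:13])
    if rows == 0 or cols == 0:
        raise FormatError("zero image dimension in header")
    if not (8 <= bits_stored <= 16):
        raise FormatError(f"header bits_stored {bits_stored} outside [8, 16]")
    maxval, bpp, limit, t1, t2, t3 = _params(bits_stored)
    payload = np.frombuffer(stream[13:], dtype=np.uint8)
    bits = np.unpackbits(payload).astype(np.uint8)
    nbits = len(bits)
    A, B, C, N, Nn = _init_state(maxval)
    x = np.zeros((rows, cols), dtype=np.int64)
    status, pos = _decode_core(bits, nbits, rows, cols, maxval, bpp, limit,
                               t1, t2, t3, A, B, C, N, Nn, x)
    if status != 0:
        raise TruncationError(
            f"stream exhausted after {pos} bits while decoding {rows}x{cols} plane"
        )
    out = x.astype(np.uint16 if bits_stored > 8 else np.uint8)
    if return_state:
        return out, {"A": A, "B": B, "C": C, "N": N, "Nn": Nn, "nbits": pos}
    return out
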