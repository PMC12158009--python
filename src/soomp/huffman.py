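"""Canonical static Huffman coding of nonnegative-integer sequences.

Each encoded block is self-describing: it carries its alphabet (the
distinct symbols with their code lengths) followed by the bit payload, so
a decoder needs no out-of-band state.  Canonical codes make the table
compact — only code *lengths* are stored, the codes themselves are
reconstructed by the standard canonical rule (codes of equal length are
consecutive integers, ordered by symbol).

Block layout (little-endian):
    uint32  n_values
    uint32  n_symbols
    uint32  * n_symbols   symbols, ascending
    uint8   * n_symbols   code length per symbol
    uint8   padding bits in the last payload byte
    bytes   payload (MSB-first bit packing)
"""

from __future__ import annotations

import heapq
import struct
from collections import Counter

import numpy as np

__all__ = ["encode_ints", "decode_ints"]


def _code_lengths(counts: Counter) -> dict[int, int]:
    """Huffman code length per symbol (package-merge not needed: depths
    stay well below 255 for realistic streams)."""
    if len(counts) == 1:
        return {next(iter(counts)): 1}
    heap = [(c, i, (s,)) for i, (s, c) in enumerate(sorted(counts.items()))]
    heapq.heapify(heap)
    depth: Counter = Counter()
    tick = len(heap)
    while len(heap) > 1:
        c1, _, s1 = heapq.heappop(heap)
        c2, _, s2 = heapq.heappop(heap)
        for s in s1 + s2:
            depth[s] += 1
        heapq.heappush(heap, (c1 + c2, tick, s1 + s2))
        tick += 1
    return dict(depth)


def _canonical_codes(lengths: dict[int, int]) -> dict[int, tuple[int, int]]:
    """symbol -> (code, length), canonical order: (length, symbol)."""
    code = 0
    prev_len = 0
    out: dict[int, tuple[int, int]] = {}
    for sym, ln in sorted(lengths.items(), key=lambda kv: (kv[1], kv[0])):
        code <<= ln - prev_len
        out[sym] = (code, ln)
        code += 1
        prev_len = ln
    return out


def encode_ints(values) -> bytes:
    """Encode a sequence of nonnegative integers into one Huffman block."""
    vals = [int(v) for v in np.asarray(values, dtype=np.int64).ravel()]
    if any(v < 0 for v in vals):
        raise ValueError("symbols must be nonnegative")
    if not vals:
        return struct.pack("<II", 0, 0)
    lengths = _code_lengths(Counter(vals))
    codes = _canonical_codes(lengths)

    symbols = sorted(lengths)
    head = struct.pack("<II", len(vals), len(symbols))
    head += struct.pack(f"<{len(symbols)}I", *symbols)
    head += bytes(lengths[s] for s in symbols)

    buf = bytearray()
    acc = 0
    nbits = 0
    for v in vals:
        c, ln = codes[v]
        acc = (acc << ln) | c
        nbits += ln
        while nbits >= 8:
            nbits -= 8
            buf.append((acc >> nbits) & 0xFF)
            acc &= (1 << nbits) - 1
    pad = (-nbits) % 8
    if nbits:
        buf.append((acc << pad) & 0xFF)
    return head + bytes([pad]) + bytes(buf)


def decode_ints(data: bytes, offset: int = 0) -> tuple[np.ndarray, int]:
    """Decode one block; returns (values, offset past the block)."""
    n_values, n_symbols = struct.unpack_from("<II", data, offset)
    offset += 8
    if n_values == 0:
        if n_symbols != 0:
            raise ValueError("malformed Huffman block")
        return np.empty(0, dtype=np.int64), offset
    symbols = struct.unpack_from(f"<{n_symbols}I", data, offset)
    offset += 4 * n_symbols
    lens = data[offset : offset + n_symbols]
    offset += n_symbols
    pad = data[offset]
    offset += 1

    codes = _canonical_codes(dict(zip(symbols, lens)))
    # invert: (length, code) -> symbol
    lookup = {(ln, c): s for s, (c, ln) in codes.items()}
    max_len = max(lens)

    out = np.empty(n_values, dtype=np.int64)
    acc = 0
    acc_len = 0
    produced = 0
    pos = offset
    while produced < n_values:
        if pos >= len(data):
            raise ValueError("truncated Huffman payload")
        byte = data[pos]
        pos += 1
        for bit_i in range(7, -1, -1):
            acc = (acc << 1) | ((byte >> bit_i) & 1)
            acc_len += 1
            if acc_len > max_len:
                raise ValueError("invalid code in Huffman payload")
            sym = lookup.get((acc_len, acc))
            if sym is not None:
                out[produced] = sym
                produced += 1
                acc = 0
                acc_len = 0
                if produced == n_values:
                    break
    # bits remaining in the current byte (and `pad` trailing zeros) are padding
    _ = pad
    return out, pos
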