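"""The BL (Binary cLuster) universal code.

A *binary cluster* is a bit pattern that starts with the seed ``"10"`` and
contains no other occurrence of ``"10"``.  Enumerated in order, the M-th
cluster (code-num ``M``) consists of a leading ``1``, then ``K − X + 1``
zeros, then ``X − 1`` ones, where the group index ``K`` is the unique integer
with ``K(K−1)/2 < M ≤ K(K+1)/2`` and ``X = M − K(K−1)/2`` is the position of
the cluster within its group.  The first clusters are ``10, 100, 101, 1000,
1001, 1011, ...``; the cluster for ``M`` has ``K + 1`` bits, so the prefix
grows like ``√(2M)`` rather than linearly as in the unary prefix of the
exponential Golomb code.

A BL codeword for a positive integer ``Z`` is the *reversed* cluster (which
then ends in the delimiter ``"01"``, making the code instantaneously
decodable) followed by a fixed-width binary suffix of ``M + S − 1`` bits,
where ``S ≥ 1`` is an external parameter controlling how many values share a
prefix.  The code-num is the smallest ``M`` with ``Z ≤ 2^S (2^M − 1)``, and
the suffix stores ``Z − 2^S (2^(M−1) − 1) − 1``.  Decoding scans to the first
``"01"``: with ``K`` the prefix length minus one and ``T`` its count of
leading ones, ``M = K(K−1)/2 + T + 1``, and ``Z`` is recovered from the
suffix by the inverse affine map.  All arithmetic is exact integer
arithmetic; no floating-point logarithms are used, so arbitrarily large ``Z``
round-trips correctly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isqrt

import numpy as np

from .bitstream import BitStream
from .errors import PatternNotFound, TruncatedCode

__all__ = [
    "BLParameters",
    "group_index",
    "position_in_group",
    "binary_cluster",
    "bl_prefix",
    "code_num_for_value",
    "encode_value",
    "decode_prefix",
    "decode_value",
    "encode_sequence",
    "decode_sequence",
    "codeword_length",
]


@dataclass(frozen=True)
class BLParameters:
    """Tunable parameter of the BL code.

    ``S`` controls the suffix width (``M + S − 1`` bits for code-num ``M``):
    larger ``S`` packs more values under each prefix.  ``S = 1`` is the
    default operating point throughout this package.
    """

    S: int = 1

    def __post_init__(self) -> None:
        if not isinstance(self.S, (int, np.integer)) or self.S < 1:
            raise ValueError(f"S must be an integer >= 1, got {self.S!r}")


def _check_code_num(M: int) -> None:
    if M < 1:
        raise ValueError(f"code-num must be >= 1, got {M}")


def _check_value(Z: int) -> None:
    if Z < 1:
        raise ValueError(f"BL codewords exist only for integers >= 1, got {Z}")


def group_index(M: int) -> int:
    """Group index ``K`` of code-num ``M``: the unique integer with
    ``K(K−1)/2 < M ≤ K(K+1)/2`` (equivalently the bit length of the M-th
    binary cluster minus one).

    Computed as the smallest ``K`` with ``M ≤ K(K+1)/2`` via an integer
    square root plus correction, avoiding floating-point error at large M.
    """
    _check_code_num(M)
    K = (isqrt(8 * M + 1) - 1) // 2  # candidate near (−1+√(1+8M))/2
    while K * (K + 1) // 2 < M:
        K += 1
    while K > 1 and (K - 1) * K // 2 >= M:
        K -= 1
    return K


def position_in_group(M: int) -> int:
    """Position ``X = M − K(K−1)/2`` of the cluster within its group, 1..K."""
    K = group_index(M)
    return M - K * (K - 1) // 2


def binary_cluster(M: int) -> str:
    """The M-th binary cluster: ``"1"`` + (K−X+1) zeros + (X−1) ones."""
    K = group_index(M)
    X = M - K * (K - 1) // 2
    return "1" + "0" * (K - X + 1) + "1" * (X - 1)


def bl_prefix(M: int) -> str:
    """Reversed binary cluster; always ends with the delimiter ``"01"``."""
    return binary_cluster(M)[::-1]


def code_num_for_value(Z: int, params: BLParameters = BLParameters()) -> int:
    """Smallest code-num ``M ≥ 1`` with ``Z ≤ 2^S (2^M − 1)``.

    Equivalent to ``ceil(log2((Z + 2^S) / 2^S))`` but computed with integer
    comparisons so exact powers of two never fall on a rounding tie.
    """
    _check_value(Z)
    S = params.S
    q = (Z + (1 << S) - 1) >> S  # ceil(Z / 2^S)
    return max(1, q.bit_length())


def _suffix_value(Z: int, M: int, S: int) -> int:
    return Z - (1 << S) * ((1 << (M - 1)) - 1) - 1


def encode_value(Z: int, params: BLParameters = BLParameters()) -> BitStream:
    """Encode one positive integer as its BL codeword.

    The codeword is ``bl_prefix(M)`` followed by the suffix value written in
    binary, left-zero-padded to exactly ``M + S − 1`` bits; the total length
    is ``K + M + S`` bits.
    """
    S = params.S
    M = code_num_for_value(Z, params)
    suffix = _suffix_value(Z, M, S)
    width = M + S - 1
    assert 0 <= suffix < (1 << width)
    return BitStream(bl_prefix(M) + format(suffix, f"0{width}b"))


def codeword_length(Z: int, params: BLParameters = BLParameters()) -> int:
    """Bit length ``K + M + S`` of the BL codeword without materializing it."""
    M = code_num_for_value(Z, params)
    return group_index(M) + M + params.S


def decode_prefix(stream: BitStream) -> tuple[int, int]:
    """Consume one BL prefix from the cursor; return ``(M, bits_consumed)``.

    The prefix is delimited by the first ``"01"``; ``K`` is the consumed
    length minus one and ``T`` the count of leading ones, giving
    ``M = K(K−1)/2 + T + 1``.
    """
    try:
        n = stream.scan_for("01")
    except PatternNotFound as exc:
        raise TruncatedCode(f"no prefix delimiter before end of stream: {exc}") from exc
    prefix = stream.read(n)
    K = n - 1
    T = 0
    while T < n and prefix[T] == 1:
        T += 1
    return K * (K - 1) // 2 + T + 1, n


def decode_value(
    stream: BitStream, params: BLParameters = BLParameters()
) -> tuple[int, int]:
    """Decode one codeword at the cursor; return ``(Z, bits_consumed)``."""
    S = params.S
    M, n_prefix = decode_prefix(stream)
    width = M + S - 1
    if stream.remaining < width:
        raise TruncatedCode(
            f"suffix truncated: need {width} bits, only {stream.remaining} remain"
        )
    suffix_bits = stream.read(width)
    suffix = 0
    for b in suffix_bits:
        suffix = (suffix << 1) | int(b)
    Z = suffix + (1 << S) * ((1 << (M - 1)) - 1) + 1
    return Z, n_prefix + width


def encode_sequence(values, params: BLParameters = BLParameters()) -> BitStream:
    """Concatenate the codewords of ``values`` with no separators.

    A numpy integer array takes a vectorized path; any other iterable (e.g.
    arbitrary-precision Python ints) is encoded value by value.
    """
    if isinstance(values, np.ndarray) and (
        values.size == 0 or int(np.max(values)) < (1 << 62)
    ):
        return _encode_array(values, params)
    stream = BitStream()
    for Z in values:
        cw = encode_value(int(Z), params)
        stream.append_array(cw.read(len(cw)))
    return stream


def _encode_array(values: np.ndarray, params: BLParameters) -> BitStream:
    """Vectorized encoder for int arrays (values must fit in int64)."""
    Z = np.asarray(values, dtype=np.int64).ravel()
    if Z.size == 0:
        return BitStream()
    if Z.min() < 1:
        bad = int(np.argmin(Z))
        raise ValueError(
            f"BL codewords exist only for integers >= 1, got {Z[bad]} at index {bad}"
        )
    S = params.S
    q = (Z + (1 << S) - 1) >> S
    # bit_length of q (q >= 1), vectorized
    M = np.ceil(np.log2(q.astype(np.float64) + 1.0)).astype(np.int64)
    # guard against float rounding on exact powers of two
    M = np.maximum(M, 1)
    low = (1 << M) - 1 < q
    M[low] += 1
    high = (M > 1) & ((1 << (M - 1)) - 1 >= q)
    M[high] -= 1
    K = ((np.sqrt(8.0 * M + 1.0) - 1.0) / 2.0).astype(np.int64)
    K[K * (K + 1) // 2 < M] += 1
    Kfix = (K > 1) & ((K - 1) * K // 2 >= M)
    K[Kfix] -= 1
    X = M - K * (K - 1) // 2
    T = X - 1
    suffix = Z - (1 << S) * ((1 << (M - 1)) - 1) - 1
    width = M + S - 1
    lengths = (K + 1) + width
    offsets = np.concatenate(([0], np.cumsum(lengths)[:-1]))
    total = int(lengths.sum())
    bits = np.zeros(total, dtype=np.uint8)
    # prefix: T ones, K−T−1 zeros, "01"; lay down ones then the delimiter
    max_T = int(T.max())
    for t in range(max_T):
        sel = T > t
        bits[offsets[sel] + t] = 1
    bits[offsets + K] = 1  # closing "1" of the "01" delimiter
    # suffix: MSB-first fixed-width binary
    suffix_start = offsets + K + 1
    max_w = int(width.max())
    for p in range(max_w):
        sel = width > p
        shift = width[sel] - 1 - p
        bits[suffix_start[sel] + p] = ((suffix[sel] >> shift) & 1).astype(np.uint8)
    stream = BitStream()
    stream.append_array(bits)
    return stream


def decode_sequence(
    stream: BitStream, count: int, params: BLParameters = BLParameters()
) -> list[int]:
    """Decode exactly ``count`` integers; inverse of :func:`encode_sequence`.

    Truncation mid-codeword raises :class:`TruncatedCode` naming the symbol
    index reached, so corrupt data is never silently misdecoded.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    out: list[int] = []
    for i in range(count):
        try:
            Z, _ = decode_value(stream, params)
        except TruncatedCode as exc:
            raise TruncatedCode(f"stream truncated at symbol {i} of {count}: {exc}") from exc
        out.append(Z)
    return out
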