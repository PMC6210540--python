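"""Baseline universal integer coders: unary, exponential Golomb, Elias
gamma, Elias delta, and Fibonacci.

These are the standard prefix-free codes the BL code is benchmarked against.
All encoders map positive integers Z >= 1 to bit strings; each code has a
matching decoder so that lossless roundtrips can be verified on concatenated
streams.

Conventions (fixed by the comparison tables this package reproduces):

* ``exp-golomb`` is the order-0 exponential Golomb code of ``Z − 1``, i.e.
  the code is indexed from Z = 1 ("1", "010", "011", "00100", ...), the
  convention used in H.264 syntax elements shifted onto positive integers.
* ``fibonacci`` uses the Zeckendorf representation over F(2)=1, F(3)=2,
  F(4)=3, ... with a terminating "1" appended (standard Fibonacci coding).
"""

from __future__ import annotations

from typing import Callable

import pandas as pd

from .bitstream import BitStream
from .errors import PatternNotFound, TruncatedCode

__all__ = [
    "unary_encode",
    "exp_golomb_encode",
    "exp_golomb_decode",
    "elias_gamma_encode",
    "elias_gamma_decode",
    "elias_delta_encode",
    "elias_delta_decode",
    "fibonacci_encode",
    "fibonacci_decode",
    "codeword_length_table",
    "ENCODERS",
    "DECODERS",
]


def _check(Z: int) -> None:
    if Z < 1:
        raise ValueError(f"codewords exist only for integers >= 1, got {Z}")


def unary_encode(N: int) -> str:
    """N−1 zeros followed by one "1"; length N."""
    _check(N)
    return "0" * (N - 1) + "1"


def unary_decode(stream: BitStream) -> tuple[int, int]:
    try:
        n = stream.scan_for("1")
    except PatternNotFound as exc:
        raise TruncatedCode(str(exc)) from exc
    stream.read(n)
    return n, n


def exp_golomb_encode(Z: int) -> str:
    """Order-0 exponential Golomb codeword of Z−1 (Z=1 → "1").

    Unary prefix of length ``floor(log2 Z) + 1`` then ``floor(log2 Z)``
    suffix bits; total length ``2·floor(log2 Z) + 1``.
    """
    _check(Z)
    b = Z.bit_length()  # floor(log2 Z) + 1
    return "0" * (b - 1) + format(Z, f"0{b}b")


def exp_golomb_decode(stream: BitStream) -> tuple[int, int]:
    """Inverse of :func:`exp_golomb_encode`; returns (Z, bits consumed)."""
    try:
        n = stream.scan_for("1")
    except PatternNotFound as exc:
        raise TruncatedCode(str(exc)) from exc
    stream.read(n)  # n−1 zeros and the leading "1" of the binary part
    rest = n - 1
    if stream.remaining < rest:
        raise TruncatedCode(f"exp-Golomb suffix needs {rest} bits, {stream.remaining} remain")
    Z = 1
    for b in stream.read(rest):
        Z = (Z << 1) | int(b)
    return Z, 2 * n - 1


def elias_gamma_encode(Z: int) -> str:
    """``floor(log2 Z)`` zeros followed by the binary expansion of Z."""
    _check(Z)
    b = Z.bit_length()
    return "0" * (b - 1) + format(Z, "b")


def elias_gamma_decode(stream: BitStream) -> tuple[int, int]:
    return exp_golomb_decode(stream)  # identical bit layout


def elias_delta_encode(Z: int) -> str:
    """Gamma code of ``floor(log2 Z) + 1`` followed by the trailing
    ``floor(log2 Z)`` bits of Z (the leading 1 is implicit)."""
    _check(Z)
    b = Z.bit_length()
    return elias_gamma_encode(b) + format(Z, "b")[1:]


def elias_delta_decode(stream: BitStream) -> tuple[int, int]:
    b, n1 = elias_gamma_decode(stream)
    rest = b - 1
    if stream.remaining < rest:
        raise TruncatedCode(f"Elias delta tail needs {rest} bits, {stream.remaining} remain")
    Z = 1
    for bit in stream.read(rest):
        Z = (Z << 1) | int(bit)
    return Z, n1 + rest


def _fib_upto(Z: int) -> list[int]:
    fibs = [1, 2]  # F(2), F(3)
    while fibs[-1] <= Z:
        fibs.append(fibs[-1] + fibs[-2])
    return fibs  # last element exceeds Z


def fibonacci_encode(Z: int) -> str:
    """Zeckendorf bits over F(2)=1, F(3)=2, ... with an appended "1".

    The greedy decomposition never selects adjacent Fibonacci numbers, so the
    appended "1" creates the only "11" in the codeword and terminates it.
    """
    _check(Z)
    fibs = _fib_upto(Z)
    k = len(fibs) - 1
    while fibs[k] > Z:
        k -= 1
    bits = ["0"] * (k + 1)
    rem = Z
    for i in range(k, -1, -1):
        if fibs[i] <= rem:
            bits[i] = "1"
            rem -= fibs[i]
    return "".join(bits) + "1"


def fibonacci_decode(stream: BitStream) -> tuple[int, int]:
    """Read through the terminating "11"; returns (Z, bits consumed)."""
    try:
        n = stream.scan_for("11")
    except PatternNotFound as exc:
        raise TruncatedCode(str(exc)) from exc
    bits = stream.read(n)
    fibs = [1, 2]
    while len(fibs) < n - 1:
        fibs.append(fibs[-1] + fibs[-2])
    Z = sum(fibs[i] for i in range(n - 1) if bits[i])
    return Z, n


ENCODERS: dict[str, Callable[[int], str]] = {
    "unary": unary_encode,
    "exp-golomb": exp_golomb_encode,
    "elias-gamma": elias_gamma_encode,
    "elias-delta": elias_delta_encode,
    "fibonacci": fibonacci_encode,
}

DECODERS: dict[str, Callable[[BitStream], tuple[int, int]]] = {
    "unary": unary_decode,
    "exp-golomb": exp_golomb_decode,
    "elias-gamma": elias_gamma_decode,
    "elias-delta": elias_delta_decode,
    "fibonacci": fibonacci_decode,
}


def codeword_length_table(coders, z_max: int, S: int = 1) -> pd.DataFrame:
    """Bit lengths of every codeword for Z = 1..z_max, one column per coder.

    ``"bl"`` may be included among the coder ids; its column uses the given
    suffix parameter ``S``.  Lengths come from materialized codewords.
    """
    from . import bl

    if z_max < 1:
        raise ValueError("z_max must be >= 1")
    cols: dict[str, list[int]] = {}
    for cid in coders:
        if cid == "bl":
            params = bl.BLParameters(S)
            cols[cid] = [len(bl.encode_value(Z, params)) for Z in range(1, z_max + 1)]
        elif cid in ENCODERS:
            cols[cid] = [len(ENCODERS[cid](Z)) for Z in range(1, z_max + 1)]
        else:
            raise KeyError(f"unknown coder id {cid!r}; known: bl, {', '.join(ENCODERS)}")
    return pd.DataFrame(cols, index=pd.RangeIndex(1, z_max + 1, name="Z"))
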