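"""Bit-level writer/reader with deterministic MSB-first byte packing.

All coders in this package produce and consume :class:`BitStream`.  Bits are
stored one per byte internally (values 0/1) which keeps append and scan simple
and lets numpy's ``packbits``/``unpackbits`` do the byte conversion.  Packing
is MSB-first: the first bit written becomes the highest bit of the first byte,
matching the left-to-right bit-string notation used for code tables.  The
final partial byte is zero-padded; decoders never rely on the padding — the
symbol count carried out-of-band (e.g. in a container header) terminates
decoding, since padding zeros could otherwise be misread as the start of a
codeword.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

from .errors import BitStreamOverrun, PatternNotFound

__all__ = ["BitStream"]


def _as_bit_array(bits: "str | bytes | bytearray | Iterable[int] | np.ndarray") -> np.ndarray:
    """Coerce a bit sequence (string of '0'/'1' or iterable of 0/1) to uint8."""
    if isinstance(bits, str):
        arr = np.frombuffer(bits.encode("ascii"), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(list(bits) if not isinstance(bits, np.ndarray) else bits, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("bits must be one-dimensional")
    if arr.size and (arr.max(initial=0) > 1 or arr.min(initial=0) < 0):
        raise ValueError("bits must contain only 0/1 symbols")
    return arr


class BitStream:
    """An append-only ordered sequence of bits with a sequential read cursor.

    Parameters
    ----------
    bits : str or iterable of int, optional
        Initial content, e.g. ``"1101"`` or ``[1, 1, 0, 1]``.
    """

    def __init__(self, bits: "str | Iterable[int] | None" = None) -> None:
        self._bits = bytearray()
        self._pos = 0
        if bits is not None:
            self.append(bits)

    # -- writing -----------------------------------------------------------

    def append(self, bits: "str | Iterable[int] | np.ndarray") -> "BitStream":
        """Append a bit sequence; order is preserved. Returns self."""
        self._bits.extend(_as_bit_array(bits).tobytes())
        return self

    def append_array(self, bits: np.ndarray) -> "BitStream":
        """Append a pre-validated uint8 0/1 array (fast path for coders)."""
        self._bits.extend(bits.astype(np.uint8, copy=False).tobytes())
        return self

    # -- reading -----------------------------------------------------------

    @property
    def position(self) -> int:
        """Current cursor position in bits."""
        return self._pos

    def seek(self, pos: int) -> None:
        if not 0 <= pos <= len(self):
            raise ValueError(f"seek position {pos} outside stream of length {len(self)}")
        self._pos = pos

    @property
    def remaining(self) -> int:
        return len(self._bits) - self._pos

    def at_end(self) -> bool:
        """True when the cursor sits exactly at the end of the stream."""
        return self._pos == len(self._bits)

    def read(self, n: int) -> np.ndarray:
        """Read the next ``n`` bits and advance the cursor.

        Raises :class:`BitStreamOverrun` if fewer than ``n`` bits remain —
        an error distinguishable from a clean end of stream (``at_end``).
        """
        if n < 0:
            raise ValueError("cannot read a negative number of bits")
        if self._pos + n > len(self._bits):
            raise BitStreamOverrun(
                f"requested {n} bits at position {self._pos} "
                f"but only {self.remaining} remain"
            )
        out = np.frombuffer(self._bits[self._pos : self._pos + n], dtype=np.uint8)
        self._pos += n
        return out

    def scan_for(self, pattern: "str | Iterable[int]") -> int:
        """Distance (in bits) from the cursor through the END of the first
        occurrence of ``pattern``; the cursor is not moved.

        Raises :class:`PatternNotFound` when the pattern does not occur before
        the end of the stream (a truncated or corrupt codeword).
        """
        pat = _as_bit_array(pattern)
        if pat.size == 0:
            raise ValueError("pattern must be non-empty")
        idx = self._bits.find(pat.tobytes(), self._pos)
        if idx < 0:
            raise PatternNotFound(
                f"pattern {''.join(map(str, pat))!r} not found after position {self._pos}"
            )
        return idx - self._pos + pat.size

    # -- byte packing ------------------------------------------------------

    def pack(self) -> bytes:
        """Pack to bytes, MSB-first, zero-padding the final partial byte."""
        return np.packbits(np.frombuffer(self._bits, dtype=np.uint8)).tobytes()

    @classmethod
    def unpack(cls, data: bytes, bit_count: int) -> "BitStream":
        """Inverse of :meth:`pack` given the original bit count."""
        if bit_count < 0 or bit_count > 8 * len(data):
            raise ValueError(f"bit_count {bit_count} inconsistent with {len(data)} bytes")
        stream = cls()
        stream._bits = bytearray(
            np.unpackbits(np.frombuffer(data, dtype=np.uint8), count=bit_count).tobytes()
        )
        return stream

    # -- dunder ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._bits)

    def __str__(self) -> str:
        return "".join("01"[b] for b in self._bits)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, BitStream):
            return self._bits == other._bits
        if isinstance(other, str):
            return str(self) == other
        return NotImplemented

    def __repr__(self) -> str:  # pragma: no cover
        s = str(self)
        if len(s) > 64:
            s = s[:61] + "..."
        return f"BitStream({s!r}, length={len(self)}, pos={self._pos})"
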