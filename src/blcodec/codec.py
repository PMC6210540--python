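"""Lossless frame codec: signed sample frames -> positive integers -> coded
bit stream, plus the self-describing ``.blc`` container and ratio metrics.

Ultrasound RF and baseband I/Q samples are signed and zero-mean, while
universal codes are defined on positive integers, so samples are first sent
through a zigzag bijection (0→1, 1→2, −1→3, 2→4, ...) that preserves the
small-magnitude→short-codeword property the codes rely on.  The container
header records everything needed for bit-exact recovery; the payload itself
carries no per-symbol overhead.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from . import bl, reference
from .bitstream import BitStream
from .errors import ContainerFormatError, TruncatedCode

__all__ = [
    "STAGES",
    "SampleFrame",
    "CompressedContainer",
    "zigzag_map",
    "zigzag_unmap",
    "compress_frame",
    "decompress_frame",
    "compression_ratio",
    "relative_improvement",
    "read_i16",
    "write_i16",
]

STAGES = ("pre-beamformed", "beamformed", "I", "Q")

#: coder ids usable for frame compression (must have both encoder and decoder)
FRAME_CODERS = ("bl", "exp-golomb", "elias-gamma", "elias-delta", "fibonacci")

_MAGIC = b"BLUC"
_VERSION = 1
_CODER_IDS = {name: i for i, name in enumerate(FRAME_CODERS)}
_CODER_NAMES = {i: name for name, i in _CODER_IDS.items()}
_MAPPING_ZIGZAG = 0


@dataclass
class SampleFrame:
    """A 2-D grid of signed integer samples with acquisition metadata.

    Rows are depth samples, columns are channels (pre-beamformed) or
    scanlines (beamformed / I / Q).  ``bit_depth`` is the ADC resolution the
    samples must fit in; ``sampling_rate`` is carried as metadata only.
    """

    samples: np.ndarray
    stage: str = "beamformed"
    bit_depth: int = 12
    sampling_rate: float = 40e6

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError(f"samples must be 2-D, got shape {self.samples.shape}")
        if not np.issubdtype(self.samples.dtype, np.integer):
            raise ValueError(f"samples must be integers, got dtype {self.samples.dtype}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if not 2 <= self.bit_depth <= 16:
            raise ValueError(f"bit_depth must be in 2..16, got {self.bit_depth}")

    @property
    def rows(self) -> int:
        return self.samples.shape[0]

    @property
    def cols(self) -> int:
        return self.samples.shape[1]

    @property
    def uncompressed_bits(self) -> int:
        """Raw size at the declared ADC resolution."""
        return self.samples.size * self.bit_depth

    def validate_bit_depth(self) -> None:
        """Raise if any sample falls outside the declared signed range."""
        lo, hi = -(1 << (self.bit_depth - 1)), (1 << (self.bit_depth - 1)) - 1
        flat = self.samples.ravel()
        bad = np.nonzero((flat < lo) | (flat > hi))[0]
        if bad.size:
            i = int(bad[0])
            r, c = divmod(i, self.cols)
            raise ValueError(
                f"sample {int(flat[i])} at (row {r}, col {c}) outside "
                f"{self.bit_depth}-bit signed range [{lo}, {hi}]"
            )


@dataclass
class CompressedContainer:
    """Self-describing compressed frame: fixed header + packed payload.

    Header layout (little-endian): magic ``BLUC``, version, coder id, S,
    mapping id, bit depth (1 byte each after the 4-byte magic), rows and
    cols (uint32), payload bit count (uint64), then the payload bytes.
    """

    coder: str
    S: int
    bit_depth: int
    rows: int
    cols: int
    payload_bits: int
    payload: bytes
    stage: str = "beamformed"
    sampling_rate: float = 40e6

    _HEADER = struct.Struct("<4sBBBBBIIQ")

    def to_bytes(self) -> bytes:
        header = self._HEADER.pack(
            _MAGIC,
            _VERSION,
            _CODER_IDS[self.coder],
            self.S,
            _MAPPING_ZIGZAG,
            self.bit_depth,
            self.rows,
            self.cols,
            self.payload_bits,
        )
        return header + self.payload

    @classmethod
    def from_bytes(cls, data: bytes) -> "CompressedContainer":
        if len(data) < cls._HEADER.size:
            raise ContainerFormatError(
                f"container too short: {len(data)} bytes < {cls._HEADER.size}-byte header"
            )
        magic, version, coder_id, S, mapping, depth, rows, cols, nbits = cls._HEADER.unpack(
            data[: cls._HEADER.size]
        )
        if magic != _MAGIC:
            raise ContainerFormatError(f"bad magic {magic!r}, expected {_MAGIC!r}")
        if version != _VERSION:
            raise ContainerFormatError(f"unsupported version {version}")
        if coder_id not in _CODER_NAMES:
            raise ContainerFormatError(f"unknown coder id {coder_id}")
        if mapping != _MAPPING_ZIGZAG:
            raise ContainerFormatError(f"unknown mapping id {mapping}")
        payload = data[cls._HEADER.size :]
        if len(payload) * 8 < nbits:
            raise ContainerFormatError(
                f"payload holds {len(payload) * 8} bits but header declares {nbits}"
            )
        return cls(
            coder=_CODER_NAMES[coder_id],
            S=S,
            bit_depth=depth,
            rows=rows,
            cols=cols,
            payload_bits=nbits,
            payload=payload,
        )

    @property
    def header_bits(self) -> int:
        return self._HEADER.size * 8


def zigzag_map(v):
    """Bijection from signed integers onto {1, 2, 3, ...}.

    0→1, 1→2, −1→3, 2→4, −2→5, ...: magnitude-ordered, so values near zero
    get the shortest codewords.  Accepts scalars or numpy arrays.
    """
    if isinstance(v, np.ndarray):
        v = v.astype(np.int64)
        return np.where(v > 0, 2 * v, 1 - 2 * v)
    v = int(v)
    return 2 * v if v > 0 else 1 - 2 * v


def zigzag_unmap(Z):
    """Inverse of :func:`zigzag_map`."""
    if isinstance(Z, np.ndarray):
        if Z.size and int(Z.min()) < 1:
            raise ValueError("zigzag codes are >= 1")
        Z = Z.astype(np.int64)
        return np.where(Z % 2 == 0, Z // 2, -(Z - 1) // 2)
    Z = int(Z)
    if Z < 1:
        raise ValueError(f"zigzag codes are >= 1, got {Z}")
    return Z // 2 if Z % 2 == 0 else -(Z - 1) // 2


def compress_frame(
    frame: SampleFrame,
    coder: str = "bl",
    params: bl.BLParameters | None = None,
) -> CompressedContainer:
    """Losslessly compress a frame: flatten row-major, zigzag-map, encode.

    ``coder`` is one of ``bl``, ``exp-golomb``, ``elias-gamma``,
    ``elias-delta``, ``fibonacci``; ``params`` applies to the BL coder only.
    """
    if coder not in FRAME_CODERS:
        raise KeyError(f"unknown coder {coder!r}; known: {FRAME_CODERS}")
    params = params or bl.BLParameters()
    frame.validate_bit_depth()
    codes = zigzag_map(frame.samples.ravel(order="C"))
    if coder == "bl":
        stream = bl.encode_sequence(codes, params)
    else:
        enc = reference.ENCODERS[coder]
        stream = BitStream("".join(enc(int(Z)) for Z in codes))
    return CompressedContainer(
        coder=coder,
        S=params.S,
        bit_depth=frame.bit_depth,
        rows=frame.rows,
        cols=frame.cols,
        payload_bits=len(stream),
        payload=stream.pack(),
        stage=frame.stage,
        sampling_rate=frame.sampling_rate,
    )


def decompress_frame(container: CompressedContainer) -> SampleFrame:
    """Exact inverse of :func:`compress_frame`."""
    stream = BitStream.unpack(container.payload, container.payload_bits)
    n = container.rows * container.cols
    params = bl.BLParameters(container.S)
    values: list[int] = []
    if container.coder == "bl":
        values = bl.decode_sequence(stream, n, params)
    else:
        dec = reference.DECODERS[container.coder]
        for i in range(n):
            try:
                Z, _ = dec(stream)
            except TruncatedCode as exc:
                raise TruncatedCode(f"stream truncated at symbol {i} of {n}: {exc}") from exc
            values.append(Z)
    if not stream.at_end():
        raise ContainerFormatError(
            f"{stream.remaining} unexpected bits after {n} symbols"
        )
    samples = zigzag_unmap(np.array(values, dtype=np.int64)).reshape(
        container.rows, container.cols
    )
    dtype = np.int16 if container.bit_depth <= 16 else np.int32
    return SampleFrame(
        samples=samples.astype(dtype),
        stage=container.stage,
        bit_depth=container.bit_depth,
        sampling_rate=container.sampling_rate,
    )


def compression_ratio(uncompressed_bits: int, compressed_bits: int) -> float:
    """Compression ratio in percent: ``(1 − compressed/uncompressed) × 100``.

    Negative values indicate expansion.
    """
    if uncompressed_bits <= 0:
        raise ValueError("uncompressed size must be positive")
    return (1.0 - compressed_bits / uncompressed_bits) * 100.0


def relative_improvement(baseline_bits: int, proposed_bits: int) -> float:
    """Size reduction of ``proposed`` relative to ``baseline``, in percent."""
    if baseline_bits <= 0:
        raise ValueError("baseline size must be positive")
    return (baseline_bits - proposed_bits) / baseline_bits * 100.0


def write_i16(path, frame: SampleFrame) -> None:
    """Write samples as raw little-endian int16, row-major."""
    frame.samples.astype("<i2").tofile(path)


def read_i16(
    path, rows: int, cols: int, bit_depth: int = 12, stage: str = "beamformed",
    sampling_rate: float = 40e6,
) -> SampleFrame:
    """Read a raw little-endian int16 file into a frame; the file size must
    equal ``rows × cols × 2`` bytes."""
    data = np.fromfile(path, dtype="<i2")
    if data.size != rows * cols:
        raise ValueError(
            f"file holds {data.size} samples but rows*cols = {rows * cols}"
        )
    return SampleFrame(
        samples=data.reshape(rows, cols),
        stage=stage,
        bit_depth=bit_depth,
        sampling_rate=sampling_rate,
    )
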