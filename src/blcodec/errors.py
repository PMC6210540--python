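"""Exception hierarchy for the codec.

Truncation (a codeword cut off mid-stream) is deliberately distinct from a
clean end-of-stream at a symbol boundary, and both are distinct from a
malformed container, so callers can tell corrupt data from short data.
"""


class BLCodecError(Exception):
    """Base class for all package errors."""


class BitStreamOverrun(BLCodecError):
    """A read requested more bits than remain past the cursor."""


class PatternNotFound(BLCodecError):
    """A delimiter pattern was not found before the end of the stream.

    Raised while scanning for a codeword delimiter; signals a truncated or
    corrupt code rather than an ordinary end of data.
    """


class TruncatedCode(BLCodecError):
    """A codeword ended before all of its declared bits were present."""


class ContainerFormatError(BLCodecError):
    """A compressed container has a bad magic, version, or field value."""
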