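"""Known-answer vectors for the BL and reference coders.

These are the published worked examples for the BL code family: the first
ten binary clusters and prefixes, the first sixteen BL and exponential
Golomb codewords, the 26-bit BL codeword of 1,000,000, the reference-code
lengths for 1,000,000, and two worked stream decodings.  ``run_checks``
recomputes each one with this package and reports any mismatch; it is the
engine behind ``blcodec verify``.

One published table row is internally inconsistent: the 7-bit entry listed
for Z = 15 cannot be produced by the code's own construction, whose prefix
"0001" and 4-bit suffix "0000" give the 8-bit codeword "00010000".  The
formulas govern here; the check encodes the corrected value and the table
below records it as such.
"""

from __future__ import annotations

from . import bl, reference
from .bitstream import BitStream
from .codec import relative_improvement

__all__ = [
    "CLUSTER_TABLE",
    "CODE_TABLE",
    "MILLION_CODEWORD",
    "run_checks",
]

#: M -> (binary cluster, reversed prefix, group index K)
CLUSTER_TABLE: dict[int, tuple[str, str, int]] = {
    1: ("10", "01", 1),
    2: ("100", "001", 2),
    3: ("101", "101", 2),
    4: ("1000", "0001", 3),
    5: ("1001", "1001", 3),
    6: ("1011", "1101", 3),
    7: ("10000", "00001", 4),
    8: ("10001", "10001", 4),
    9: ("10011", "11001", 4),
    10: ("10111", "11101", 4),
}

#: Z -> (exponential Golomb codeword, BL codeword at S=1).
#: Z = 15 carries the formula-corrected 8-bit BL codeword (see module docs).
CODE_TABLE: dict[int, tuple[str, str]] = {
    1: ("1", "010"),
    2: ("010", "011"),
    3: ("011", "00100"),
    4: ("00100", "00101"),
    5: ("00101", "00110"),
    6: ("00110", "00111"),
    7: ("00111", "101000"),
    8: ("0001000", "101001"),
    9: ("0001001", "101010"),
    10: ("0001010", "101011"),
    11: ("0001011", "101100"),
    12: ("0001100", "101101"),
    13: ("0001101", "101110"),
    14: ("0001110", "101111"),
    15: ("0001111", "00010000"),
    16: ("000010000", "00010001"),
}

MILLION_CODEWORD = "11100011110100001001000001"  # BL, S=1, Z = 1,000,000

#: reference-code bit lengths for Z = 1,000,000
MILLION_LENGTHS = {"elias-gamma": 39, "elias-delta": 28, "fibonacci": 30}

#: worked stream decodings at S=1: bits -> integer
DECODE_EXAMPLES = {"1101100101": 100, "111010000000001": 1024}

#: (Z, BL bits, Golomb bits, improvement % to 1 decimal)
LENGTH_EXAMPLES = [(100, 10, 13, 23.1), (1000, 14, 19, 26.3)]


def run_checks() -> list[tuple[str, bool, str]]:
    """Recompute every known-answer vector; return (name, passed, detail)."""
    results: list[tuple[str, bool, str]] = []

    def check(name: str, got, want) -> None:
        ok = got == want
        results.append((name, ok, f"got {got!r}" + ("" if ok else f", want {want!r}")))

    for M, (cluster, prefix, K) in CLUSTER_TABLE.items():
        check(f"cluster M={M}", bl.binary_cluster(M), cluster)
        check(f"prefix M={M}", bl.bl_prefix(M), prefix)
        check(f"group index M={M}", bl.group_index(M), K)

    for Z, (golomb, blcw) in CODE_TABLE.items():
        check(f"exp-Golomb Z={Z}", reference.exp_golomb_encode(Z), golomb)
        check(f"BL Z={Z}", str(bl.encode_value(Z)), blcw)

    check("BL Z=1000000 codeword", str(bl.encode_value(1_000_000)), MILLION_CODEWORD)
    check("BL Z=1000000 length", bl.codeword_length(1_000_000), len(MILLION_CODEWORD))
    for coder, length in MILLION_LENGTHS.items():
        check(f"{coder} Z=1000000 length", len(reference.ENCODERS[coder](1_000_000)), length)

    for bits, Z in DECODE_EXAMPLES.items():
        got, consumed = bl.decode_value(BitStream(bits))
        check(f"decode {bits}", (got, consumed), (Z, len(bits)))

    for Z, bl_len, g_len, improvement in LENGTH_EXAMPLES:
        check(f"BL length Z={Z}", bl.codeword_length(Z), bl_len)
        check(f"Golomb length Z={Z}", len(reference.exp_golomb_encode(Z)), g_len)
        check(
            f"improvement Z={Z}",
            round(relative_improvement(g_len, bl_len), 1),
            improvement,
        )

    return results
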