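"""BL code: cluster enumeration, prefix construction, encode/decode."""

from math import isqrt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blcodec import (
    BitStream,
    BLParameters,
    TruncatedCode,
    binary_cluster,
    bl_prefix,
    code_num_for_value,
    codeword_length,
    decode_sequence,
    decode_value,
    encode_sequence,
    encode_value,
    group_index,
    position_in_group,
)
from blcodec.bl import decode_prefix

# first ten rows of the cluster enumeration: M -> (cluster, prefix, K)
CLUSTER_ROWS = [
    (1, "10", "01", 1),
    (2, "100", "001", 2),
    (3, "101", "101", 2),
    (4, "1000", "0001", 3),
    (5, "1001", "1001", 3),
    (6, "1011", "1101", 3),
    (7, "10000", "00001", 4),
    (8, "10001", "10001", 4),
    (9, "10011", "11001", 4),
    (10, "10111", "11101", 4),
]

# first sixteen BL codewords at S=1 (Z=15 is the formula-consistent 8-bit
# codeword: prefix "0001" + suffix "0000")
BL_CODEWORDS = {
    1: "010", 2: "011", 3: "00100", 4: "00101", 5: "00110", 6: "00111",
    7: "101000", 8: "101001", 9: "101010", 10: "101011", 11: "101100",
    12: "101101", 13: "101110", 14: "101111", 15: "00010000", 16: "00010001",
}


def brute_group_index(M: int) -> int:
    K = 1
    while K * (K + 1) // 2 < M:
        K += 1
    return K


def brute_code_num(Z: int, S: int) -> int:
    M = 1
    while Z > (1 << S) * ((1 << M) - 1):
        M += 1
    return M


class TestClusterEnumeration:
    @pytest.mark.parametrize("M,cluster,prefix,K", CLUSTER_ROWS)
    def test_first_ten_clusters(self, M, cluster, prefix, K):
        assert binary_cluster(M) == cluster
        assert bl_prefix(M) == prefix
        assert group_index(M) == K

    @pytest.mark.parametrize("M,K", [(5, 3), (19, 6), (10**6, 1414)])
    def test_group_index_values(self, M, K):
        assert group_index(M) == K
        assert brute_group_index(M) == K

    @pytest.mark.parametrize("M,X", [(10, 4), (1, 1), (19, 4)])
    def test_position_in_group(self, M, X):
        assert position_in_group(M) == X

    def test_cluster_of_19_matches_million_prefix(self):
        assert binary_cluster(19) == "1000111"
        assert bl_prefix(19) == "1110001"

    def test_group_index_triangular_bounds(self):
        for M in range(1, 5000):
            K = group_index(M)
            assert K * (K - 1) // 2 < M <= K * (K + 1) // 2
            assert K == brute_group_index(M)

    def test_strict_floor_formula_equivalence(self):
        """Integer-search K equals the strict floor of (1+sqrt(1+8M))/2
        (at integer arguments the strict floor yields the value minus one)."""
        for M in range(1, 10**6 + 1):
            s = isqrt(8 * M + 1)
            if s * s == 8 * M + 1 and (1 + s) % 2 == 0:
                K_formula = (1 + s) // 2 - 1
            else:
                K_formula = (1 + s) // 2
            assert group_index(M) == K_formula, M

    def test_cluster_structure(self):
        for M in range(1, 10001):
            cluster = binary_cluster(M)
            assert cluster.startswith("10")
            assert cluster.count("10") == 1
            prefix = bl_prefix(M)
            assert prefix.endswith("01")
            assert prefix.count("01") == 1

    def test_leading_ones_equal_position_minus_one(self):
        for M in range(1, 10001):
            prefix = bl_prefix(M)
            T = len(prefix) - len(prefix.lstrip("1"))
            assert T == position_in_group(M) - 1

    def test_invalid_code_num_rejected(self):
        for fn in (group_index, position_in_group, binary_cluster, bl_prefix):
            with pytest.raises(ValueError):
                fn(0)


class TestCodeNum:
    @pytest.mark.parametrize("Z,M", [(100, 6), (16, 4), (1_000_000, 19), (1, 1), (2, 1), (3, 2)])
    def test_known_code_nums(self, Z, M):
        assert code_num_for_value(Z) == M

    @pytest.mark.parametrize("S", [1, 2, 3])
    def test_matches_brute_force_search(self, S):
        params = BLParameters(S)
        for Z in range(1, 5001):
            assert code_num_for_value(Z, params) == brute_code_num(Z, S)

    def test_exact_powers_of_two_no_rounding_tie(self):
        for M in range(1, 40):
            Z_hi = 2 * ((1 << M) - 1)  # last value of code-num M at S=1
            assert code_num_for_value(Z_hi) == M
            assert code_num_for_value(Z_hi + 1) == M + 1

    def test_invalid_s_rejected(self):
        with pytest.raises(ValueError):
            BLParameters(0)


class TestEncode:
    @pytest.mark.parametrize("Z,codeword", sorted(BL_CODEWORDS.items()))
    def test_first_sixteen_codewords(self, Z, codeword):
        assert str(encode_value(Z)) == codeword

    def test_million_codeword(self):
        cw = encode_value(1_000_000)
        assert str(cw) == "11100011110100001001000001"
        assert len(cw) == 26

    @pytest.mark.parametrize("Z,length", [(100, 10), (1000, 14), (1_000_000, 26)])
    def test_codeword_length_without_materializing(self, Z, length):
        assert codeword_length(Z) == length
        assert len(encode_value(Z)) == length

    @pytest.mark.parametrize("S", [1, 2, 3])
    def test_length_law(self, S):
        params = BLParameters(S)
        for Z in range(1, 2001):
            M = code_num_for_value(Z, params)
            assert codeword_length(Z, params) == group_index(M) + M + S
            assert len(encode_value(Z, params)) == codeword_length(Z, params)

    def test_range_partition_and_suffix_order(self):
        """At S=1, code-num M covers exactly 2(2^(M-1)-1)+1 .. 2(2^M-1) and
        the suffix enumerates the range in increasing binary order."""
        for M in range(1, 13):
            lo = 2 * ((1 << (M - 1)) - 1) + 1
            hi = 2 * ((1 << M) - 1)
            prefix = bl_prefix(M)
            for offset, Z in enumerate(range(lo, hi + 1)):
                cw = str(encode_value(Z))
                assert cw.startswith(prefix)
                assert cw[len(prefix):] == format(offset, f"0{M}b")

    def test_nonpositive_rejected(self):
        for Z in (0, -5):
            with pytest.raises(ValueError):
                encode_value(Z)
            with pytest.raises(ValueError):
                codeword_length(Z)


class TestDecode:
    def test_decode_prefix_worked_example(self):
        M, n = decode_prefix(BitStream("1101100101"))
        assert (M, n) == (6, 4)

    def test_decode_prefix_seed_cluster(self):
        assert decode_prefix(BitStream("01XXX".replace("X", "0"))) == (1, 2)

    def test_decode_prefix_m10(self):
        assert decode_prefix(BitStream("111010000000001")) == (10, 5)

    @pytest.mark.parametrize("bits,Z,consumed", [
        ("1101100101", 100, 10),
        ("111010000000001", 1024, 15),
        ("010", 1, 3),
    ])
    def test_decode_worked_examples(self, bits, Z, consumed):
        got, n = decode_value(BitStream(bits))
        assert (got, n) == (Z, consumed)

    def test_truncated_prefix_raises(self):
        with pytest.raises(TruncatedCode):
            decode_value(BitStream("1111"))

    def test_truncated_suffix_raises(self):
        with pytest.raises(TruncatedCode):
            decode_value(BitStream("1101100"))  # needs 6 suffix bits, has 3

    @pytest.mark.parametrize("S", [1, 2, 3])
    @settings(derandomize=True, max_examples=300)
    @given(Z=st.integers(min_value=1, max_value=10**30))
    def test_roundtrip_identity(self, S, Z):
        params = BLParameters(S)
        stream = encode_value(Z, params)
        got, n = decode_value(stream, params)
        assert got == Z
        assert n == len(stream)


class TestSequences:
    def test_worked_concatenation(self):
        assert str(encode_sequence([100, 1024])) == "1101100101" + "111010000000001"

    def test_first_three_values(self):
        assert str(encode_sequence([1, 2, 3])) == "010" + "011" + "00100"

    def test_empty_sequence(self):
        assert len(encode_sequence([])) == 0
        assert decode_sequence(BitStream("0101"), 0) == []

    def test_worked_stream_decodes(self):
        stream = BitStream("1101100101" + "111010000000001")
        assert decode_sequence(stream, 2) == [100, 1024]

    def test_random_roundtrip(self, rng):
        values = [int(v) for v in rng.integers(1, 10**6, 10000)]
        stream = encode_sequence(values)
        assert decode_sequence(stream, len(values)) == values
        assert stream.at_end()

    def test_vectorized_path_matches_scalar(self, rng):
        for S in (1, 2, 3):
            params = BLParameters(S)
            values = rng.integers(1, 10**9, 3000)
            vec = encode_sequence(values, params)
            scalar = encode_sequence([int(v) for v in values], params)
            assert vec == scalar

    def test_truncation_names_symbol_index(self):
        stream = BitStream(str(encode_sequence([7, 7, 7]))[:-2])
        with pytest.raises(TruncatedCode, match="symbol 2"):
            decode_sequence(stream, 3)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            encode_sequence([3, 0, 5])
        with pytest.raises(ValueError):
            encode_sequence(np.array([3, 0, 5]))
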