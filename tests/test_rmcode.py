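"""Reed-Muller construction, encoding and majority-logic decoding."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opmr import rmcode


def gf2_rank(mat: np.ndarray) -> int:
    mat = mat.copy() % 2
    rank = 0
    for col in range(mat.shape[1]):
        pivot = np.nonzero(mat[rank:, col])[0]
        if pivot.size == 0:
            continue
        p = rank + pivot[0]
        mat[[rank, p]] = mat[[p, rank]]
        for i in range(mat.shape[0]):
            if i != rank and mat[i, col]:
                mat[i] ^= mat[rank]
        rank += 1
        if rank == mat.shape[0]:
            break
    return rank


def all_codewords(code: rmcode.RMCode) -> np.ndarray:
    infos = np.array(list(itertools.product([0, 1], repeat=code.k)), dtype=np.uint8)
    return (infos @ code.generator) & 1


@pytest.mark.parametrize("m", range(1, 9))
def test_parameters_closed_form(m):
    """n, k, d and t follow the closed forms for every order 0 <= r <= m."""
    for r in range(m + 1):
        code = rmcode.make_code(r, m)
        assert code.n == 2 ** m
        assert code.k == sum(comb(m, i) for i in range(r + 1))
        assert code.d == 2 ** (m - r)
        if r < m:
            assert code.t == 2 ** (m - r - 1) - 1


@pytest.mark.parametrize("r,m", [(-1, 3), (4, 3), (0, 0), (1, -2)])
def test_invalid_parameters_raise(r, m):
    with pytest.raises(ValueError):
        rmcode.make_code(r, m)


@pytest.mark.parametrize("r,m", [(1, 4), (2, 5), (1, 6), (2, 7)])
def test_generator_full_row_rank(r, m):
    code = rmcode.make_code(r, m)
    assert gf2_rank(code.generator) == code.k


@pytest.mark.parametrize("r,m", [(0, 3), (1, 3), (1, 4), (2, 4), (2, 3)])
def test_minimum_distance_exhaustive(r, m):
    """Every nonzero codeword has weight >= 2^(m-r), by full enumeration."""
    code = rmcode.make_code(r, m)
    weights = all_codewords(code).sum(axis=1)
    assert weights[0] == 0
    assert weights[1:].min() == code.d


def test_order_zero_is_repetition():
    code = rmcode.make_code(0, 3)
    assert (code.n, code.k, code.d, code.t) == (8, 1, 8, 3)
    assert np.array_equal(rmcode.encode(code, [1]), np.ones(8, dtype=np.uint8))


def test_constant_monomial_row_is_all_ones():
    code = rmcode.make_code(1, 2)
    info = np.zeros(code.k, dtype=np.uint8)
    info[code.monomials.index(())] = 1
    assert np.array_equal(rmcode.encode(code, info), np.ones(4, dtype=np.uint8))


def test_encode_all_zero():
    code = rmcode.make_code(1, 6)
    assert rmcode.encode(code, np.zeros(7, dtype=np.uint8)).sum() == 0


def test_encode_wrong_length():
    code = rmcode.make_code(1, 6)
    with pytest.raises(ValueError):
        rmcode.encode(code, np.zeros(6, dtype=np.uint8))
    with pytest.raises(ValueError):
        rmcode.decode(code, np.zeros(63, dtype=np.uint8))


@settings(derandomize=True, max_examples=50)
@given(a=st.integers(0, 2 ** 5 - 1), b=st.integers(0, 2 ** 5 - 1))
def test_encode_linearity(a, b):
    """encode(a XOR b) = encode(a) XOR encode(b)."""
    code = rmcode.make_code(1, 4)
    ea = rmcode.encode(code, rmcode.bits_from_int(a, code.k))
    eb = rmcode.encode(code, rmcode.bits_from_int(b, code.k))
    eab = rmcode.encode(code, rmcode.bits_from_int(a ^ b, code.k))
    assert np.array_equal(eab, ea ^ eb)


def test_decode_uncorrupted(rng):
    for r, m in [(1, 4), (1, 6), (2, 7)]:
        code = rmcode.make_code(r, m)
        info = rng.integers(0, 2, code.k).astype(np.uint8)
        out = rmcode.decode(code, rmcode.encode(code, info))
        assert np.array_equal(out.info, info)
        assert out.n_corrected == 0
        assert not out.low_confidence


def test_decode_matches_brute_force_within_radius(rng):
    """Majority-logic decoding equals nearest-codeword search for all
    error patterns of weight <= t on small codes."""
    for r, m in [(1, 3), (1, 4), (2, 4)]:
        code = rmcode.make_code(r, m)
        cws = all_codewords(code)
        # linearity makes the error pattern, not the codeword, the hard part;
        # still sample several codewords
        picks = rng.choice(len(cws), size=min(6, len(cws)), replace=False)
        patterns = [p for wt in range(code.t + 1)
                    for p in itertools.combinations(range(code.n), wt)]
        for v in picks:
            base = cws[v]
            for pos in patterns:
                word = base.copy()
                word[list(pos)] ^= 1
                out = rmcode.decode(code, word)
                dists = np.count_nonzero(cws != word, axis=1)
                assert dists.argmin() == v  # oracle: unique nearest codeword
                assert rmcode.int_from_bits(out.info) == v
                assert out.n_corrected == len(pos)
                assert not out.low_confidence


@pytest.mark.parametrize("r,m,trials", [(1, 6, 500), (2, 7, 500)])
def test_decode_monte_carlo_at_radius(r, m, trials, rng):
    """Random payloads with exactly t random flips always recover."""
    code = rmcode.make_code(r, m)
    for _ in range(trials):
        info = rng.integers(0, 2, code.k).astype(np.uint8)
        word = rmcode.encode(code, info)
        pos = rng.choice(code.n, size=code.t, replace=False)
        word[pos] ^= 1
        out = rmcode.decode(code, word)
        assert np.array_equal(out.info, info)
        assert out.n_corrected == code.t


def test_rm16_recovers_with_15_flips(rng):
    """The 64-bit first-order code corrects a full 15-error pattern."""
    code = rmcode.make_code(1, 6)
    info = rmcode.bits_from_int(77, code.k)
    word = rmcode.encode(code, info)
    word[rng.choice(64, 15, replace=False)] ^= 1
    out = rmcode.decode(code, word)
    assert rmcode.int_from_bits(out.info) == 77
    assert out.n_corrected == 15


def test_beyond_radius_is_best_effort_low_confidence(rng):
    """Past the guarantee the decoder still answers, flagged low confidence."""
    code = rmcode.make_code(1, 4)  # t = 3, d = 8
    info = rng.integers(0, 2, code.k).astype(np.uint8)
    word = rmcode.encode(code, info)
    word[rng.choice(16, 4, replace=False)] ^= 1  # weight d/2: tie territory
    out = rmcode.decode(code, word)
    assert out.info.shape == (code.k,)
    if not np.array_equal(out.info, info):
        assert out.low_confidence


def test_capacity_table_five_rows():
    rows = rmcode.capacity_table([
        (10, 1, 6, 36), (12, 1, 7, 16), (12, 2, 7, 16),
        (17, 1, 8, 33), (17, 2, 8, 33)])
    got = [(x.array_size, x.total_bits, x.orientation_bits, x.encoding_bits,
            x.information_units, x.encodable_count, x.correctable) for x in rows]
    assert got == [
        (10, 100, 36, 64, 7, 128, 15),
        (12, 144, 16, 128, 8, 256, 31),
        (12, 144, 16, 128, 29, 2 ** 29, 15),
        (17, 289, 33, 256, 9, 512, 63),
        (17, 289, 33, 256, 37, 2 ** 37, 31),
    ]


def test_capacity_table_rejects_inconsistent_spec():
    with pytest.raises(ValueError):
        rmcode.capacity_table([(10, 1, 7, 36)])   # 2^7 != 64-bit budget
    with pytest.raises(ValueError):
        rmcode.capacity_table([(8, 1, 6, 36)])    # 36 + 64 > 64 cells


def test_payload_bit_round_trip(rng):
    for _ in range(20):
        v = int(rng.integers(0, 2 ** 37))
        assert rmcode.int_from_bits(rmcode.bits_from_int(v, 37)) == v
    with pytest.raises(ValueError):
        rmcode.bits_from_int(128, 7)
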