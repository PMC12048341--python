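"""Binary Reed-Muller codes RM(r, m): construction, encoding, majority-logic decoding.

A Reed-Muller code of order ``r`` and length ``n = 2**m`` treats each codeword
position as a point of GF(2)^m and each information bit as the coefficient of a
degree-<= r monomial in the m point coordinates.  The code encodes
``k = sum_{i<=r} C(m, i)`` information bits, has minimum distance
``d = 2**(m - r)`` and guarantees correction of ``t = 2**(m - r - 1) - 1``
arbitrary bit errors (for ``r < m``).  This trade-off between payload size and
correction radius is what lets a dissolvable microneedle patch keep its message
readable while individual fluorescent bits fade or are cleared over months.

Decoding uses Reed's majority-logic algorithm: coefficients are peeled off one
degree level at a time, each decided by a majority vote over parity sums taken
on the cosets of the monomial's characteristic subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "RMCode",
    "CapacityRow",
    "make_code",
    "encode",
    "decode",
    "capacity_table",
]


def _monomials(r: int, m: int) -> list[tuple[int, ...]]:
    """Degree-ascending, lexicographic-within-degree monomial order.

    Each monomial is the tuple of variable indices it multiplies; () is the
    constant monomial.  This fixed order defines both the generator row order
    and the information-bit order.
    """
    out: list[tuple[int, ...]] = []
    for deg in range(r + 1):
        out.extend(combinations(range(m), deg))
    return out


def _evaluate_monomial(mono: tuple[int, ...], m: int) -> np.ndarray:
    """Evaluate prod_{i in mono} x_i over all 2**m points in counting order.

    Point ``p`` assigns variable ``x_i`` the i-th bit of ``p``.
    """
    n = 1 << m
    points = np.arange(n, dtype=np.uint32)
    row = np.ones(n, dtype=np.uint8)
    for i in mono:
        row &= ((points >> i) & 1).astype(np.uint8)
    return row


@dataclass(frozen=True)
class RMCode:
    """A constructed RM(r, m) code with its generator and derived capacities."""

    r: int
    m: int
    n: int
    k: int
    d: int
    t: int
    monomials: tuple[tuple[int, ...], ...]
    generator: np.ndarray = field(repr=False)  # (k, n) uint8 over GF(2)

    def __str__(self) -> str:  # e.g. "RM(1, 6)"
        return f"RM({self.r}, {self.m})"


@dataclass(frozen=True)
class CapacityRow:
    """One row of the array-capacity table for an N x N patch layout."""

    array_size: int
    total_bits: int
    orientation_bits: int
    encoding_bits: int
    code: str
    information_units: int
    encodable_count: int
    correctable: int


@dataclass(frozen=True)
class DecodeOutcome:
    """Result of majority-logic decoding."""

    info: np.ndarray
    n_corrected: int
    n_ties: int
    low_confidence: bool


def make_code(r: int, m: int) -> RMCode:
    """Construct RM(r, m) from monomial evaluations.

    Raises
    ------
    ValueError
        If ``r > m``, ``r < 0`` or ``m < 1``.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if r < 0 or r > m:
        raise ValueError(f"order must satisfy 0 <= r <= m, got r={r}, m={m}")
    monos = _monomials(r, m)
    gen = np.stack([_evaluate_monomial(mo, m) for mo in monos])
    n = 1 << m
    k = sum(comb(m, i) for i in range(r + 1))
    d = 1 << (m - r)
    t = (1 << (m - r - 1)) - 1 if r < m else 0
    return RMCode(r=r, m=m, n=n, k=k, d=d, t=t,
                  monomials=tuple(monos), generator=gen)


def _as_bits(x, length: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=np.uint8).ravel()
    if arr.size != length:
        raise ValueError(f"{name} must have length {length}, got {arr.size}")
    if not np.all((arr == 0) | (arr == 1)):
        raise ValueError(f"{name} must be binary (0/1)")
    return arr


def encode(code: RMCode, info) -> np.ndarray:
    """Encode k information bits into an n-bit codeword (info . G over GF(2))."""
    bits = _as_bits(info, code.k, "info")
    return (bits @ code.generator) & 1


def decode(code: RMCode, word) -> DecodeOutcome:
    """Reed majority-logic decoding of an n-bit received word.

    Coefficients of the highest remaining degree are each decided by a
    majority vote: for monomial with variable set S, every assignment of the
    variables outside S contributes one vote, namely the XOR of the received
    word over the 2**|S| points of the corresponding coset.  Decided
    contributions are XOR-ed out and the next degree level is processed.

    Even vote splits resolve to 0 and are counted; any tie, or a residual
    error weight beyond the guaranteed radius, marks the result low
    confidence.  The decoder always returns its best effort.
    """
    y = _as_bits(word, code.n, "word").copy()
    m = code.m
    coeffs: dict[tuple[int, ...], int] = {}
    n_ties = 0
    points = np.arange(code.n, dtype=np.uint32)

    for deg in range(code.r, -1, -1):
        level = [mo for mo in code.monomials if len(mo) == deg]
        decided: dict[tuple[int, ...], int] = {}
        for mo in level:
            comp = [i for i in range(m) if i not in mo]
            # index of each point within the complement subcube
            idx = np.zeros(code.n, dtype=np.int64)
            for rank, i in enumerate(comp):
                idx |= ((points >> i) & 1).astype(np.int64) << rank
            votes = np.bincount(idx, weights=y, minlength=1 << len(comp))
            votes = votes.astype(np.int64) & 1
            ones = int(votes.sum())
            half = votes.size / 2
            if ones > half:
                decided[mo] = 1
            else:
                if ones == half:
                    n_ties += 1
                decided[mo] = 0
        # peel this degree level off the residual word
        for mo, a in decided.items():
            if a:
                y ^= _evaluate_monomial(mo, m)
        coeffs.update(decided)

    info = np.array([coeffs[mo] for mo in code.monomials], dtype=np.uint8)
    reencoded = encode(code, info)
    n_corrected = int(np.count_nonzero(reencoded ^ _as_bits(word, code.n, "word")))
    low_confidence = n_ties > 0 or n_corrected > code.t
    return DecodeOutcome(info=info, n_corrected=n_corrected,
                         n_ties=n_ties, low_confidence=low_confidence)


def capacity_table(specs) -> list[CapacityRow]:
    """Build capacity rows for (N, r, m, orientation_bits) layout specs.

    Every derived quantity comes from the constructed code; nothing is looked
    up.  ``encoding_bits = 2**m`` must equal the usable string-bit budget
    ``2**floor(log2(N*N))`` and fit alongside the orientation cells.
    """
    rows = []
    for (N, r, m, orientation_bits) in specs:
        code = make_code(r, m)
        total = N * N
        usable = 1 << int(np.floor(np.log2(total)))
        if code.n != usable:
            raise ValueError(
                f"code length {code.n} does not match the {N}x{N} string-bit "
                f"budget 2^floor(log2({total})) = {usable}")
        if orientation_bits + code.n > total:
            raise ValueError(
                f"{orientation_bits} orientation + {code.n} encoding bits "
                f"exceed the {total} cells of a {N}x{N} array")
        rows.append(CapacityRow(
            array_size=N, total_bits=total,
            orientation_bits=orientation_bits, encoding_bits=code.n,
            code=str(code), information_units=code.k,
            encodable_count=1 << code.k, correctable=code.t))
    return rows


def bits_from_int(value: int, k: int) -> np.ndarray:
    """Big-endian bit expansion of a payload integer onto k information bits."""
    if value < 0 or value >= (1 << k):
        raise ValueError(f"payload {value} out of range for {k} information bits")
    return np.array([(value >> (k - 1 - i)) & 1 for i in range(k)], dtype=np.uint8)


def int_from_bits(bits) -> int:
    """Inverse of :func:`bits_from_int`."""
    out = 0
    for b in np.asarray(bits, dtype=np.uint8).ravel():
        out = (out << 1) | int(b)
    return out
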