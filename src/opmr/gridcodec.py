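"""Mapping codewords onto N x N patch grids: orientation markers, XOR mask, rotation.

A physical patch is an N x N array of needles, each one binary bit (dye loaded
= ON).  Corner cells are reserved as orientation markers — three corners ON
and the bottom-right corner OFF — so a captured image, which the rectification
step can only normalise up to a 90-degree ambiguity, can be rotated into
canonical position by comparing corners against their expected values.  The
remaining cells carry the error-correction codeword in raster order, XOR-ed
with a fixed pseudo-random mask so the fabricated pattern is roughly half ON
regardless of payload (and unreadable without the mask).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridTemplate",
    "MaskSpec",
    "OrientationAmbiguityError",
    "make_template",
    "place_bits",
    "extract_bits",
    "make_mask",
    "apply_mask",
    "detect_orientation",
]


class OrientationAmbiguityError(ValueError):
    """Two or more rotations fit the corner markers equally well."""


@dataclass(frozen=True)
class GridTemplate:
    """Partition of an N x N grid into marker cells and ordered data cells."""

    N: int
    #: {(row, col): expected 0/1 marker value}
    reserved: dict[tuple[int, int], int]
    #: raster-ordered non-reserved cells; the first ``encoding_bits`` carry
    #: codeword bits, any surplus is fixed OFF
    data_order: tuple[tuple[int, int], ...]
    encoding_bits: int

    @property
    def marker_grid(self) -> np.ndarray:
        """Expected marker values on an otherwise-zero grid."""
        g = np.zeros((self.N, self.N), dtype=np.uint8)
        for (i, j), v in self.reserved.items():
            g[i, j] = v
        return g


@dataclass(frozen=True)
class MaskSpec:
    """Fixed XOR obfuscation mask, reproducible from its seed."""

    N: int
    mask: np.ndarray  # (N, N) uint8
    seed: int


def _corner_blocks(N: int, s: int) -> dict[tuple[int, int], int]:
    """Four s x s corner blocks; top-left/top-right/bottom-left ON, bottom-right OFF."""
    res: dict[tuple[int, int], int] = {}
    for di in range(s):
        for dj in range(s):
            res[(di, dj)] = 1                      # top-left
            res[(di, N - 1 - dj)] = 1              # top-right
            res[(N - 1 - di, dj)] = 1              # bottom-left
            res[(N - 1 - di, N - 1 - dj)] = 0      # bottom-right
    return res


def make_template(N: int) -> GridTemplate:
    """Build the marker/data layout for an N x N patch.

    Native layouts: 10x10 uses four 3x3 corners (36 marker cells, 64 data),
    12x12 four 2x2 corners (16, 128), 17x17 three 3x3 ON corners plus a 3x2
    OFF block at the bottom-right (33, 256).  Other N >= 6 use the largest
    corner side s with ``4*s*s <= N*N - 2**floor(log2(N*N))``; data cells
    beyond the string-bit budget are fixed OFF.
    """
    if N < 6:
        raise ValueError(f"grid side must be >= 6 to host markers, got {N}")
    total = N * N
    encoding_bits = 1 << int(np.floor(np.log2(total)))
    if N == 10:
        reserved = _corner_blocks(10, 3)
    elif N == 12:
        reserved = _corner_blocks(12, 2)
    elif N == 17:
        reserved = {}
        for di in range(3):
            for dj in range(3):
                reserved[(di, dj)] = 1
                reserved[(di, 16 - dj)] = 1
                reserved[(16 - di, dj)] = 1
        for di in range(3):            # 3 rows tall, 2 cols wide, all OFF
            for dj in range(2):
                reserved[(16 - di, 16 - dj)] = 0
    else:
        budget = total - encoding_bits
        s = int(np.floor(np.sqrt(budget / 4)))
        if s < 1:
            raise ValueError(
                f"{N}x{N} grid cannot host corner markers plus "
                f"{encoding_bits} data bits")
        reserved = _corner_blocks(N, s)
    data_order = tuple((i, j) for i in range(N) for j in range(N)
                       if (i, j) not in reserved)
    if encoding_bits > len(data_order):
        raise ValueError(
            f"{N}x{N} template has only {len(data_order)} data cells for "
            f"{encoding_bits} string bits")
    return GridTemplate(N=N, reserved=reserved, data_order=data_order,
                        encoding_bits=encoding_bits)


def place_bits(template: GridTemplate, codeword) -> np.ndarray:
    """Write marker values and the codeword (raster order) onto a fresh grid."""
    bits = np.asarray(codeword, dtype=np.uint8).ravel()
    if bits.size != template.encoding_bits:
        raise ValueError(
            f"codeword length {bits.size} != template encoding bits "
            f"{template.encoding_bits}")
    grid = np.zeros((template.N, template.N), dtype=np.uint8)
    for (i, j), v in template.reserved.items():
        grid[i, j] = v
    for b, (i, j) in zip(bits, template.data_order):
        grid[i, j] = b
    return grid


def extract_bits(template: GridTemplate, grid: np.ndarray) -> np.ndarray:
    """Read data cells back in raster order, truncated to the string-bit budget."""
    grid = np.asarray(grid, dtype=np.uint8)
    if grid.shape != (template.N, template.N):
        raise ValueError(f"grid shape {grid.shape} != template {template.N}")
    cells = template.data_order[:template.encoding_bits]
    return np.array([grid[i, j] for i, j in cells], dtype=np.uint8)


def make_mask(N: int, seed: int, max_tries: int = 1000) -> MaskSpec:
    """Pseudo-random ~half-ON mask, zero on the template's marker cells.

    Drawn Bernoulli(1/2) per data cell and redrawn (deterministically) until
    the data-cell ON fraction lies in [0.4, 0.6], so the masked pattern is
    guaranteed close to half ON / half OFF.
    """
    template = make_template(N)
    rng = np.random.default_rng(seed)
    n_data = len(template.data_order)
    for _ in range(max_tries):
        bits = rng.integers(0, 2, n_data, dtype=np.uint8)
        frac = bits.mean()
        if 0.4 <= frac <= 0.6:
            mask = np.zeros((N, N), dtype=np.uint8)
            for b, (i, j) in zip(bits, template.data_order):
                mask[i, j] = b
            return MaskSpec(N=N, mask=mask, seed=seed)
    raise RuntimeError("mask rejection sampling did not converge")  # pragma: no cover


def apply_mask(grid: np.ndarray, mask: MaskSpec) -> np.ndarray:
    """Cell-wise XOR with the mask; its own inverse, so it both encrypts and decrypts."""
    grid = np.asarray(grid, dtype=np.uint8)
    if grid.shape != mask.mask.shape:
        raise ValueError(f"grid shape {grid.shape} != mask shape {mask.mask.shape}")
    return grid ^ mask.mask


def detect_orientation(grid: np.ndarray, template: GridTemplate):
    """Find the 90-degree rotation that matches the corner markers.

    Tries all four rotations of ``grid`` and scores each by the number of
    marker-cell mismatches against the template's expected values.  Returns
    ``(rotation_deg, normalized_grid, marker_errors)`` where ``rotation_deg``
    is the counter-clockwise rotation applied to normalise.

    Raises
    ------
    OrientationAmbiguityError
        If two rotations tie at minimum mismatch (e.g. symmetric corruption).
    """
    grid = np.asarray(grid, dtype=np.uint8)
    if grid.shape != (template.N, template.N):
        raise ValueError(f"grid shape {grid.shape} != template {template.N}")
    expected = template.marker_grid
    cells = list(template.reserved)
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    scores = []
    candidates = []
    for k in range(4):
        rotated = np.rot90(grid, k)
        scores.append(int(np.count_nonzero(
            rotated[rows, cols] != expected[rows, cols])))
        candidates.append(rotated)
    order = np.argsort(scores, kind="stable")
    best, second = order[0], order[1]
    if scores[best] == scores[second]:
        raise OrientationAmbiguityError(
            f"rotations {best * 90} and {second * 90} deg both leave "
            f"{scores[best]} marker mismatches")
    return int(best) * 90, candidates[best], scores[best]


def fabrication_export(grid: np.ndarray):
    """ON-cell coordinates as a DataFrame with columns ``row,col`` (mask-tape cutting)."""
    import pandas as pd

    rows, cols = np.nonzero(np.asarray(grid, dtype=np.uint8))
    return pd.DataFrame({"row": rows, "col": cols})
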