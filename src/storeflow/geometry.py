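"""Hierarchical quadrant coding of a square occupancy grid.

A store floor is discretised into a ``2^depth × 2^depth`` grid of square
cells. Each cell is named by a fixed-length string in which the character at
level ``d`` (1-based) picks one of four quadrants of the recursive
subdivision at that level. Every level uses its own disjoint 4-letter
alphabet block (level 1: ``a–d``, level 2: ``e–h``, …), so the level of any
character is recoverable from the character alone and codes that share a
prefix are spatially close (they lie in the same quadtree square).

Quadrant ordering is Z-order: at each level the quadrant index is
``2 * row_bit + col_bit`` with bits taken most-significant first, the origin
at the min-x/min-y corner and rows increasing with y.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Tuple

__all__ = [
    "GridSpec",
    "CellRangeError",
    "CodeFormatError",
    "encode_cell",
    "decode_code",
    "validate_code",
    "point_to_cell",
    "cell_center",
    "prefix_region",
]

#: Maximum supported recursion depth (the level blocks must fit in a–z).
MAX_DEPTH = 6

_LETTERS = string.ascii_lowercase


class CellRangeError(ValueError):
    """A cell index or physical point lies outside the grid."""


class CodeFormatError(ValueError):
    """A location code is malformed; the message names the bad position."""


def level_block(level: int) -> str:
    """The 4-letter alphabet block of a 1-based subdivision level."""
    if not 1 <= level <= MAX_DEPTH:
        raise ValueError(f"level must be in 1..{MAX_DEPTH}, got {level}")
    start = 4 * (level - 1)
    return _LETTERS[start : start + 4]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the discretised store.

    Parameters
    ----------
    n_cols, n_rows:
        Cell counts per side; must both equal ``2 ** depth``.
    depth:
        Quadtree recursion depth == number of characters per cell code.
    cell_size_m:
        Physical edge length of one cell in meters.
    origin:
        Corner convention tag; only ``"lower-left"`` is defined (x grows
        with columns, y grows with rows).
    """

    n_cols: int
    n_rows: int
    depth: int
    cell_size_m: float
    origin: str = field(default="lower-left")

    def __post_init__(self) -> None:
        if self.depth < 1 or self.depth > MAX_DEPTH:
            raise ValueError(f"depth must be in 1..{MAX_DEPTH}, got {self.depth}")
        side = 2**self.depth
        if self.n_cols != side or self.n_rows != side:
            raise ValueError(
                "grid must be square with side 2**depth "
                f"(expected {side}×{side}, got {self.n_cols}×{self.n_rows})"
            )
        if not self.cell_size_m > 0:
            raise ValueError("cell_size_m must be positive")
        if self.origin != "lower-left":
            raise ValueError(f"unknown origin convention {self.origin!r}")

    # -- presets ---------------------------------------------------------
    @classmethod
    def full(cls, cell_size_m: float = 0.25) -> "GridSpec":
        """The full-scale 64×64 store grid (depth 6)."""
        return cls(64, 64, 6, cell_size_m)

    @classmethod
    def desk(cls, cell_size_m: float = 0.5) -> "GridSpec":
        """A small 16×16 grid (depth 4) sized for CPU experiments."""
        return cls(16, 16, 4, cell_size_m)

    # -- config round trip ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_cols": self.n_cols,
            "n_rows": self.n_rows,
            "depth": self.depth,
            "cell_size_m": self.cell_size_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            n_cols=int(d["n_cols"]),
            n_rows=int(d["n_rows"]),
            depth=int(d["depth"]),
            cell_size_m=float(d["cell_size_m"]),
        )

    @property
    def width_m(self) -> float:
        return self.n_cols * self.cell_size_m

    @property
    def height_m(self) -> float:
        return self.n_rows * self.cell_size_m

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows


def encode_cell(col: int, row: int, grid: GridSpec) -> str:
    """Encode 0-based cell indices into a ``grid.depth``-character code."""
    if not (0 <= col < grid.n_cols and 0 <= row < grid.n_rows):
        raise CellRangeError(
            f"cell ({col}, {row}) outside {grid.n_cols}×{grid.n_rows} grid"
        )
    chars = []
    for level in range(grid.depth):
        shift = grid.depth - 1 - level
        q = 2 * ((row >> shift) & 1) + ((col >> shift) & 1)
        chars.append(_LETTERS[4 * level + q])
    return "".join(chars)


def decode_code(code: str, grid: GridSpec) -> Tuple[int, int]:
    """Inverse of :func:`encode_cell`; raises :class:`CodeFormatError`."""
    _check_code(code, grid)
    col = 0
    row = 0
    for level, ch in enumerate(code):
        q = ord(ch) - ord("a") - 4 * level
        col = (col << 1) | (q & 1)
        row = (row << 1) | (q >> 1)
    return col, row


def _check_code(code: str, grid: GridSpec) -> None:
    if len(code) != grid.depth:
        raise CodeFormatError(
            f"code {code!r} has length {len(code)}, expected {grid.depth}"
        )
    for i, ch in enumerate(code):
        block = level_block(i + 1)
        if ch not in block:
            raise CodeFormatError(
                f"character {ch!r} at position {i} not in level-{i + 1} "
                f"block {block!r}"
            )


def validate_code(s: str, grid: GridSpec) -> bool:
    """True iff ``s`` is a well-formed code for this grid (total function)."""
    try:
        _check_code(s, grid)
    except CodeFormatError:
        return False
    return True


def point_to_cell(x_m: float, y_m: float, grid: GridSpec) -> Tuple[int, int]:
    """Map a physical point to its (col, row) cell; cells are half-open."""
    if not (0 <= x_m < grid.width_m and 0 <= y_m < grid.height_m):
        raise CellRangeError(
            f"point ({x_m}, {y_m}) outside store bounds "
            f"[0, {grid.width_m}) × [0, {grid.height_m})"
        )
    return int(x_m // grid.cell_size_m), int(y_m // grid.cell_size_m)


def cell_center(col: int, row: int, grid: GridSpec) -> Tuple[float, float]:
    """Physical center of a cell, in meters from the origin corner."""
    if not (0 <= col < grid.n_cols and 0 <= row < grid.n_rows):
        raise CellRangeError(
            f"cell ({col}, {row}) outside {grid.n_cols}×{grid.n_rows} grid"
        )
    s = grid.cell_size_m
    return (col + 0.5) * s, (row + 0.5) * s


def prefix_region(prefix: str, grid: GridSpec) -> Tuple[int, int, int, int]:
    """Bounding box ``(col_min, row_min, col_max, row_max)`` of a code prefix.

    The region is the axis-aligned square of side ``2**(depth - len(prefix))``
    cells containing exactly the cells whose codes start with ``prefix``.
    """
    p = len(prefix)
    if p > grid.depth:
        raise CodeFormatError(f"prefix {prefix!r} longer than depth {grid.depth}")
    col = 0
    row = 0
    for level, ch in enumerate(prefix):
        block = level_block(level + 1)
        if ch not in block:
            raise CodeFormatError(
                f"character {ch!r} at position {level} not in level-{level + 1} "
                f"block {block!r}"
            )
        q = ord(ch) - ord("a") - 4 * level
        col = (col << 1) | (q & 1)
        row = (row << 1) | (q >> 1)
    side = 2 ** (grid.depth - p)
    col_min = col * side
    row_min = row * side
    return col_min, row_min, col_min + side - 1, row_min + side - 1


@lru_cache(maxsize=8)
def _code_table(grid: GridSpec) -> tuple:
    # row-major: table[row * n_cols + col]
    return tuple(
        encode_cell(c, r, grid) for r in range(grid.n_rows) for c in range(grid.n_cols)
    )


def code_of(col: int, row: int, grid: GridSpec) -> str:
    """Cached :func:`encode_cell`; fast path for corpus building."""
    if not (0 <= col < grid.n_cols and 0 <= row < grid.n_rows):
        raise CellRangeError(
            f"cell ({col}, {row}) outside {grid.n_cols}×{grid.n_rows} grid"
        )
    return _code_table(grid)[row * grid.n_cols + col]


def all_codes(grid: GridSpec) -> tuple:
    """All cell codes of the grid in row-major order (cached)."""
    return _code_table(grid)
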