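"""Partition of a frame into the fixed-size subimage grid.

A 512 x 512 angiograph at the default tile size of 32 yields a 16 x 16 grid
of subimages p(i, j).  Tiles carry a vascular/nonvascular label assigned by
the classification stage; the regional-expansion stage then works on the
clipped 3 x 3 block of tiles around each vascular tile.

Tile indices are 0-based ``(i, j)`` = (tile row, tile col) internally;
user-facing CSV reports use 1-based indices.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TileLabel", "TileGrid", "tile_image", "tile_neighborhood"]


class TileLabel(enum.IntEnum):
    UNKNOWN = 0
    VASCULAR = 1
    NONVASCULAR = 2


@dataclass
class TileGrid:
    """A grayscale image partitioned into square tiles with per-tile labels."""

    image: np.ndarray
    tile_size: int
    labels: np.ndarray = field(default=None)  # (n_rows, n_cols) of TileLabel

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = np.full(
                (self.n_rows, self.n_cols), TileLabel.UNKNOWN, dtype=np.int8
            )

    @property
    def n_rows(self) -> int:
        return self.image.shape[0] // self.tile_size

    @property
    def n_cols(self) -> int:
        return self.image.shape[1] // self.tile_size

    def tile_slices(self, i: int, j: int) -> tuple[slice, slice]:
        """Pixel slices of tile (i, j)."""
        self._check_index(i, j)
        t = self.tile_size
        return slice(i * t, (i + 1) * t), slice(j * t, (j + 1) * t)

    def tile(self, i: int, j: int) -> np.ndarray:
        """View of tile (i, j)'s pixels."""
        rs, cs = self.tile_slices(i, j)
        return self.image[rs, cs]

    def block_slices(self, i: int, j: int) -> tuple[slice, slice]:
        """Pixel slices of the clipped 3 x 3 tile block centred on (i, j)."""
        self._check_index(i, j)
        t = self.tile_size
        r0 = max(i - 1, 0) * t
        r1 = min(i + 2, self.n_rows) * t
        c0 = max(j - 1, 0) * t
        c1 = min(j + 2, self.n_cols) * t
        return slice(r0, r1), slice(c0, c1)

    def tiles_with_label(self, label: TileLabel) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.labels == label)]

    def _check_index(self, i: int, j: int) -> None:
        if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
            raise IndexError(
                f"tile index ({i}, {j}) outside {self.n_rows} x {self.n_cols} grid"
            )


def tile_image(img: np.ndarray, tile_size: int = 32) -> TileGrid:
    """Divide *img* into ``tile_size`` x ``tile_size`` subimages.

    Every pixel belongs to exactly one tile and all labels start UNKNOWN.
    Dimensions that are not divisible by *tile_size* are rejected rather than
    padded, so pixel accounting stays exact.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    h, w = img.shape
    if h % tile_size or w % tile_size:
        raise ValueError(
            f"image dimensions {h} x {w} not divisible by tile size {tile_size}"
        )
    return TileGrid(image=img, tile_size=tile_size)


def tile_neighborhood(grid: TileGrid, i: int, j: int) -> list[tuple[int, int]]:
    """The 3 x 3 block of tile indices around (i, j), clipped at grid borders.

    Includes the centre tile itself; an interior tile has 9 entries, a corner
    tile 4.  Returned in row-major order.
    """
    grid._check_index(i, j)
    out = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            ni, nj = i + di, j + dj
            if 0 <= ni < grid.n_rows and 0 <= nj < grid.n_cols:
                out.append((ni, nj))
    return out
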