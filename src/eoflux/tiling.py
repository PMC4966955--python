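"""Tiled (hierarchical) processing of large grids.

A full-resolution EOF analysis of a continental grid is memory-bound, so
the grid is partitioned into rectangular spatial tiles and the analysis
runs independently per tile, with results stitched back in place. Tiles are
disjoint and cover the grid exactly once; edge tiles may be smaller than
the nominal size. No overlap or seam blending is applied — seam artifacts
are accepted and measured rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import ContractError, ParameterError
from .field import SpaceTimeField

__all__ = ["TileLayout", "make_layout", "map_tiles", "extract_tile", "insert_tile"]


@dataclass(frozen=True)
class TileLayout:
    """Disjoint exact cover of a grid by rectangular tiles.

    ``tiles`` holds half-open pixel ranges ``(r0, r1, c0, c1)`` per tile.
    """

    grid_shape: tuple[int, int]
    tile_rows: int
    tile_cols: int
    tiles: tuple[tuple[int, int, int, int], ...]

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)


def make_layout(grid_shape: tuple[int, int], tile_rows: int = 200,
                tile_cols: int = 200) -> TileLayout:
    """Partition ``grid_shape`` into tiles of nominal size ``tile_rows x tile_cols``.

    A tile larger than the grid yields a single tile covering everything.
    Tile dimensions must be at least 2.
    """
    rows, cols = int(grid_shape[0]), int(grid_shape[1])
    if tile_rows < 2 or tile_cols < 2:
        raise ParameterError(f"tile dims must be >= 2, got {tile_rows}x{tile_cols}")
    tiles = []
    for r0 in range(0, rows, tile_rows):
        for c0 in range(0, cols, tile_cols):
            tiles.append((r0, min(r0 + tile_rows, rows),
                          c0, min(c0 + tile_cols, cols)))
    return TileLayout(grid_shape=(rows, cols), tile_rows=tile_rows,
                      tile_cols=tile_cols, tiles=tuple(tiles))


def extract_tile(field: SpaceTimeField, tile: tuple[int, int, int, int]) -> SpaceTimeField:
    """Cut one tile out of a field as a stand-alone sub-field."""
    r0, r1, c0, c1 = tile
    rows, cols = field.grid_shape
    vals = field.values.reshape(rows, cols, field.n_times)[r0:r1, c0:c1]
    mask = field.mask.reshape(rows, cols, field.n_times)[r0:r1, c0:c1]
    tr, tc = r1 - r0, c1 - c0
    return SpaceTimeField(
        values=vals.reshape(tr * tc, field.n_times).copy(),
        mask=mask.reshape(tr * tc, field.n_times).copy(),
        grid_shape=(tr, tc), times=field.times, pixel_size=field.pixel_size,
    )


def insert_tile(values_out: np.ndarray, mask_out: np.ndarray,
                grid_shape: tuple[int, int], tile: tuple[int, int, int, int],
                tile_field: SpaceTimeField) -> None:
    """Write a processed tile back into full-grid ``(P, N)`` output arrays."""
    r0, r1, c0, c1 = tile
    rows, cols = grid_shape
    n = tile_field.n_times
    tr, tc = r1 - r0, c1 - c0
    values_out.reshape(rows, cols, n)[r0:r1, c0:c1] = \
        tile_field.values.reshape(tr, tc, n)
    mask_out.reshape(rows, cols, n)[r0:r1, c0:c1] = \
        tile_field.mask.reshape(tr, tc, n)


def map_tiles(field: SpaceTimeField, layout: TileLayout,
              op: Callable[[SpaceTimeField], SpaceTimeField]) -> SpaceTimeField:
    """Apply a field→field operation independently to every tile and stitch.

    ``op`` must preserve each tile's grid shape and time axis; a wrong-shaped
    return raises :class:`ContractError` naming the tile.
    """
    if layout.grid_shape != field.grid_shape:
        raise ParameterError(
            f"layout grid {layout.grid_shape} != field grid {field.grid_shape}"
        )
    values_out = np.empty_like(field.values)
    mask_out = np.empty_like(field.mask)
    for i, tile in enumerate(layout.tiles):
        sub = extract_tile(field, tile)
        result = op(sub)
        if (result.grid_shape != sub.grid_shape
                or result.n_times != sub.n_times):
            raise ContractError(
                f"tile {i} {tile}: op returned grid {result.grid_shape} x "
                f"{result.n_times} steps, expected {sub.grid_shape} x {sub.n_times}"
            )
        insert_tile(values_out, mask_out, field.grid_shape, tile, result)
    return field.with_values(values_out, mask=mask_out)
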