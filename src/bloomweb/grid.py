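"""Rectangular simulation grids with a land mask and shoreline distance.

The grid origin is the top-left (north-west) cell; cells are addressed
``(row, col)`` with 0-based indices in row-major order.  Water cells are the
computational domain; land cells are inert and act as no-flux boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["GridSpec"]


@dataclass
class GridSpec:
    """A rectangular grid with land masking.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; both must be at least 2.
    cell_width_km
        Side length of a (square) cell in km; ``cell_area_km2`` is its square.
    land_mask
        Boolean ``(n_rows, n_cols)`` array, ``True`` on land.  Defaults to a
        single land column along the western (left) edge, emulating a
        shoreline with water opening to the open shelf.
    """

    n_rows: int
    n_cols: int
    cell_width_km: float = 5.0
    land_mask: np.ndarray | None = None
    coast_distance: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.cell_width_km <= 0:
            raise ValueError("cell_width_km must be positive")
        if self.land_mask is None:
            mask = np.zeros((self.n_rows, self.n_cols), dtype=bool)
            mask[:, 0] = True
            self.land_mask = mask
        else:
            self.land_mask = np.asarray(self.land_mask, dtype=bool)
            if self.land_mask.shape != (self.n_rows, self.n_cols):
                raise ValueError("land_mask shape mismatch")
        if not (~self.land_mask).any():
            raise ValueError("grid has no water cells")
        self.coast_distance = self._coast_distance()

    # ------------------------------------------------------------------
    def _coast_distance(self) -> np.ndarray:
        """Distance (km) from each water cell to the nearest shoreline.

        Cells orthogonally adjacent to land (or, in an all-water grid, to the
        grid edge) get distance 0; land cells get 0 as well.
        """
        water = ~self.land_mask
        if self.land_mask.any():
            d_cells = ndimage.distance_transform_edt(water)
            d_cells = np.clip(d_cells - 1.0, 0.0, None)
        else:  # shoreline is the grid edge
            rr, cc = np.indices((self.n_rows, self.n_cols))
            d_cells = np.minimum.reduce(
                [rr, cc, self.n_rows - 1 - rr, self.n_cols - 1 - cc]
            ).astype(float)
        d = d_cells * self.cell_width_km
        d[self.land_mask] = 0.0
        return d

    # ------------------------------------------------------------------
    @property
    def cell_area_km2(self) -> float:
        return self.cell_width_km**2

    @property
    def water_mask(self) -> np.ndarray:
        return ~self.land_mask

    @property
    def n_water(self) -> int:
        return int(self.water_mask.sum())

    @property
    def water_rc(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of water cells, row-major order."""
        return np.nonzero(self.water_mask)

    def flatten(self, field2d: np.ndarray) -> np.ndarray:
        """Extract the water cells of a ``(n_rows, n_cols, ...)`` field."""
        return np.asarray(field2d)[self.water_mask]

    def unflatten(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter per-water-cell values back onto the full 2-D grid."""
        values = np.asarray(values)
        out = np.full((self.n_rows, self.n_cols) + values.shape[1:], fill, dtype=float)
        out[self.water_mask] = values
        return out

    def neighbor_indices(self) -> np.ndarray:
        """(4, n_water) indices into the flat water vector for N/S/W/E
        neighbours; -1 where the neighbour is land or outside the grid."""
        idx2d = np.full((self.n_rows, self.n_cols), -1, dtype=int)
        idx2d[self.water_mask] = np.arange(self.n_water)
        rr, cc = self.water_rc
        out = np.full((4, self.n_water), -1, dtype=int)
        for d, (dr, dc) in enumerate([(-1, 0), (1, 0), (0, -1), (0, 1)]):
            r2, c2 = rr + dr, cc + dc
            ok = (r2 >= 0) & (r2 < self.n_rows) & (c2 >= 0) & (c2 < self.n_cols)
            out[d, ok] = idx2d[r2[ok], c2[ok]]
        return out

    @classmethod
    def regular(
        cls,
        n_rows: int,
        n_cols: int,
        cell_width_km: float = 5.0,
        land_cols: int = 1,
    ) -> "GridSpec":
        """A simple shelf: ``land_cols`` land columns on the western edge."""
        mask = np.zeros((n_rows, n_cols), dtype=bool)
        mask[:, :land_cols] = True
        return cls(n_rows, n_cols, cell_width_km, mask)
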