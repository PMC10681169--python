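"""Square-grid quadrat quantification with tissue-coverage filtering.

A grid of square cells (quadrats) is overlaid on the raster; each cell gets
a particle-signal value and a tissue-coverage fraction, and cells whose
coverage falls below a threshold are excluded from statistical analysis so
that airway lumens and off-lobe space do not masquerade as "empty tissue".

Conventions (fixed so outputs are bit-reproducible):

* cell size in pixels = ``round(cell_size_um / microns_per_pixel)``, min 1;
* cells are half-open pixel intervals ``[start, start + size)`` anchored at
  ``origin_px`` — every pixel belongs to exactly one cell, and edge cells
  may be partial;
* partial cells are retained and judged by their *actual* pixel count
  (dropping them would bias lobe margins, padding would dilute coverage);
* ``signal_mode="mask_area"`` counts particle-mask pixels,
  ``"intensity_sum"`` sums particle-channel intensity under the mask. On a
  noiseless rendering the two are affinely related.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .color_masking import ClassMasks
from .image_io import CalibratedImage, um_to_px

__all__ = ["GridSpec", "QuadratTable", "quantify", "sweep_grids"]


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry plus the inclusion criterion.

    The default operating point — 200 um cells with a 90% tissue-coverage
    requirement — is the combination that proved most robust across the
    3 x 4 sweep of grid sizes (100/200/500 um) and coverage criteria
    (50/75/90/98%).
    """

    cell_size_um: float = 200.0
    coverage_threshold: float = 0.90
    origin_px: tuple[int, int] = (0, 0)  # (x, y) grid anchor
    signal_mode: Literal["mask_area", "intensity_sum"] = "mask_area"

    def __post_init__(self) -> None:
        if self.cell_size_um <= 0:
            raise ValueError("cell_size_um must be positive")
        if not 0.0 <= self.coverage_threshold <= 1.0:
            raise ValueError("coverage_threshold must lie in [0, 1]")
        if self.signal_mode not in ("mask_area", "intensity_sum"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")

    def cell_size_px(self, microns_per_pixel: float) -> int:
        """Whole-pixel cell edge; round-half-even via np.rint, floor 1."""
        return max(1, int(np.rint(um_to_px(self.cell_size_um, microns_per_pixel))))


@dataclass
class QuadratTable:
    """Per-cell signal, tissue coverage and inclusion flag.

    ``data`` columns: cell_row, cell_col, signal, tissue_fraction, included,
    n_pixels. Indices are grid coordinates relative to the origin (negative
    when the origin is shifted into the raster interior).
    """

    data: pd.DataFrame
    grid: GridSpec
    cell_size_px: int
    image_shape: tuple[int, int]
    microns_per_pixel: float
    image_id: str = ""

    @property
    def included(self) -> pd.DataFrame:
        return self.data[self.data["included"]]

    @property
    def included_signals(self) -> np.ndarray:
        return self.included["signal"].to_numpy(dtype=float)

    def total_signal(self) -> float:
        return float(self.data["signal"].sum())

    def to_csv(self, path: str | Path) -> Path:
        """CSV of the table plus a JSON sidecar carrying the grid metadata."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps({
            "grid": asdict(self.grid),
            "cell_size_px": self.cell_size_px,
            "image_shape": list(self.image_shape),
            "microns_per_pixel": self.microns_per_pixel,
            "image_id": self.image_id,
        }, indent=2))
        return path


def _cell_indices(n: int, origin: int, size: int) -> np.ndarray:
    """Cell index of each of n pixel coordinates along one axis."""
    return np.floor_divide(np.arange(n) - origin, size)


def quantify(
    masks: ClassMasks,
    image: CalibratedImage,
    grid: GridSpec | None = None,
    image_id: str = "",
) -> QuadratTable:
    """Overlay the grid and tabulate per-cell signal and tissue coverage.

    Signal is conserved exactly: summing the ``signal`` column reproduces
    the whole-image total regardless of grid size or origin.
    """
    grid = grid or GridSpec()
    h, w = image.shape
    if masks.particle_mask.shape != (h, w):
        raise ValueError(f"mask shape {masks.particle_mask.shape} != image shape {(h, w)}")
    size = grid.cell_size_px(image.microns_per_pixel)
    ox, oy = grid.origin_px

    row_cell = _cell_indices(h, oy, size)   # per pixel-row
    col_cell = _cell_indices(w, ox, size)   # per pixel-col
    r0, c0 = int(row_cell.min()), int(col_cell.min())
    n_r = int(row_cell.max()) - r0 + 1
    n_c = int(col_cell.max()) - c0 + 1
    flat = (row_cell[:, None] - r0) * n_c + (col_cell[None, :] - c0)

    if grid.signal_mode == "mask_area":
        signal_px = masks.particle_mask.astype(np.float64)
    else:
        chan = image.channel_index("particle")
        signal_px = np.where(masks.particle_mask, image.pixels[:, :, chan], 0).astype(np.float64)

    n_cells = n_r * n_c
    flat_r = flat.ravel()
    signal = np.bincount(flat_r, weights=signal_px.ravel(), minlength=n_cells)
    tissue = np.bincount(flat_r, weights=masks.tissue_mask.ravel().astype(np.float64),
                         minlength=n_cells)
    n_px = np.bincount(flat_r, minlength=n_cells)

    occupied = n_px > 0  # grid rectangle cells that actually contain pixels
    idx = np.nonzero(occupied)[0]
    tissue_fraction = tissue[idx] / n_px[idx]
    df = pd.DataFrame({
        "cell_row": idx // n_c + r0,
        "cell_col": idx % n_c + c0,
        "signal": signal[idx],
        "tissue_fraction": tissue_fraction,
        "included": tissue_fraction >= grid.coverage_threshold,
        "n_pixels": n_px[idx],
    })
    return QuadratTable(
        data=df, grid=grid, cell_size_px=size, image_shape=(h, w),
        microns_per_pixel=image.microns_per_pixel, image_id=image_id,
    )


def sweep_grids(
    masks: ClassMasks,
    image: CalibratedImage,
    sizes_um: Sequence[float] = (100.0, 200.0, 500.0),
    thresholds: Sequence[float] = (0.50, 0.75, 0.90, 0.98),
    signal_mode: Literal["mask_area", "intensity_sum"] = "mask_area",
    image_id: str = "",
) -> Iterator[QuadratTable]:
    """One table per (cell size, coverage threshold) pair, in the stated
    order — sizes outer, thresholds inner. Defaults are the 3 x 4 sweep
    used to pick the operating point."""
    if not sizes_um or not thresholds:
        raise ValueError("sizes_um and thresholds must be non-empty")
    for size in sizes_um:
        for thr in thresholds:
            yield quantify(
                masks, image,
                GridSpec(cell_size_um=size, coverage_threshold=thr, signal_mode=signal_mode),
                image_id=image_id,
            )
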