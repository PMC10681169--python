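"""Calibrated image container and TIFF input/output.

Pixel coordinate convention, used by every module in this package:
0-based, origin at the top-left corner, ``x`` = column index, ``y`` = row
index. Physical positions in micrometres refer to pixel centres, so the
centre of pixel ``(row, col)`` sits at ``((col + 0.5) * mpp, (row + 0.5) *
mpp)`` where ``mpp`` is the microns-per-pixel calibration.

Calibration is always an explicit input: whole-lobe stitches rarely carry a
trustworthy resolution tag, and a silently guessed scale would corrupt every
micrometre-denominated threshold downstream (grid cell size, proximity
radius, lumen area floor). ``read_image`` therefore refuses to default it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = [
    "CalibratedImage",
    "read_image",
    "write_image",
    "write_mask",
    "read_mask",
    "um_to_px",
    "DEFAULT_RGB_SEMANTICS",
]

#: Channel roles for a plain RGB fluorescence composite: the red plane
#: carries the particle/reporter signal, green carries tissue
#: autofluorescence, blue is unassigned (a nuclear stain when present).
DEFAULT_RGB_SEMANTICS: Mapping[int, str] = {0: "particle", 1: "tissue", 2: "nuclear"}

_ALLOWED_DTYPES = (np.uint8, np.uint16)


@dataclass(frozen=True)
class CalibratedImage:
    """A pixel raster with channel semantics and a physical scale.

    Parameters
    ----------
    pixels
        ``H x W x C`` (or ``H x W``, treated as single-channel) integer
        array, 8- or 16-bit unsigned.
    channel_semantics
        Mapping from channel index to its role (e.g. ``{0: "particle",
        1: "tissue"}``). Roles are free-form strings; the masking module
        looks up ``"particle"`` and ``"tissue"``.
    microns_per_pixel
        Positive, finite edge length of one pixel in micrometres. Pixels
        are assumed square.
    """

    pixels: np.ndarray
    microns_per_pixel: float
    channel_semantics: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, np.newaxis]
        if px.ndim != 3:
            raise ValueError(f"pixels must be HxW or HxWxC, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have H, W >= 1")
        if px.dtype not in _ALLOWED_DTYPES:
            raise ValueError(f"pixels must be uint8 or uint16, got {px.dtype}")
        mpp = float(self.microns_per_pixel)
        if not np.isfinite(mpp) or mpp <= 0:
            raise ValueError(f"microns_per_pixel must be positive and finite, got {mpp}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "microns_per_pixel", mpp)

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) in pixels."""
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def channel_index(self, role: str) -> int:
        """Index of the channel playing ``role``; raises if absent."""
        for idx, r in self.channel_semantics.items():
            if r == role:
                return int(idx)
        raise KeyError(f"no channel with role {role!r} in {dict(self.channel_semantics)}")


def read_image(
    path: str | Path,
    microns_per_pixel: float,
    channel_semantics: Mapping[int, str] | None = None,
) -> CalibratedImage:
    """Read a TIFF into a :class:`CalibratedImage`.

    The raster is loaded unmodified. Calibration is attached from the
    argument and never inferred from file metadata; passing ``None`` or a
    non-positive value is an error.
    """
    if microns_per_pixel is None:
        raise ValueError("microns_per_pixel is mandatory; refusing to default")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pixels = tifffile.imread(path)
    if channel_semantics is None:
        channel_semantics = (
            DEFAULT_RGB_SEMANTICS if pixels.ndim == 3 and pixels.shape[2] == 3 else {0: "signal"}
        )
    return CalibratedImage(pixels, microns_per_pixel, channel_semantics)


def write_image(path: str | Path, image: CalibratedImage) -> Path:
    """Write the raster as a plain TIFF (lossless, shape-preserving)."""
    path = Path(path)
    px = image.pixels
    if px.shape[2] == 1:
        px = px[:, :, 0]
    tifffile.imwrite(path, px)
    return path


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    """Write a boolean raster as a single-channel 8-bit TIFF (0 / 255)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel mask TIFF back to a boolean raster."""
    return np.asarray(tifffile.imread(Path(path))) > 0


def um_to_px(length_um: float, image_or_mpp: CalibratedImage | float) -> float:
    """Convert a micrometre length to (fractional) pixels.

    No rounding happens here; each consumer applies its own documented
    rounding rule (e.g. the grid module rounds cell edges to whole pixels).
    """
    if length_um < 0:
        raise ValueError("length_um must be >= 0")
    mpp = (
        image_or_mpp.microns_per_pixel
        if isinstance(image_or_mpp, CalibratedImage)
        else float(image_or_mpp)
    )
    return float(length_um) / mpp
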