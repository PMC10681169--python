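"""Per-pixel color classification into particle / tissue / autofluorescence.

Whole-lobe fluorescence composites contain three color classes that matter
for deposition quantification: the saturated signal color of the deposits
(red microspheres or dsRed+ cells), ordinary tissue autofluorescence (dim
green), and the bright yellow-shifted autofluorescence that real lung shows
around airways. The third class is *exclusionary* for particle counting —
a bright peri-airway pixel must never be mistaken for a deposit — but it is
plainly tissue, so it still counts toward tissue coverage.

Rules operate in HSV space on single pixels (no spatial context), which
keeps them robust to the brightness gradients typical of tiled stitches.
All thresholds are plain dataclass fields, serialised with every run so a
mask is always reproducible from its provenance record.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Any

import numpy as np
from skimage.color import rgb2hsv

from .image_io import CalibratedImage

__all__ = ["HsvRange", "ColorModel", "ClassMasks", "build_particle_mask",
           "build_tissue_mask", "classify", "remove_small_objects_mask"]


@dataclass(frozen=True)
class HsvRange:
    """An inclusive HSV box; hue wraps around 1.0 when ``hue_lo > hue_hi``."""

    hue_lo: float
    hue_hi: float
    sat_min: float = 0.0
    val_min: float = 0.0

    def contains(self, hsv: np.ndarray) -> np.ndarray:
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        if self.hue_lo <= self.hue_hi:
            hue_ok = (h >= self.hue_lo) & (h <= self.hue_hi)
        else:  # wrap-around (red straddles hue 0)
            hue_ok = (h >= self.hue_lo) | (h <= self.hue_hi)
        return hue_ok & (s >= self.sat_min) & (v >= self.val_min)


@dataclass(frozen=True)
class ColorModel:
    """The three per-pixel classification rules.

    Defaults match the synthetic renderer's palette: red deposits, a
    yellow-green bright peri-airway band, and any sufficiently bright,
    sufficiently saturated pixel counting as tissue. For real images the
    ranges are configuration, not constants.

    ``min_object_px`` optionally removes connected particle components
    smaller than the given pixel area — off by default, since the source
    images are analysed minimally processed.
    """

    particle_rule: HsvRange = HsvRange(hue_lo=0.92, hue_hi=0.08, sat_min=0.5, val_min=0.3)
    autofluor_rule: HsvRange = HsvRange(hue_lo=0.09, hue_hi=0.22, sat_min=0.4, val_min=0.5)
    tissue_value_min: float = 0.12
    tissue_sat_min: float = 0.15
    min_object_px: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def tissue_rule(self, hsv: np.ndarray) -> np.ndarray:
        """Any colored (non-background) pixel: deposits sit on tissue and
        the peri-airway band is tissue, so both also satisfy this rule."""
        return (hsv[..., 2] >= self.tissue_value_min) & (hsv[..., 1] >= self.tissue_sat_min)


@dataclass(frozen=True)
class ClassMasks:
    """The three aligned boolean rasters plus provenance.

    Invariants enforced at construction: identical shapes; particle and
    autofluorescence masks disjoint; tissue mask contains the
    autofluorescence mask.
    """

    particle_mask: np.ndarray
    tissue_mask: np.ndarray
    autofluor_mask: np.ndarray
    model: ColorModel
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        shapes = {self.particle_mask.shape, self.tissue_mask.shape, self.autofluor_mask.shape}
        if shapes != {tuple(self.image_shape)}:
            raise ValueError(f"mask shapes {shapes} do not all equal image shape {self.image_shape}")
        if (self.particle_mask & self.autofluor_mask).any():
            raise ValueError("particle and autofluorescence masks must be disjoint")
        if (self.autofluor_mask & ~self.tissue_mask).any():
            raise ValueError("autofluorescent pixels must be contained in the tissue mask")


def _hsv(image: CalibratedImage) -> np.ndarray:
    px = image.pixels
    if px.shape[2] == 1:
        px = np.repeat(px, 3, axis=2)
    elif px.shape[2] != 3:
        raise ValueError(f"color model expects 1 or 3 channels, got {px.shape[2]}")
    max_val = 255.0 if px.dtype == np.uint8 else 65535.0
    return rgb2hsv(px.astype(np.float64) / max_val)


def remove_small_objects_mask(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop connected components with area < min_px (8-connectivity)."""
    if min_px <= 1:
        return mask
    from scipy import ndimage

    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    areas = np.bincount(lab.ravel())
    keep = areas >= min_px
    keep[0] = False
    return keep[lab]


def build_particle_mask(image: CalibratedImage, model: ColorModel | None = None) -> np.ndarray:
    """True exactly where the particle rule holds and the autofluorescence
    rule does not (exclusionary criterion)."""
    model = model or ColorModel()
    hsv = _hsv(image)
    mask = model.particle_rule.contains(hsv) & ~model.autofluor_rule.contains(hsv)
    if model.min_object_px > 1:
        mask = remove_small_objects_mask(mask, model.min_object_px)
    return mask


def build_tissue_mask(image: CalibratedImage, model: ColorModel | None = None) -> np.ndarray:
    """True where any tissue-characteristic color (including the bright
    peri-airway autofluorescence) is present; lumens and off-lobe
    background are dark and fall below the value floor."""
    model = model or ColorModel()
    hsv = _hsv(image)
    return model.tissue_rule(hsv) | model.autofluor_rule.contains(hsv)


def classify(image: CalibratedImage, model: ColorModel | None = None) -> ClassMasks:
    """Classify every pixel into the three classes at once."""
    model = model or ColorModel()
    hsv = _hsv(image)
    auto = model.autofluor_rule.contains(hsv)
    particle = model.particle_rule.contains(hsv) & ~auto
    if model.min_object_px > 1:
        particle = remove_small_objects_mask(particle, model.min_object_px)
    tissue = model.tissue_rule(hsv) | auto
    return ClassMasks(
        particle_mask=particle,
        tissue_mask=tissue,
        autofluor_mask=auto,
        model=model,
        image_shape=image.shape,
    )
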