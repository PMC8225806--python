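"""Frame normalization, wound segmentation and mask refinement.

The segmentation chain mirrors the first stages of the thermal-image pipeline:
min-max normalization, Otsu thresholding with anomaly-side selection (the
wound is the thermally anomalous region -- warmer when inflamed, cooler when
hypoxic), largest-connected-component extraction with hole filling, and
morphological enhancement (closing then opening with a small disc).  The whole
chain is invariant under any affine temperature map T -> a*T + b with a > 0,
because every step operates on min-max-normalized values.

Masking *excludes* background pixels rather than zeroing them: zero-filling
would inject an artificial grey level into the co-occurrence statistics
computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateMaskError, NoWoundFoundError, WoundTextureError
from .thermal_io import ThermalFrame

#: GLCM statistics on fewer pixel pairs are unstable; a floor must exist.
MIN_WOUND_PIXELS = 64

#: The largest thresholded component must hold at least this fraction of its
#: side's pixels for the frame to count as containing a coherent wound.
MIN_COMPONENT_FRACTION = 0.2


@dataclass
class NormalizedFrame:
    """Min-max scaled frame in [0, 1] plus the scaling used (invertible)."""

    values: np.ndarray
    t_min: float
    t_max: float
    degenerate: bool = False
    source: Optional[ThermalFrame] = None


@dataclass
class WoundMask:
    """Boolean matrix marking wound-bed pixels."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise DegenerateMaskError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class MaskedFrame:
    """A temperature matrix with an attached validity mask.

    Temperatures are never altered; background is excluded, not zeroed.
    """

    pixels: np.ndarray
    mask: np.ndarray

    @property
    def in_mask_values(self) -> np.ndarray:
        return self.pixels[self.mask]


def normalize_thermal(frame: ThermalFrame) -> NormalizedFrame:
    """Min-max scale a frame to [0, 1] over the whole image.

    A constant frame maps to all zeros and is flagged degenerate.
    """
    t_min = float(frame.pixels.min())
    t_max = float(frame.pixels.max())
    if t_max > t_min:
        values = (frame.pixels - t_min) / (t_max - t_min)
        degenerate = False
    else:
        values = np.zeros_like(frame.pixels)
        degenerate = True
    return NormalizedFrame(
        values=values, t_min=t_min, t_max=t_max, degenerate=degenerate, source=frame
    )


def _largest_component(binary: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(binary, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    ))  # 4-connectivity
    if n == 0:
        raise NoWoundFoundError("no connected component found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == int(sizes.argmax())


def detect_wound_contour(
    norm: NormalizedFrame,
    min_wound_pixels: int = MIN_WOUND_PIXELS,
    min_component_fraction: float = MIN_COMPONENT_FRACTION,
) -> WoundMask:
    """Segment the wound bed from a normalized frame (raw mask).

    Otsu's between-class-variance threshold splits the frame in two; the side
    whose values deviate more (mean absolute deviation) from the frame median
    is taken as the wound candidate -- anomalous regions may be warmer or
    cooler than periwound skin.  The largest 4-connected component of that
    side, hole-filled, is the raw mask.  The contour is recoverable as the
    mask boundary.

    Raises :class:`NoWoundFoundError` when the frame is constant, the largest
    component is smaller than ``min_wound_pixels``, or the component holds
    less than ``min_component_fraction`` of its side's pixels (an incoherent,
    noise-like side).
    """
    if norm.degenerate:
        raise NoWoundFoundError("constant frame: nothing to segment")
    v = norm.values
    thr = threshold_otsu(v)
    above = v > thr
    if not above.any() or above.all():
        raise NoWoundFoundError("threshold did not split the frame")
    med = np.median(v)
    dev_above = float(np.abs(v[above] - med).mean())
    dev_below = float(np.abs(v[~above] - med).mean())
    side = above if dev_above >= dev_below else ~above

    component = _largest_component(side)
    size = int(component.sum())
    if size < min_wound_pixels:
        raise NoWoundFoundError(
            f"largest component has {size} px < {min_wound_pixels}"
        )
    if size < min_component_fraction * side.sum():
        raise NoWoundFoundError(
            "no coherent wound region: the anomalous side is scattered "
            f"(largest component holds {size / side.sum():.1%} of it)"
        )
    return WoundMask(ndimage.binary_fill_holes(component))


def refine_mask(raw: WoundMask, radius: int = 2) -> WoundMask:
    """Morphologically enhance a raw mask.

    Closing then opening with a square structuring element of side
    ``2 * radius + 1`` (default radius 2), hole filling, then
    largest-4-connected-component selection.  A square element -- unlike a
    disc -- leaves solid rectangular masks untouched (opening with a disc
    rounds convex corners), so refinement only removes pepper noise, specks
    and holes.  Idempotent on wound-like masks and never grows the bounding
    box by more than the radius.
    """
    if raw.n_pixels == 0:
        raise DegenerateMaskError("raw mask is empty")
    footprint = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
    m = ndimage.binary_closing(raw.mask, structure=footprint)
    m = ndimage.binary_opening(m, structure=footprint)
    m = ndimage.binary_fill_holes(m)
    if not m.any():
        raise DegenerateMaskError("refinement emptied the mask")
    try:
        m = _largest_component(m)
    except NoWoundFoundError as exc:
        raise DegenerateMaskError(str(exc)) from exc
    return WoundMask(m)


def apply_mask(frame: ThermalFrame, mask: Union[WoundMask, np.ndarray]) -> MaskedFrame:
    """Attach a validity mask to a frame without altering temperatures."""
    mask_arr = mask.mask if isinstance(mask, WoundMask) else np.asarray(mask, bool)
    if mask_arr.shape != frame.pixels.shape:
        raise WoundTextureError(
            f"mask shape {mask_arr.shape} != frame shape {frame.pixels.shape}"
        )
    if not mask_arr.any():
        raise DegenerateMaskError("cannot apply an empty mask")
    return MaskedFrame(pixels=frame.pixels, mask=mask_arr)


def thermal_area(
    mask: WoundMask, pixel_area: Union[float, str] = "pixel"
) -> float:
    """Wound area from a refined mask: pixel count times the per-pixel area.

    With ``pixel_area="pixel"`` the raw count is returned -- sufficient for
    week-to-week ratios, which are unit-free.  (Converting to cm^2 would need
    the camera-to-wound distance, which the acquisition does not record.)
    """
    n = mask.n_pixels
    if pixel_area == "pixel":
        return float(n)
    return float(n) * float(pixel_area)


def segment_wound(
    frame: ThermalFrame,
    min_wound_pixels: int = MIN_WOUND_PIXELS,
    morphology_radius: int = 2,
) -> WoundMask:
    """Convenience chain: normalize -> detect contour -> refine."""
    norm = normalize_thermal(frame)
    raw = detect_wound_contour(norm, min_wound_pixels=min_wound_pixels)
    refined = refine_mask(raw, radius=morphology_radius)
    if refined.n_pixels < min_wound_pixels:
        raise DegenerateMaskError(
            f"refined mask has {refined.n_pixels} px < {min_wound_pixels}"
        )
    return refined
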