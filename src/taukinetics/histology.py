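"""AT8 immunohistochemistry quantification.

Brightfield slides are hematoxylin-counterstained (blue-purple nuclei) and
DAB-developed (brown AT8-positive tau). Quantification follows the classical
thresholding pipeline: an HSB window on the 0-255 scale selects nuclei
(another selects DAB), the nucleus mask is dilated, hole-filled and split by
a distance-transform watershed, and particles are kept if their area is at
least 200 px² and their circularity 4 pi A / P² exceeds 0.5. The tau burden
of an image is the DAB-positive pixel area divided by the nucleus count.

The DAB hue window wraps around the hue origin (brown hues straddle 0), so
its hue test is "<= low OR >= high".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import color, morphology, segmentation, measure

__all__ = ["HSBWindow", "QuantResult", "CELL_WINDOW", "TAU_WINDOW",
           "hsb_threshold", "count_cells", "tau_burden", "rgb_from_hsb255"]

#: Minimum particle area (px²) and circularity for a counted cell.
MIN_CELL_AREA = 200
MIN_CIRCULARITY = 0.5


@dataclass(frozen=True)
class HSBWindow:
    """Hue/saturation/brightness intervals on a 0-255 scale.

    With ``hue_wraps`` the hue test passes values <= hue_low OR >= hue_high
    (a circular window through 0, as needed for brown DAB hues).
    """

    hue_low: float
    hue_high: float
    sat_low: float
    sat_high: float
    bri_low: float
    bri_high: float
    hue_wraps: bool = False

    def __post_init__(self) -> None:
        for v in (self.hue_low, self.hue_high, self.sat_low, self.sat_high,
                  self.bri_low, self.bri_high):
            if not (0 <= v <= 255):
                raise ValueError("HSB window bounds must lie in [0, 255]")

    def contains(self, h, s, b):
        h, s, b = (np.asarray(x, dtype=float) for x in (h, s, b))
        if self.hue_wraps:
            hue_ok = (h <= self.hue_low) | (h >= self.hue_high)
        else:
            hue_ok = (h >= self.hue_low) & (h <= self.hue_high)
        return (hue_ok & (s >= self.sat_low) & (s <= self.sat_high)
                & (b >= self.bri_low) & (b <= self.bri_high))


#: Hematoxylin nucleus window: hue 108-200, saturation 25-141, brightness 145-230.
CELL_WINDOW = HSBWindow(108, 200, 25, 141, 145, 230)

#: DAB tau window: hue <= 44 or >= 222 (wrapping), saturation >= 42,
#: brightness <= 206.
TAU_WINDOW = HSBWindow(44, 222, 42, 255, 0, 206, hue_wraps=True)


@dataclass(frozen=True)
class QuantResult:
    """Per-image quantification: nucleus count, tau pixel area, burden."""

    cell_count: int
    tau_area_px: int
    burden: Optional[float]  # None when no cells were found

    def __post_init__(self) -> None:
        if self.cell_count < 0 or self.tau_area_px < 0:
            raise ValueError("counts must be nonnegative")


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image with 3 channels")
    if image.dtype != np.uint8:
        raise ValueError("expected 8-bit channels (uint8)")
    return image


def _hsb255(image: np.ndarray) -> tuple:
    hsv = color.rgb2hsv(image)
    return hsv[..., 0] * 255.0, hsv[..., 1] * 255.0, hsv[..., 2] * 255.0


def rgb_from_hsb255(h: float, s: float, b: float) -> tuple:
    """Inverse conversion: an HSB triple on 0-255 to an 8-bit RGB tuple."""
    rgb = color.hsv2rgb(np.array([[[h / 255.0, s / 255.0, b / 255.0]]]))
    return tuple(int(round(c * 255)) for c in rgb[0, 0])


def hsb_threshold(image: np.ndarray, window: HSBWindow) -> np.ndarray:
    """Binary mask of pixels whose HSB triple falls inside the window."""
    image = _check_rgb(image)
    h, s, b = _hsb255(image)
    return np.asarray(window.contains(h, s, b))


def count_cells(image: np.ndarray, window: HSBWindow = CELL_WINDOW,
                min_area: int = MIN_CELL_AREA,
                min_circularity: float = MIN_CIRCULARITY) -> tuple:
    """Count nuclei: threshold, dilate, fill holes, watershed, filter particles.

    Returns (count, labeled mask). Particles are filtered after the watershed
    split: area >= ``min_area`` px² and circularity 4 pi A / P² above
    ``min_circularity``.
    """
    mask = hsb_threshold(image, window)
    if not mask.any():
        return 0, np.zeros(mask.shape, dtype=int)
    mask = morphology.dilation(mask, footprint=np.ones((3, 3), bool))
    mask = ndi.binary_fill_holes(mask)

    distance = ndi.distance_transform_edt(mask)
    # suppress shallow maxima (depth 1 px) before seeding the watershed
    peaks = morphology.h_maxima(distance, 1.0)
    markers, _ = ndi.label(peaks)
    labels = segmentation.watershed(-distance, markers, mask=mask)

    kept = np.zeros_like(labels)
    count = 0
    for prop in measure.regionprops(labels):
        if prop.area < min_area:
            continue
        perim = prop.perimeter
        circ = 4.0 * np.pi * prop.area / perim**2 if perim > 0 else 0.0
        if circ <= min_circularity:
            continue
        count += 1
        kept[labels == prop.label] = count
    return count, kept


def tau_burden(image: np.ndarray, tau_window: HSBWindow = TAU_WINDOW,
               cell_window: HSBWindow = CELL_WINDOW) -> QuantResult:
    """Tau area per cell: DAB-positive pixel count normalized by nucleus count.

    The burden is None (undefined) when no cells are detected.
    """
    tau_area = int(hsb_threshold(image, tau_window).sum())
    cells, _ = count_cells(image, cell_window)
    burden = tau_area / cells if cells > 0 else None
    return QuantResult(cell_count=cells, tau_area_px=tau_area, burden=burden)
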