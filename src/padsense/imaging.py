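"""Detection-zone image handling: loading, ROI location and mean-color extraction.

A µPAD detection zone is photographed twice — before analyte exposure (the
*reference* image) and after (the *response* image).  The scalar signal of the
assay is built from the per-channel mean color of the circular detection zone
in each photograph.  This module reads 8-bit RGB rasters, locates the circular
zone (from an explicit geometry, automatically, or as the inscribed circle of
the full frame) and averages the R, G and B intensities over the zone.

Images are ``(H, W, 3)`` numpy arrays, 0-based, origin top-left, ``(row, col)``
indexing, channel values in ``[0, 255]``.  In-memory arrays may be float-valued
(the synthetic generator produces continuous intensities); files on disk are
8-bit PNG/TIFF/JPEG.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import imageio.v3 as iio
import numpy as np
from skimage import measure

__all__ = [
    "FormatError",
    "DetectionError",
    "ZoneROI",
    "ColorVector",
    "circle_mask",
    "load_image",
    "save_image",
    "locate_zone",
    "mean_color",
]


class FormatError(ValueError):
    """Raised for rasters that are not 3-channel 8/16-bit color images."""


class DetectionError(RuntimeError):
    """Raised when automatic zone detection finds no plausible zone."""


@dataclass(frozen=True)
class ZoneROI:
    """A circular region of interest.

    Pixel membership follows the pixel-center convention: a pixel belongs to
    the ROI iff the Euclidean distance from its center ``(row, col)`` to
    ``center`` is at most ``radius``.  Boundary pixels are wholly in or out;
    there is no area weighting.
    """

    center: tuple[float, float]  # (row, col)
    radius: float
    mode: str = "fixed-circle"

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"ROI radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class ColorVector:
    """Mean R, G, B intensities over an ROI and the pixel count averaged."""

    R: float
    G: float
    B: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("ColorVector needs at least one pixel")

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.G, self.B], dtype=float)


def validate_grid(grid: np.ndarray) -> np.ndarray:
    """Check that ``grid`` is an (H, W, 3) image with values in [0, 255]."""
    grid = np.asarray(grid)
    if grid.ndim != 3 or grid.shape[2] != 3:
        raise FormatError(f"expected an (H, W, 3) RGB image, got shape {grid.shape}")
    if grid.size and (np.nanmin(grid) < 0 or np.nanmax(grid) > 255):
        raise ValueError("channel intensities must lie in [0, 255]")
    return grid


def circle_mask(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    """Boolean mask of pixels whose centers fall within ``radius`` of ``center``."""
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


def load_image(path: str | PathLike) -> np.ndarray:
    """Read a raster as a uint8 (H, W, 3) array.

    16-bit inputs are rescaled to 8-bit; grayscale or alpha-carrying images are
    rejected because the response statistic is defined on exactly three
    channels.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # undecodable content
        raise FormatError(f"could not decode {path!s} as an image: {exc}") from exc
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"{path!s}: expected 3 color channels, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        return np.rint(arr * (255.0 / 65535.0)).astype(np.uint8)
    raise FormatError(f"{path!s}: unsupported dtype {arr.dtype}")


def save_image(path: str | PathLike, grid: np.ndarray) -> None:
    """Write an image as 8-bit PNG, rounding float intensities to integers."""
    grid = validate_grid(grid)
    arr = np.rint(np.clip(grid, 0, 255)).astype(np.uint8)
    iio.imwrite(path, arr)


def locate_zone(
    grid: np.ndarray,
    mode: str = "fixed-circle",
    *,
    center: tuple[float, float] | None = None,
    radius: float | None = None,
    color_cutoff: float = 30.0,
    min_area: int = 64,
) -> ZoneROI:
    """Locate the circular detection zone in ``grid``.

    Modes
    -----
    fixed-circle
        Return the supplied ``center``/``radius`` verbatim (after checking the
        circle sits fully inside the frame).  The deterministic default.
    auto-circle
        Threshold pixels whose color distance from the frame-border median
        color exceeds ``color_cutoff``, keep the largest connected component of
        area >= ``min_area`` and return its centroid and equivalent-area radius.
    full-frame
        The circle inscribed in the frame.
    """
    grid = validate_grid(grid)
    h, w = grid.shape[:2]

    if mode == "fixed-circle":
        if center is None or radius is None:
            raise ValueError("fixed-circle mode requires center and radius")
        roi = ZoneROI(tuple(float(c) for c in center), float(radius), mode)
        _check_inside(roi, h, w)
        return roi

    if mode == "full-frame":
        return ZoneROI(((h - 1) / 2.0, (w - 1) / 2.0), (min(h, w) - 1) / 2.0, mode)

    if mode == "auto-circle":
        border = np.concatenate(
            [grid[0, :, :], grid[-1, :, :], grid[:, 0, :], grid[:, -1, :]]
        ).astype(float)
        background = np.median(border, axis=0)
        dist = np.linalg.norm(grid.astype(float) - background, axis=2)
        labels = measure.label(dist > color_cutoff)
        regions = [r for r in measure.regionprops(labels) if r.area >= min_area]
        if not regions:
            raise DetectionError(
                f"no connected component of area >= {min_area} differs from the "
                f"border color by more than {color_cutoff}"
            )
        zone = max(regions, key=lambda r: r.area)
        return ZoneROI(tuple(zone.centroid), float(np.sqrt(zone.area / np.pi)), mode)

    raise ValueError(f"unknown ROI mode {mode!r}")


def _check_inside(roi: ZoneROI, h: int, w: int) -> None:
    cr, cc = roi.center
    if cr - roi.radius < 0 or cc - roi.radius < 0 or cr + roi.radius > h - 1 or cc + roi.radius > w - 1:
        raise ValueError(
            f"ROI (center={roi.center}, radius={roi.radius}) does not fit inside "
            f"a {h}x{w} frame"
        )


def mean_color(grid: np.ndarray, roi: ZoneROI) -> ColorVector:
    """Arithmetic per-channel mean over the ROI pixels.

    This is the zone-averaging step of the readout: every pixel of the
    detection zone contributes equally, so the result is invariant under any
    permutation of pixels within the ROI.
    """
    grid = validate_grid(grid)
    _check_inside(roi, *grid.shape[:2])
    mask = circle_mask(grid.shape[:2], roi.center, roi.radius)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI covers no pixel centers")
    means = grid[mask].astype(float).mean(axis=0)
    return ColorVector(float(means[0]), float(means[1]), float(means[2]), n)
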