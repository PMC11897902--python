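"""Top-view quantification: segment plant pixels, measure area per tube.

The segmentation strategy follows the classic color-threshold workflow for
green plants on a neutral background: convert RGB to CIELAB, keep the a*
(green-magenta) channel where chlorophyll is strongly negative, binarize
with a fixed threshold (plants are the dark side), drop small connected
components as noise, then count plant pixels inside each tube's circular
region of interest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.color import rgb2lab

from .config import PipelineConfig, parse_image_filename
from .records import SampleRecord

logger = logging.getLogger(__name__)


@dataclass
class TubeImage:
    """One photo of three culture tubes plus its acquisition metadata."""

    pixels: np.ndarray          # H x W x 3 uint8 RGB
    view: str                   # "top" | "side"
    timestamp: datetime
    camera_id: int
    path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("TubeImage requires an H x W x 3 RGB array")
        if self.view not in ("top", "side"):
            raise ValueError(f"view must be 'top' or 'side', got {self.view!r}")
        self.pixels = px.astype(np.uint8, copy=False)


@dataclass(frozen=True)
class RoiSet:
    """Three circular regions of interest, one per tube position."""

    centers: tuple[tuple[int, int], ...]   # (row, col) per tube
    radius: int

    def __post_init__(self) -> None:
        if len(self.centers) != 3:
            raise ValueError("RoiSet requires exactly 3 centers")


def load_image(path: str | Path, view_for_camera: dict[int, str] | None = None) -> TubeImage:
    """Read a tube photo, deriving metadata from the filename.

    ``view_for_camera`` maps camera ids to "top"/"side"; by default odd
    cameras are top-view and even cameras side-view.
    """
    path = Path(path)
    parsed = parse_image_filename(path.name)
    if parsed is None:
        raise ValueError(f"filename {path.name!r} does not match <YYYYMMDD-HHMMSS>_cam<N>.<ext>")
    ts, cam = parsed
    if view_for_camera is None:
        view = "top" if cam % 2 == 1 else "side"
    else:
        view = view_for_camera[cam]
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"))
    return TubeImage(pixels=pixels, view=view, timestamp=ts, camera_id=cam, path=str(path))


def to_greenmagenta(image: TubeImage | np.ndarray) -> np.ndarray:
    """a* (green-magenta) channel of the image, rescaled to uint8.

    Uses the 8-bit LAB convention a* + 128 (D65 illuminant), so neutral
    gray sits near 128, green well below, magenta well above.  Plant
    material therefore appears dark in the returned channel.
    """
    rgb = image.pixels if isinstance(image, TubeImage) else np.asarray(image)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB array")
    a_star = rgb2lab(rgb)[..., 1]
    return np.clip(a_star + 128.0, 0, 255).round().astype(np.uint8)


def threshold_binary(gray: np.ndarray, threshold: int, polarity: str = "dark") -> np.ndarray:
    """Binary mask from a grayscale image; "dark" marks pixels < threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    gray = np.asarray(gray)
    if polarity == "dark":
        return (gray < threshold).astype(np.uint8)
    if polarity == "light":
        return (gray > threshold).astype(np.uint8)
    raise ValueError(f"polarity must be 'dark' or 'light', got {polarity!r}")


def fill_noise(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Remove white connected components smaller than ``min_size`` pixels.

    8-connectivity, matching the object-detection step downstream.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    mask = np.asarray(mask).astype(bool)
    if min_size <= 1:
        return mask.astype(np.uint8)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask.astype(np.uint8)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.concatenate(([False], sizes >= min_size))
    return keep[labels].astype(np.uint8)


def partition_rois(image_shape: tuple[int, int], config: PipelineConfig) -> RoiSet:
    """Three equally spaced circular ROIs along the tube axis."""
    rc = config.rois
    centers = tuple(
        (rc.center_row, rc.first_center_col + i * rc.spacing_cols) for i in range(3)
    )
    h, w = image_shape[:2]
    for row, col in centers:
        if not (rc.radius <= row <= h - 1 - rc.radius and rc.radius <= col <= w - 1 - rc.radius):
            raise ValueError(
                f"ROI circle at ({row},{col}) r={rc.radius} exceeds image bounds {h}x{w}"
            )
    for (r0, c0), (r1, c1) in zip(centers, centers[1:]):
        if (r0 - r1) ** 2 + (c0 - c1) ** 2 < (2 * rc.radius) ** 2:
            raise ValueError("ROI circles overlap")
    return RoiSet(centers=centers, radius=rc.radius)


def measure_areas(mask: np.ndarray, rois: RoiSet) -> list[int]:
    """Total plant area (px) per ROI.

    Each white connected component is assigned to the ROI containing its
    centroid and contributes its full pixel count there; components whose
    centroid falls outside every circle are discarded.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    areas = [0, 0, 0]
    if n == 0:
        return areas
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(mask, labels, index=idx)
    centroids = ndimage.center_of_mass(mask, labels, index=idx)
    r2 = rois.radius**2
    for size, (crow, ccol) in zip(sizes, centroids):
        for i, (row, col) in enumerate(rois.centers):
            if (crow - row) ** 2 + (ccol - col) ** 2 <= r2:
                areas[i] += int(size)
                break
    return areas


def segment(image: TubeImage | np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Green-magenta channel -> binary threshold -> noise fill."""
    gray = to_greenmagenta(image)
    mask = threshold_binary(gray, config.segmentation.threshold, "dark")
    return fill_noise(mask, config.segmentation.min_size)


def quantify_top_image(image: TubeImage, config: PipelineConfig) -> list[SampleRecord]:
    """Full top-view workflow; one partial record per tube position."""
    mask = segment(image, config)
    rois = partition_rois(image.pixels.shape[:2], config)
    areas = measure_areas(mask, rois)
    name = Path(image.path).name if image.path else ""
    return [
        SampleRecord(
            image_name=name,
            camera_id=image.camera_id,
            timestamp=image.timestamp,
            roi_index=i,
            area_px=area,
        )
        for i, area in enumerate(areas)
    ]
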