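"""Side-view quantification: floating-mat depth and barcode identity.

Mat depth uses a row-threshold rule on the segmented mask: a pixel row
counts toward the depth only when its white-pixel count reaches a set
threshold, so depth is only accumulated where the culture is dense enough
to span the tube, suppressing spikes from stray reflections.

Barcode reading retries decoding over a grid of binarization thresholds
and rotations, because label placement and exposure vary from tube to
tube; the first successful decode wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import rotate as _rotate

from . import code128
from .config import PipelineConfig
from .imaging import TubeImage, segment
from .records import SampleRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DepthMeasurement:
    depth_rows: int
    row_threshold: int


@dataclass(frozen=True)
class BarcodeResult:
    payload: str | None
    attempts: int
    winning_threshold: int | None = None
    winning_rotation: float | None = None


def measure_mat_depth(mask: np.ndarray, row_threshold: int) -> DepthMeasurement:
    """Count pixel rows whose white-pixel total reaches ``row_threshold``.

    Rows need not be contiguous; isolated sparse rows are simply excluded.
    """
    if row_threshold < 1:
        raise ValueError("row_threshold must be >= 1")
    mask = np.asarray(mask).astype(bool)
    depth = int(np.count_nonzero(mask.sum(axis=1) >= row_threshold))
    return DepthMeasurement(depth_rows=depth, row_threshold=row_threshold)


def crop_barcode_region(
    image: TubeImage | np.ndarray, crop_box: tuple[int, int, int, int]
) -> np.ndarray:
    """Grayscale sub-image of the barcode label.

    ``crop_box`` is (row0, col0, row1, col1), half-open, image coordinates.
    """
    rgb = image.pixels if isinstance(image, TubeImage) else np.asarray(image)
    r0, c0, r1, c1 = crop_box
    h, w = rgb.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"crop box {crop_box} outside image bounds {h}x{w}")
    region = rgb[r0:r1, c0:c1]
    if region.ndim == 3:
        # ITU-R 601 luma, the standard grayscale reduction
        region = region @ np.array([0.299, 0.587, 0.114])
    return region.astype(np.float64)


def decode_barcode_robust(
    region: np.ndarray,
    thresholds: tuple[int, ...] | list[int],
    rotations: tuple[float, ...] | list[float],
) -> BarcodeResult:
    """Cycle binarization thresholds and rotations until a decode succeeds.

    Rotation is the outer loop (0 deg should come first in the list so the
    cheap unrotated attempts run before resampled ones); within each
    rotation every threshold is tried.  Rotation uses nearest-neighbor
    resampling to keep bar edges crisp at small angles.
    """
    if len(thresholds) == 0 or len(rotations) == 0:
        raise ValueError("thresholds and rotations must be non-empty")
    region = np.asarray(region, dtype=np.float64)
    attempts = 0
    for angle in rotations:
        if angle == 0:
            rotated = region
        else:
            rotated = _rotate(
                region, angle, resize=True, order=0, mode="constant",
                cval=255.0, preserve_range=True,
            )
        for threshold in thresholds:
            attempts += 1
            payload = code128.decode_image(rotated < threshold)
            if payload is not None:
                return BarcodeResult(
                    payload=payload,
                    attempts=attempts,
                    winning_threshold=int(threshold),
                    winning_rotation=float(angle),
                )
    return BarcodeResult(payload=None, attempts=attempts)


def quantify_side_image(image: TubeImage, config: PipelineConfig) -> list[SampleRecord]:
    """Full side-view workflow; one partial record per tube position.

    Per position: segment the green mat within the tube's column slot,
    measure depth with the row-threshold rule, then crop and decode the
    barcode.  An undecodable barcode still yields a record (payload None)
    so the failure is visible downstream.
    """
    layout = config.layout
    mask = segment(image, config)
    name = Path(image.path).name if image.path else ""
    records: list[SampleRecord] = []
    for pos in range(layout.n_positions):
        c0 = pos * layout.slot_width
        c1 = c0 + layout.slot_width
        tube_mask = mask[layout.mat_top_row : layout.mat_bottom_row, c0:c1]
        row_thr = config.depth.row_threshold
        if row_thr is None:
            row_thr = layout.slot_width // 2
        depth = measure_mat_depth(tube_mask, row_thr)
        br0, bc0, br1, bc1 = config.barcode.crop_box
        region = crop_barcode_region(image, (br0, c0 + bc0, br1, c0 + bc1))
        result = decode_barcode_robust(
            region, config.barcode.thresholds, config.barcode.rotations
        )
        if result.payload is None:
            logger.warning(
                "barcode undecoded in %s position %d after %d attempts",
                name or "<array>", pos, result.attempts,
            )
        records.append(
            SampleRecord(
                image_name=name,
                camera_id=image.camera_id,
                timestamp=image.timestamp,
                roi_index=pos,
                barcode=result.payload,
                depth_rows=depth.depth_rows,
            )
        )
    return records
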