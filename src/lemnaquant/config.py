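"""Pipeline configuration: one nested dataclass tree, YAML round-trippable.

Holds the calibration values the imaging rig leaves unspecified (binary
threshold, fill size, ROI geometry, barcode crop boxes) alongside the
analysis constants of the salinity-tolerance protocol (1000 px viability
area over >= 15 consecutive days, 10-day RGR window, 0.8 adjusted-R^2 gate,
500 bootstrap replicates).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import yaml

#: camera ids of top-view cameras and their paired side-view camera
DEFAULT_CAMERA_PAIRS = {1: 2, 3: 4}

_FILENAME_RE = re.compile(
    r"^(?P<ts>\d{8}-\d{6})_cam(?P<cam>\d+)\.(?P<ext>png|jpg|jpeg)$",
    re.IGNORECASE,
)


@dataclass
class SegmentationConfig:
    threshold: int = 120          # a*-channel cut; plant pixels are darker
    min_size: int = 50            # smallest connected component kept, px


@dataclass
class RoiConfig:
    center_row: int = 240
    first_center_col: int = 240
    spacing_cols: int = 480
    radius: int = 170


@dataclass
class DepthConfig:
    # white pixels a row must reach before it counts toward mat depth;
    # None -> half the tube crop width (depth only measured once the mat
    # spans the tube)
    row_threshold: int | None = None


@dataclass
class BarcodeConfig:
    # (row0, col0, row1, col1) crop per tube position, relative to the
    # tube's own 480-px column slot
    crop_box: tuple[int, int, int, int] = (40, 60, 160, 420)
    thresholds: tuple[int, ...] = (60, 80, 100, 120, 140, 160, 180, 200, 220)
    rotations: tuple[float, ...] = (0, 3, -3, 6, -6, 9, -9, 12, -12)


@dataclass
class TubeLayoutConfig:
    n_positions: int = 3
    slot_width: int = 480         # image is n_positions * slot_width wide
    # rows of the side-view region where the floating mat can sit
    mat_top_row: int = 200
    mat_bottom_row: int = 460


@dataclass
class ViabilityConfig:
    min_area_px: int = 1000
    min_days: float = 15.0
    # "consecutive days" read as a consecutive-observation run spanning
    # >= min_days; flip to count observations instead
    count_observations: bool = False
    min_observations: int = 15


@dataclass
class RgrConfig:
    window_days: float = 10.0
    min_fit: float = 0.8


@dataclass
class DoseResponseConfig:
    n_boot: int = 500
    # "observed": baseline = mean measured RGR at dose 0 (default);
    # "fitted": baseline = fitted upper limit d
    baseline_mode: str = "observed"


@dataclass
class PairingConfig:
    camera_pairs: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_CAMERA_PAIRS)
    )
    tolerance_minutes: float = 10.0


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    rois: RoiConfig = field(default_factory=RoiConfig)
    depth: DepthConfig = field(default_factory=DepthConfig)
    barcode: BarcodeConfig = field(default_factory=BarcodeConfig)
    layout: TubeLayoutConfig = field(default_factory=TubeLayoutConfig)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    filter: ViabilityConfig = field(default_factory=ViabilityConfig)
    rgr: RgrConfig = field(default_factory=RgrConfig)
    dose_response: DoseResponseConfig = field(default_factory=DoseResponseConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            sub = data[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in _SECTION_TYPES:
                section_cls = _SECTION_TYPES[f.name]
                sec = {k: _coerce(section_cls, k, v) for k, v in sub.items()}
                kwargs[f.name] = section_cls(**sec)
            else:
                kwargs[f.name] = sub
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_yamlable(self.to_dict()), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


_SECTION_TYPES = {
    "segmentation": SegmentationConfig,
    "rois": RoiConfig,
    "depth": DepthConfig,
    "barcode": BarcodeConfig,
    "layout": TubeLayoutConfig,
    "pairing": PairingConfig,
    "filter": ViabilityConfig,
    "rgr": RgrConfig,
    "dose_response": DoseResponseConfig,
}

_TUPLE_FIELDS = {"crop_box", "thresholds", "rotations"}


def _coerce(section_cls, key, value):
    if key in _TUPLE_FIELDS and isinstance(value, list):
        return tuple(value)
    if key == "camera_pairs" and isinstance(value, dict):
        return {int(k): int(v) for k, v in value.items()}
    return value


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, list):
        return [_yamlable(v) for v in obj]
    return obj


def parse_image_filename(name: str) -> tuple[datetime, int] | None:
    """Extract (timestamp, camera_id) from ``YYYYMMDD-HHMMSS_cam<N>.<ext>``.

    Returns None for names in other dialects so directory scans can skip
    non-image files quietly.
    """
    m = _FILENAME_RE.match(name)
    if m is None:
        return None
    ts = datetime.strptime(m.group("ts"), "%Y%m%d-%H%M%S")
    return ts, int(m.group("cam"))


def format_image_filename(ts: datetime, camera_id: int, ext: str = "png") -> str:
    return f"{ts.strftime('%Y%m%d-%H%M%S')}_cam{camera_id}.{ext}"
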