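"""Record types shared across the pipeline and their JSON/CSV serialization.

The quantification stage appends one JSON record per tube position per
image; the record stream is then converted to the user-facing CSV whose
columns mirror the quantification output schema:
``image_name, camera_id, timestamp, area_px, barcode, depth_rows``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["image_name", "camera_id", "timestamp", "area_px", "barcode", "depth_rows"]


@dataclass
class SampleRecord:
    """One tube at one timepoint, after (or before) top/side joining."""

    image_name: str
    camera_id: int
    timestamp: datetime
    roi_index: int
    area_px: int | None = None
    barcode: str | None = None
    depth_rows: int | None = None

    def to_json_dict(self) -> dict:
        return {
            "image_name": self.image_name,
            "camera_id": self.camera_id,
            "timestamp": self.timestamp.isoformat(),
            "roi_index": self.roi_index,
            "area_px": self.area_px,
            "barcode": self.barcode,
            "depth_rows": self.depth_rows,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SampleRecord":
        return cls(
            image_name=d["image_name"],
            camera_id=int(d["camera_id"]),
            timestamp=datetime.fromisoformat(d["timestamp"]),
            roi_index=int(d["roi_index"]),
            area_px=None if d.get("area_px") is None else int(d["area_px"]),
            barcode=d.get("barcode"),
            depth_rows=None if d.get("depth_rows") is None else int(d["depth_rows"]),
        )


def write_records_json(records: Iterable[SampleRecord], path: str | Path) -> None:
    """JSON-lines record stream, one object per line (append-friendly)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json_dict()) + "\n")


def read_records_json(path: str | Path) -> list[SampleRecord]:
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(SampleRecord.from_json_dict(json.loads(line)))
            except (ValueError, KeyError) as exc:
                logger.warning("skipping malformed JSON record at line %d: %s", i, exc)
    return records


def write_records_csv(records: Iterable[SampleRecord], path: str | Path) -> None:
    """Write joined records as CSV with ISO-8601 timestamps.

    Output is deterministic: column order fixed, rows in input order.
    """
    rows = [
        {
            "image_name": r.image_name,
            "camera_id": r.camera_id,
            "timestamp": r.timestamp.isoformat(),
            "area_px": "" if r.area_px is None else r.area_px,
            "barcode": "" if r.barcode is None else r.barcode,
            "depth_rows": "" if r.depth_rows is None else r.depth_rows,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[SampleRecord]:
    """Read a records CSV; malformed rows are skipped with a logged warning."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV missing columns: {missing}")
    records: list[SampleRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                SampleRecord(
                    image_name=row.image_name,
                    camera_id=int(row.camera_id),
                    timestamp=datetime.fromisoformat(row.timestamp),
                    roi_index=0,
                    area_px=int(float(row.area_px)) if row.area_px != "" else None,
                    barcode=row.barcode or None,
                    depth_rows=int(float(row.depth_rows)) if row.depth_rows != "" else None,
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("skipping malformed CSV row %d: %s", i, exc)
    return records


@dataclass
class GrowthCurve:
    """Time-ordered observations for one barcoded sample."""

    barcode: str
    elapsed_days: list[float] = field(default_factory=list)
    area_px: list[int] = field(default_factory=list)
    depth_rows: list[int | None] = field(default_factory=list)
    clone: str | None = None
    condition_mM: float | None = None
    replicate: int | None = None

    def __len__(self) -> int:
        return len(self.elapsed_days)
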