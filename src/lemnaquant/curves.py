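"""Join top- and side-view records and assemble per-sample growth curves.

A top-view photo shows plant area but no label, so its three tube
positions are linked to barcodes through a fixed camera pairing (each
top-view camera has a dedicated side-view partner photographing the same
rack positions) plus timestamp proximity within one imaging pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .records import GrowthCurve, SampleRecord

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0

CURVES_COLUMNS = [
    "barcode", "elapsed_days", "area_px", "depth_rows",
    "clone", "condition_mM", "replicate",
]


@dataclass(frozen=True)
class BarcodeMapEntry:
    clone: str
    condition_mM: float
    replicate: int


def read_barcode_map(path: str | Path) -> dict[str, BarcodeMapEntry]:
    """Load the barcode -> (clone, dose, replicate) map CSV.

    Expected header: ``barcode,clone,condition_mM,replicate``.
    """
    df = pd.read_csv(path, dtype={"barcode": str, "clone": str})
    required = {"barcode", "clone", "condition_mM", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"barcode map missing columns: {sorted(missing)}")
    if df["barcode"].duplicated().any():
        dupes = df.loc[df["barcode"].duplicated(), "barcode"].tolist()
        raise ValueError(f"duplicate barcodes in map: {dupes}")
    return {
        row.barcode: BarcodeMapEntry(
            clone=row.clone,
            condition_mM=float(row.condition_mM),
            replicate=int(row.replicate),
        )
        for row in df.itertuples(index=False)
    }


def pair_views(
    top_records: list[SampleRecord],
    side_records: list[SampleRecord],
    config: PipelineConfig,
) -> list[SampleRecord]:
    """Merge each top record with its side partner.

    Matching key: (paired camera, tube position, nearest timestamp within
    the tolerance window).  The side record contributes barcode and depth;
    the top record contributes area.  Records that cannot be matched, or
    whose side barcode never decoded, are dropped with a warning.

    Output order is deterministic (timestamp, camera, position) regardless
    of input order.
    """
    pairs = config.pairing.camera_pairs
    tol_s = config.pairing.tolerance_minutes * 60.0
    by_key: dict[tuple[int, int], list[SampleRecord]] = {}
    for rec in side_records:
        by_key.setdefault((rec.camera_id, rec.roi_index), []).append(rec)
    for recs in by_key.values():
        recs.sort(key=lambda r: r.timestamp)

    merged: list[SampleRecord] = []
    for top in sorted(top_records, key=lambda r: (r.timestamp, r.camera_id, r.roi_index)):
        side_cam = pairs.get(top.camera_id)
        if side_cam is None:
            logger.warning("no side camera paired with camera %d; dropping record", top.camera_id)
            continue
        candidates = by_key.get((side_cam, top.roi_index), [])
        best = None
        best_dt = tol_s
        for side in candidates:
            dt = abs((side.timestamp - top.timestamp).total_seconds())
            if dt <= best_dt:
                best, best_dt = side, dt
        if best is None:
            logger.warning(
                "no side record within %.0f s for %s cam%d pos%d; dropped",
                tol_s, top.image_name, top.camera_id, top.roi_index,
            )
            continue
        if best.barcode is None:
            logger.warning(
                "side barcode undecoded for %s cam%d pos%d; merged record dropped",
                top.image_name, top.camera_id, top.roi_index,
            )
            continue
        merged.append(
            SampleRecord(
                image_name=top.image_name,
                camera_id=top.camera_id,
                timestamp=top.timestamp,
                roi_index=top.roi_index,
                area_px=top.area_px,
                barcode=best.barcode,
                depth_rows=best.depth_rows,
            )
        )
    return merged


def assemble_curves(
    records: list[SampleRecord],
    barcode_map: dict[str, BarcodeMapEntry] | None = None,
) -> list[GrowthCurve]:
    """Group joined records by barcode into time-sorted growth curves.

    Elapsed time is measured in fractional days from each curve's first
    observation.  Two records of one barcode closer than one minute apart
    are treated as a duplicate pass: the later one wins and the collision
    is logged.
    """
    by_barcode: dict[str, list[SampleRecord]] = {}
    for rec in records:
        if rec.barcode is None:
            continue
        by_barcode.setdefault(rec.barcode, []).append(rec)

    curves: list[GrowthCurve] = []
    for barcode in sorted(by_barcode):
        recs = sorted(by_barcode[barcode], key=lambda r: r.timestamp)
        deduped: list[SampleRecord] = []
        for rec in recs:
            if deduped and (rec.timestamp - deduped[-1].timestamp).total_seconds() < 60.0:
                logger.warning(
                    "duplicate pass for barcode %s at %s; keeping later record",
                    barcode, rec.timestamp.isoformat(),
                )
                deduped[-1] = rec
            else:
                deduped.append(rec)
        t0 = deduped[0].timestamp
        curve = GrowthCurve(
            barcode=barcode,
            elapsed_days=[(r.timestamp - t0).total_seconds() / SECONDS_PER_DAY for r in deduped],
            area_px=[r.area_px if r.area_px is not None else 0 for r in deduped],
            depth_rows=[r.depth_rows for r in deduped],
        )
        if barcode_map is not None:
            entry = barcode_map.get(barcode)
            if entry is None:
                logger.warning("barcode %s absent from barcode map; metadata empty", barcode)
            else:
                curve.clone = entry.clone
                curve.condition_mM = entry.condition_mM
                curve.replicate = entry.replicate
        curves.append(curve)
    return curves


def curves_to_frame(curves: list[GrowthCurve]) -> pd.DataFrame:
    """Long-format table, one row per observation."""
    rows = []
    for c in curves:
        for t, a, d in zip(c.elapsed_days, c.area_px, c.depth_rows):
            rows.append(
                {
                    "barcode": c.barcode,
                    "elapsed_days": t,
                    "area_px": a,
                    "depth_rows": d,
                    "clone": c.clone,
                    "condition_mM": c.condition_mM,
                    "replicate": c.replicate,
                }
            )
    return pd.DataFrame(rows, columns=CURVES_COLUMNS)


def write_curves_csv(curves: list[GrowthCurve], path: str | Path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def read_curves_csv(path: str | Path) -> list[GrowthCurve]:
    df = pd.read_csv(path, dtype={"barcode": str, "clone": str})
    curves = []
    for barcode, group in df.groupby("barcode", sort=True):
        group = group.sort_values("elapsed_days")
        first = group.iloc[0]
        curves.append(
            GrowthCurve(
                barcode=str(barcode),
                elapsed_days=group["elapsed_days"].tolist(),
                area_px=[int(a) for a in group["area_px"]],
                depth_rows=[None if pd.isna(d) else int(d) for d in group["depth_rows"]],
                clone=None if pd.isna(first["clone"]) else str(first["clone"]),
                condition_mM=None if pd.isna(first["condition_mM"]) else float(first["condition_mM"]),
                replicate=None if pd.isna(first["replicate"]) else int(first["replicate"]),
            )
        )
    return curves
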