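"""Ground-truthed synthetic fixtures for every pipeline level.

Three generators, composable from curves up to pixels:

* :func:`simulate_trial_curves` — per-sample area time series under the
  salinity-trial design (6 clones x 6 added-sodium doses x 6 replicates,
  imaged 5 days a week for 4 weeks = 20 imaging days), with exponential
  growth after a transplant lag, a carrying-capacity cap and lognormal
  multiplicative measurement noise; doses of 200 mM and above are lethal
  and decay.
* :func:`render_top_image` / :func:`render_side_image` — draw tube-rack
  photographs whose ground truth (exact plant pixel area, mat depth rows,
  barcode payload/rotation/contrast) is recorded in a scene manifest.
  Areas are counted from the painted mask, not from geometry formulas, so
  the manifest is exact by construction.
* :func:`simulate_trial_images` — compose the two: a directory of
  timestamped photos plus the barcode map and truth tables.

All generators are pure functions of (parameters, seed).

True per-(clone, dose) growth rates follow a log-logistic decline in
dose, with clone parameters chosen so the most tolerant clone grows at
0.19 day^-1 at 100 mM added sodium — 70% of its optimal (0 mM) rate —
and the spread of tolerances across clones mirrors a realistic trial.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import rotate as _rotate

from . import code128
from .config import PipelineConfig, format_image_filename
from .records import GrowthCurve

#: Mon-Fri imaging over four weeks: 20 imaging days spanning 25 calendar days
DEFAULT_SCHEDULE = tuple(w * 7 + d for w in range(4) for d in range(5))

DEFAULT_DOSES_MM = (0.0, 50.0, 100.0, 200.0, 300.0, 400.0)

#: optimal growth rate d (day^-1) and tolerance scale e (mM) per clone;
#: true RGR at dose x is d / (1 + (x/e)^b) with shared slope b.
DEFAULT_CLONES: dict[str, tuple[float, float]] = {
    "France": (0.30, 105.0),
    "Germany": (0.24, 120.0),
    "Greece": (0.26, 115.0),
    "Israel": (0.22, 125.0),
    "Kashmir": (0.19 / 0.7, 100.0 * (3.0 / 7.0) ** (-1 / 2.5)),
    "Saudi": (0.25, 130.0),
}


@dataclass
class TrialDesign:
    """Study design plus the generative growth model per sample."""

    clones: tuple[str, ...] = tuple(DEFAULT_CLONES)
    doses_mM: tuple[float, ...] = DEFAULT_DOSES_MM
    replicates: int = 6
    schedule_days: tuple[int, ...] = DEFAULT_SCHEDULE
    clone_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLONES)
    )
    dose_slope_b: float = 2.5
    lethal_dose_mM: float = 200.0     # doses >= this kill the culture
    initial_area_px: float = 600.0
    carrying_capacity_px: float = 30000.0
    lag_days: float = 1.0
    decay_rate: float = 0.4           # day^-1 shrinkage of lethal samples
    noise_sigma: float = 0.05         # lognormal sd of measured area
    quantize_px: bool = True          # round measured areas to whole pixels
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return len(self.clones) * len(self.doses_mM) * self.replicates

    def true_rgr(self, clone: str, dose_mM: float) -> float:
        d, e = self.clone_params[clone]
        if dose_mM >= self.lethal_dose_mM:
            return -self.decay_rate
        if dose_mM == 0:
            return d
        return d / (1.0 + (dose_mM / e) ** self.dose_slope_b)

    def true_ec50(self, clone: str) -> float:
        """Dose at which the true rate is half the optimal rate."""
        _, e = self.clone_params[clone]
        return e


def barcode_for(clone: str, dose_mM: float, replicate: int) -> str:
    return f"{clone[:2].upper()}-{int(round(dose_mM)):03d}-{replicate}"


def _sample_table(design: TrialDesign) -> pd.DataFrame:
    rows = []
    for clone in design.clones:
        for dose in design.doses_mM:
            for rep in range(1, design.replicates + 1):
                rows.append(
                    {
                        "barcode": barcode_for(clone, dose, rep),
                        "clone": clone,
                        "condition_mM": dose,
                        "replicate": rep,
                        "true_rgr": design.true_rgr(clone, dose),
                        "lethal": dose >= design.lethal_dose_mM,
                    }
                )
    return pd.DataFrame(rows)


def _true_area(design: TrialDesign, rate: float, lethal: bool, t: np.ndarray) -> np.ndarray:
    if lethal:
        return design.initial_area_px * np.exp(-design.decay_rate * t)
    grown = design.initial_area_px * np.exp(rate * np.maximum(0.0, t - design.lag_days))
    return np.minimum(grown, design.carrying_capacity_px)


def simulate_trial_curves(design: TrialDesign | None = None) -> tuple[list[GrowthCurve], pd.DataFrame]:
    """Simulate every sample's growth curve; returns (curves, truth table).

    The truth table has one row per sample with its true rate and design
    labels, and is what recovery tests compare pipeline estimates against.
    """
    design = design or TrialDesign()
    rng = np.random.default_rng(design.seed)
    truth = _sample_table(design)
    t = np.asarray(design.schedule_days, dtype=float)
    curves = []
    for row in truth.itertuples(index=False):
        area = _true_area(design, row.true_rgr, row.lethal, t)
        noise = np.exp(rng.normal(0.0, design.noise_sigma, size=t.size))
        observed = area * noise
        if design.quantize_px:
            observed = np.maximum(1, np.rint(observed).astype(int))
        curves.append(
            GrowthCurve(
                barcode=row.barcode,
                elapsed_days=t.tolist(),
                area_px=observed.tolist(),
                depth_rows=[_depth_rule(a) for a in observed],
                clone=row.clone,
                condition_mM=row.condition_mM,
                replicate=row.replicate,
            )
        )
    return curves, truth


def _depth_rule(area_px: float) -> int:
    """Mat depth (rows) the renderer pairs with a given plant area.

    The mat only registers once the culture is dense enough to span the
    tube; below that the side view shows no full-width band.
    """
    if area_px < 2000:
        return 0
    return int(min(120, 5 + round(area_px / 500.0)))


# --------------------------------------------------------------------------
# image rendering

PLANT_RGB = (60, 140, 60)
BACKGROUND_RGB = (170, 170, 170)
TUBE_RGB = (110, 110, 110)


@dataclass
class TubeScene:
    """Ground truth for one tube position in one image pair."""

    barcode: str
    target_area_px: float
    rendered_area_px: int = 0
    depth_rows: int = 0
    barcode_rotation_deg: float = 0.0
    barcode_contrast: tuple[int, int] = (20, 235)
    colonies: list[tuple[int, int, int, int]] = field(default_factory=list)  # (row, col, r_row, r_col)


@dataclass
class SceneManifest:
    image_shape: tuple[int, int] = (480, 1440)
    tube_radius: int = 150
    tubes: list[TubeScene] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)


def _paint_ellipse(mask: np.ndarray, row: int, col: int, r_row: int, r_col: int) -> None:
    h, w = mask.shape
    rr0, rr1 = max(0, row - r_row), min(h, row + r_row + 1)
    cc0, cc1 = max(0, col - r_col), min(w, col + r_col + 1)
    yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
    inside = ((yy - row) / max(r_row, 1e-9)) ** 2 + ((xx - col) / max(r_col, 1e-9)) ** 2 <= 1.0
    mask[rr0:rr1, cc0:cc1] |= inside


def _colony_layout(target_area: float, rng: np.random.Generator) -> list[tuple[float, float, float]]:
    """Split a target area into 1-4 elliptical colonies: (frac, drow, dcol).

    Every fragment stays comfortably above the segmentation noise-fill
    size so ground-truth areas survive quantification.
    """
    if target_area < 2000:
        return [(1.0, 0.0, 0.0)]
    fracs = np.array([1.0])
    for _ in range(10):
        k = int(rng.integers(1, 5))
        candidate = rng.dirichlet(np.ones(k) * 4.0)
        if candidate.min() * target_area >= 150:
            fracs = candidate
            break
    offsets = rng.uniform(-60, 60, size=(len(fracs), 2))
    return [(float(f), float(o[0]), float(o[1])) for f, o in zip(fracs, offsets)]


def render_top_image(
    manifest: SceneManifest, seed: int, config: PipelineConfig | None = None
) -> np.ndarray:
    """Draw a top-view photo; updates each tube's ``rendered_area_px``.

    Colonies are hard-edged green ellipses inside each tube's circular
    opening; glare speckles (small white dots, below the noise-fill size)
    are sprinkled outside the colonies.  The exact plant pixel count is
    written back to the manifest.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    h, w = manifest.image_shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = BACKGROUND_RGB
    rc = config.rois
    centers = [(rc.center_row, rc.first_center_col + i * rc.spacing_cols) for i in range(3)]
    for (crow, ccol), tube in zip(centers, manifest.tubes):
        # tube opening
        yy, xx = np.mgrid[0:h, 0:w]
        opening = (yy - crow) ** 2 + (xx - ccol) ** 2 <= manifest.tube_radius**2
        img[opening] = TUBE_RGB

        plant = np.zeros((h, w), dtype=bool)
        tube.colonies = []
        if tube.target_area_px > 0:
            inner = manifest.tube_radius - 20
            for frac, drow, dcol in _colony_layout(tube.target_area_px, rng):
                part = tube.target_area_px * frac
                stretch = float(rng.uniform(0.7, 1.4))
                r_col = np.sqrt(part / np.pi * stretch)
                r_row = part / np.pi / max(r_col, 1e-9)
                # keep the colony inside the tube opening
                max_r = max(r_row, r_col)
                lim = max(0.0, inner - max_r)
                off = np.hypot(drow, dcol)
                if off > lim > 0:
                    drow, dcol = drow * lim / off, dcol * lim / off
                elif lim == 0.0:
                    drow = dcol = 0.0
                e_row, e_col = int(round(crow + drow)), int(round(ccol + dcol))
                _paint_ellipse(plant, e_row, e_col, int(round(r_row)), int(round(r_col)))
                tube.colonies.append((e_row, e_col, int(round(r_row)), int(round(r_col))))
        jitter = rng.integers(-12, 13, size=3)
        color = np.clip(np.array(PLANT_RGB) + jitter, 0, 255).astype(np.uint8)
        img[plant] = color

        # glare speckles: bright dots away from the plant, each well below
        # the noise-fill size so segmentation must remove them
        for _ in range(int(rng.integers(2, 6))):
            srow = int(rng.integers(crow - 100, crow + 100))
            scol = int(rng.integers(ccol - 100, ccol + 100))
            sr = int(rng.integers(1, 4))
            speck = np.zeros((h, w), dtype=bool)
            _paint_ellipse(speck, srow, scol, sr, sr)
            if not (speck & plant).any():
                img[speck] = (245, 245, 245)

        tube.rendered_area_px = int(plant.sum())
    return img


def _render_barcode_patch(
    payload: str, height: int, module_px: int, contrast: tuple[int, int]
) -> np.ndarray:
    lo, hi = contrast
    mods = code128.encode_modules(payload, quiet_zone=10)
    line = np.where(np.repeat(mods, module_px) == 1, lo, hi).astype(np.uint8)
    return np.tile(line, (height, 1))


def render_side_image(
    manifest: SceneManifest, seed: int, config: PipelineConfig | None = None
) -> np.ndarray:
    """Draw a side-view photo: mat band plus barcode label per tube."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    layout = config.layout
    h, w = manifest.image_shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = BACKGROUND_RGB
    for pos, tube in enumerate(manifest.tubes):
        c0 = pos * layout.slot_width
        # green mat band, full tube width, 'depth_rows' rows deep
        if tube.depth_rows > 0:
            top = layout.mat_bottom_row - tube.depth_rows
            jitter = rng.integers(-12, 13, size=3)
            color = np.clip(np.array(PLANT_RGB) + jitter, 0, 255).astype(np.uint8)
            img[top : layout.mat_bottom_row, c0 + 20 : c0 + layout.slot_width - 20] = color
        # barcode label
        br0, bc0, br1, bc1 = config.barcode.crop_box
        box_h, box_w = br1 - br0, bc1 - bc0
        patch = _render_barcode_patch(tube.barcode, height=50, module_px=2,
                                      contrast=tube.barcode_contrast)
        if tube.barcode_rotation_deg != 0:
            patch = _rotate(
                patch.astype(float), tube.barcode_rotation_deg, resize=True,
                order=0, mode="constant", cval=float(tube.barcode_contrast[1]),
                preserve_range=True,
            ).astype(np.uint8)
        ph, pw = patch.shape
        if ph > box_h or pw > box_w:
            raise ValueError(
                f"rendered barcode {ph}x{pw} exceeds crop box {box_h}x{box_w}"
            )
        r_off = br0 + (box_h - ph) // 2
        c_off = c0 + bc0 + (box_w - pw) // 2
        img[r_off : r_off + ph, c_off : c_off + pw] = patch[..., None]
    return img


def simulate_trial_images(
    design: TrialDesign,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    start: datetime | None = None,
) -> pd.DataFrame:
    """Render the whole trial to ``out_dir``; returns the truth table.

    Writes ``<YYYYMMDD-HHMMSS>_cam<N>.png`` photos (camera 1 = top,
    camera 2 = side), ``Barcode_Sample_Map.csv``, ``truth_curves.csv``
    (per-observation simulated areas/depths) and ``truth_samples.csv``
    (per-sample true rates), plus one manifest JSON per image pair.
    """
    config = config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    start = start or datetime(2024, 3, 4, 9, 0, 0)

    curves, truth = simulate_trial_curves(design)
    by_barcode = {c.barcode: c for c in curves}
    order = [c.barcode for c in curves]

    truth.to_csv(out_dir / "truth_samples.csv", index=False)
    pd.DataFrame(
        {
            "barcode": truth["barcode"],
            "clone": truth["clone"],
            "condition_mM": truth["condition_mM"],
            "replicate": truth["replicate"],
        }
    ).to_csv(out_dir / "Barcode_Sample_Map.csv", index=False)

    obs_rows = []
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 7]))
    for day_idx, day in enumerate(design.schedule_days):
        for g0 in range(0, len(order), 3):
            group = order[g0 : g0 + 3]
            ts = start + timedelta(days=int(day), minutes=2 * (g0 // 3))
            manifest = SceneManifest()
            for barcode in group:
                curve = by_barcode[barcode]
                area = float(curve.area_px[day_idx])
                manifest.tubes.append(
                    TubeScene(
                        barcode=barcode,
                        target_area_px=area if area >= 20 else 0.0,
                        depth_rows=curve.depth_rows[day_idx] or 0,
                        barcode_rotation_deg=float(rng.choice((-9, -6, -3, 0, 3, 6, 9))),
                        barcode_contrast=(int(rng.integers(10, 60)), int(rng.integers(180, 240))),
                    )
                )
            while len(manifest.tubes) < 3:  # pad the last rack group
                manifest.tubes.append(TubeScene(barcode="PAD-000-0", target_area_px=0.0))
            pair_seed = int(rng.integers(0, 2**31 - 1))
            top = render_top_image(manifest, seed=pair_seed, config=config)
            side = render_side_image(manifest, seed=pair_seed + 1, config=config)
            top_name = format_image_filename(ts, 1)
            side_name = format_image_filename(ts + timedelta(seconds=30), 2)
            Image.fromarray(top).save(out_dir / top_name)
            Image.fromarray(side).save(out_dir / side_name)
            (out_dir / f"{top_name}.manifest.json").write_text(
                json.dumps(manifest.to_json_dict(), indent=1)
            )
            for pos, tube in enumerate(manifest.tubes):
                if tube.barcode.startswith("PAD-"):
                    continue
                obs_rows.append(
                    {
                        "barcode": tube.barcode,
                        "day": day,
                        "image": top_name,
                        "position": pos,
                        "true_area_px": tube.rendered_area_px,
                        "true_depth_rows": tube.depth_rows,
                    }
                )
    pd.DataFrame(obs_rows).to_csv(out_dir / "truth_curves.csv", index=False)
    return truth
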