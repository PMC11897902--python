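"""Viability filtering and relative growth rate estimation.

A sample's relative growth rate (RGR, day^-1) is the slope of ln(area)
against time.  Because transplanted colonies often lag before entering
exponential growth and plateau once the mat covers the tube, the rate is
estimated inside a sliding window: every window of ``window_days`` days
starting at an observation gets its own log-linear ordinary least squares
fit, and the maximum slope whose adjusted R^2 clears the fitness gate is
taken as the sample's RGR.  Samples that never sustain a minimum area for
long enough are excluded as dead or non-growing before any fitting.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RgrConfig, ViabilityConfig
from .records import GrowthCurve

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ViabilityVerdict:
    barcode: str
    viable: bool
    longest_run_days: float


@dataclass(frozen=True)
class RGRResult:
    barcode: str
    rgr_per_day: float
    window_start_day: float
    adj_r2: float | None
    n_points: int
    selected: bool


def viability_filter(
    curve: GrowthCurve,
    min_area_px: int = 1000,
    min_days: float = 15.0,
    count_observations: bool = False,
    min_observations: int = 15,
) -> ViabilityVerdict:
    """Decide whether a sample grew at all.

    Finds the longest run of consecutive observations whose area is at
    least ``min_area_px``; the sample is viable when that run's calendar
    span reaches ``min_days`` (or, with ``count_observations``, when the
    run holds ``min_observations`` points).  Imaging happens five days a
    week, so the span rule is the natural reading of "N consecutive days".
    """
    if len(curve) == 0:
        raise ValueError("viability_filter requires a non-empty curve")
    t = np.asarray(curve.elapsed_days, dtype=float)
    ok = np.asarray(curve.area_px, dtype=float) >= min_area_px
    best_span = 0.0
    best_len = 0
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        if (not flag or i == len(ok) - 1) and start is not None:
            end = i if flag else i - 1
            best_span = max(best_span, t[end] - t[start])
            best_len = max(best_len, end - start + 1)
            start = None
    if count_observations:
        viable = best_len >= min_observations
    else:
        viable = best_span >= min_days
    return ViabilityVerdict(barcode=curve.barcode, viable=viable, longest_run_days=float(best_span))


def _ols_loglinear(t: np.ndarray, ln_area: np.ndarray) -> tuple[float, float]:
    """Slope and adjusted R^2 of ln(area) ~ t by closed-form OLS."""
    n = t.size
    tm, ym = t.mean(), ln_area.mean()
    sxx = float(((t - tm) ** 2).sum())
    if sxx == 0.0:
        return 0.0, -math.inf
    sxy = float(((t - tm) * (ln_area - ym)).sum())
    slope = sxy / sxx
    syy = float(((ln_area - ym) ** 2).sum())
    # guard against rounding residue when ln(area) is constant to machine
    # precision: treat variance below the float noise floor as zero scatter
    if syy <= n * (1e-12 * max(1.0, abs(ym))) ** 2:
        r2 = 1.0
    else:
        r2 = 1.0 - (syy - slope * sxy) / syy
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, adj


def window_rgr(curve: GrowthCurve, window_days: float = 10.0) -> list[RGRResult]:
    """Log-linear OLS slope inside every sliding window.

    A window anchors at each observation i and spans the closed interval
    [t_i, t_i + window_days]; it is fitted when it holds at least three
    points, all with positive area (ln is undefined at zero, so a window
    containing a zero-area point is skipped).
    """
    t = np.asarray(curve.elapsed_days, dtype=float)
    area = np.asarray(curve.area_px, dtype=float)
    results: list[RGRResult] = []
    for i in range(len(t)):
        sel = (t >= t[i]) & (t <= t[i] + window_days)
        if sel.sum() < 3:
            continue
        if (area[sel] <= 0).any():
            continue
        slope, adj = _ols_loglinear(t[sel], np.log(area[sel]))
        results.append(
            RGRResult(
                barcode=curve.barcode,
                rgr_per_day=slope,
                window_start_day=float(t[i]),
                adj_r2=adj,
                n_points=int(sel.sum()),
                selected=False,
            )
        )
    return results


def select_rgr(results: list[RGRResult], min_fit: float = 0.8) -> RGRResult | None:
    """Maximum RGR among windows whose adjusted R^2 clears ``min_fit``.

    Ties break toward the earliest window.  Returns None when no window
    qualifies; input order never matters.
    """
    qualifying = [r for r in results if r.adj_r2 is not None and r.adj_r2 >= min_fit]
    if not qualifying:
        return None
    best = min(qualifying, key=lambda r: (-r.rgr_per_day, r.window_start_day))
    return RGRResult(
        barcode=best.barcode,
        rgr_per_day=best.rgr_per_day,
        window_start_day=best.window_start_day,
        adj_r2=best.adj_r2,
        n_points=best.n_points,
        selected=True,
    )


def sample_rgr_table(
    curves: list[GrowthCurve],
    viability: ViabilityConfig | None = None,
    rgr_config: RgrConfig | None = None,
) -> pd.DataFrame:
    """Per-sample RGR table for all viable samples.

    Columns: barcode, clone, condition_mM, replicate, rgr_per_day,
    adj_r2, selected, viable.  Non-viable samples keep a row (selected
    False, rgr NaN) so downstream lethality accounting can see them.
    """
    viability = viability or ViabilityConfig()
    rgr_config = rgr_config or RgrConfig()
    rows = []
    for curve in curves:
        verdict = viability_filter(
            curve,
            min_area_px=viability.min_area_px,
            min_days=viability.min_days,
            count_observations=viability.count_observations,
            min_observations=viability.min_observations,
        )
        row = {
            "barcode": curve.barcode,
            "clone": curve.clone,
            "condition_mM": curve.condition_mM,
            "replicate": curve.replicate,
            "rgr_per_day": np.nan,
            "adj_r2": np.nan,
            "selected": False,
            "viable": verdict.viable,
        }
        if verdict.viable:
            chosen = select_rgr(
                window_rgr(curve, rgr_config.window_days), rgr_config.min_fit
            )
            if chosen is None:
                logger.warning(
                    "sample %s viable but no window met the %.2f fitness gate; excluded",
                    curve.barcode, rgr_config.min_fit,
                )
            else:
                row["rgr_per_day"] = chosen.rgr_per_day
                row["adj_r2"] = chosen.adj_r2
                row["selected"] = True
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "barcode", "clone", "condition_mM", "replicate",
            "rgr_per_day", "adj_r2", "selected", "viable",
        ],
    )


def substitute_lethal(rgr_table: pd.DataFrame, per_clone: bool = False) -> pd.DataFrame:
    """Zero-substitute the lowest fully lethal dose; drop doses above it.

    A dose is lethal when no sample of any clone is viable at it (trial-
    wide rule, matching how a uniformly lethal concentration is treated:
    its replicates enter the dose-response data as RGR 0, and strictly
    higher doses are removed).  With ``per_clone`` the rule is applied
    within each clone separately.
    """
    df = rgr_table.copy()
    if df.empty:
        return df

    def _apply(group: pd.DataFrame) -> pd.DataFrame:
        doses = sorted(group["condition_mM"].dropna().unique())
        lethal = [d for d in doses if not group.loc[group["condition_mM"] == d, "viable"].any()]
        if not lethal:
            out = group.copy()
        else:
            lowest = min(lethal)
            out = group[group["condition_mM"] <= lowest].copy()
            at = out["condition_mM"] == lowest
            out.loc[at, "rgr_per_day"] = 0.0
            out.loc[at, "adj_r2"] = np.nan
            out.loc[at, "selected"] = True
        # samples that died or failed the fitness gate at surviving doses
        # carry no usable rate and are excluded from fitting
        return out[out["selected"]].copy()

    if per_clone:
        parts = [_apply(g) for _, g in df.groupby("clone", sort=True)]
        return pd.concat(parts, ignore_index=True)
    return _apply(df).reset_index(drop=True)
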