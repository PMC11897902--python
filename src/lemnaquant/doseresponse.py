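"""Five-parameter log-logistic dose-response fitting and EC50 estimation.

The response (per-sample RGR, day^-1) is modeled against added-sodium
dose x (mM) with the five-parameter log-logistic family

    f(x) = c + (d - c) / (1 + exp(b * (ln x - ln e)))^f

where c and d are the lower and upper asymptotes, b the slope, e the
inflection dose and f the asymmetry.  EC50 is the dose at which the
fitted response equals half the 0 mM (optimal) growth rate, found by
bracketed root finding on the fitted curve; its uncertainty comes from a
within-dose case-resampling bootstrap that refits the model on each
resample.

Fitting uses bounded nonlinear least squares (trust region reflective)
with data-driven initialization and a small multi-start fallback on the
slope, which is the parameter the loss surface is most sensitive to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoseResponseFit:
    clone: str
    b: float
    c: float
    d: float
    e: float
    f: float
    sse: float
    converged: bool

    @property
    def params(self) -> tuple[float, float, float, float, float]:
        return (self.b, self.c, self.d, self.e, self.f)


@dataclass(frozen=True)
class EC50Estimate:
    clone: str
    ec50_mM: float | None
    baseline_rgr: float
    sd_mM: float | None = None
    n_boot_effective: int | None = None
    extrapolated: bool = False
    sd_reliable: bool = True


def ll5(x, b: float, c: float, d: float, e: float, f: float):
    """Five-parameter log-logistic response at dose(s) ``x``.

    Dose 0 is handled by the analytic limit: d for b > 0, c for b < 0
    (the midpoint for b = 0).
    """
    if e <= 0 or f <= 0:
        raise ValueError("ll5 requires e > 0 and f > 0")
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if (x < 0).any():
        raise ValueError("doses must be >= 0")
    out = np.empty_like(x)
    pos = x > 0
    with np.errstate(over="ignore"):
        z = np.exp(np.clip(b * (np.log(x[pos]) - np.log(e)), -700, 700))
        out[pos] = c + (d - c) / (1.0 + z) ** f
    if b > 0:
        limit0 = d
    elif b < 0:
        limit0 = c
    else:
        limit0 = c + (d - c) / 2.0**f
    out[~pos] = limit0
    return float(out[0]) if scalar else out


def fit_ll5(doses, responses, clone: str = "") -> DoseResponseFit:
    """Least-squares LL5 fit to pooled replicate data.

    Initialization: c0 = min response, d0 = max response, e0 = geometric
    mean of positive doses, b0 = 1, f0 = 1; on poor convergence the fit
    restarts over b0 in {0.5, 1, 2}.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size != responses.size:
        raise ValueError("doses and responses must have equal length")
    if doses.size < 5 or np.unique(doses).size < 3:
        raise ValueError("need >= 5 points over >= 3 distinct doses")

    pos = doses[doses > 0]
    e0 = float(np.exp(np.log(pos).mean())) if pos.size else 1.0
    c0 = float(responses.min())
    d0 = float(responses.max())
    span = max(d0 - c0, 1e-6)
    max_dose = float(doses.max())

    def residuals(theta):
        b, c, d, log_e, log_f = theta
        return ll5(doses, b, c, d, np.exp(log_e), np.exp(log_f)) - responses

    lo = [-50.0, c0 - 2 * span, c0 - 2 * span, np.log(1e-3), np.log(1e-3)]
    hi = [50.0, d0 + 2 * span, d0 + 2 * span, np.log(max(10 * max_dose, 1.0)), np.log(1e3)]

    best = None
    for b0 in (1.0, 0.5, 2.0):
        theta0 = np.array([b0, c0, d0, np.log(e0), 0.0])
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception as exc:  # pathological data
            logger.debug("LL5 start b0=%.1f failed: %s", b0, exc)
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost <= 1e-20:
            break

    if best is None:
        return DoseResponseFit(clone, np.nan, np.nan, np.nan, np.nan, np.nan,
                               np.inf, converged=False)
    b, c, d, log_e, log_f = best.x
    sse = float(2.0 * best.cost)
    converged = bool(best.success)
    return DoseResponseFit(
        clone=clone, b=float(b), c=float(c), d=float(d),
        e=float(np.exp(log_e)), f=float(np.exp(log_f)),
        sse=sse, converged=converged,
    )


def ec50(
    fit: DoseResponseFit,
    baseline_rgr: float,
    max_dose: float,
    rtol: float = 1e-6,
) -> EC50Estimate:
    """Dose at which the fitted response crosses half the baseline rate.

    Solved by bisection-bracketed root finding on (0, 2 * max_dose]; the
    estimate is flagged extrapolated when it exceeds the tested range.
    """
    if not fit.converged:
        return EC50Estimate(clone=fit.clone, ec50_mM=None, baseline_rgr=baseline_rgr)
    if baseline_rgr <= 0:
        raise ValueError("baseline_rgr must be positive")
    target = 0.5 * baseline_rgr

    def g(x):
        return ll5(x, *fit.params) - target

    upper = 2.0 * max_dose
    lower = 1e-9 * max(max_dose, 1.0)
    if g(lower) * g(upper) > 0:
        return EC50Estimate(clone=fit.clone, ec50_mM=None, baseline_rgr=baseline_rgr)
    root = optimize.brentq(g, lower, upper, xtol=1e-12, rtol=rtol)
    return EC50Estimate(
        clone=fit.clone,
        ec50_mM=float(root),
        baseline_rgr=float(baseline_rgr),
        extrapolated=bool(root > max_dose),
    )


def _baseline(table: pd.DataFrame, fit: DoseResponseFit, mode: str) -> float:
    if mode == "fitted":
        return max(fit.c, fit.d) if fit.b <= 0 else fit.d
    at_zero = table.loc[table["condition_mM"] == 0.0, "rgr_per_day"]
    if at_zero.empty:
        raise ValueError("no dose-0 responses to define the baseline")
    return float(at_zero.mean())


def bootstrap_ec50(
    clone_table: pd.DataFrame,
    n_boot: int = 500,
    seed: int | np.random.Generator = 0,
    baseline_mode: str = "observed",
) -> EC50Estimate:
    """Point estimate plus bootstrap SD of EC50 for one clone.

    ``clone_table`` holds one row per replicate with columns
    ``condition_mM`` and ``rgr_per_day`` (lethal-dose zeros included).
    Each iteration resamples replicates with replacement within every
    dose (keeping the original count per dose), refits the model,
    recomputes the baseline from the resample and re-solves for EC50.
    Iterations whose fit fails or whose crossing leaves the bracket are
    dropped; the SD is flagged unreliable when more than half fail.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    clone = str(clone_table["clone"].iloc[0]) if "clone" in clone_table and len(clone_table) else ""
    doses = clone_table["condition_mM"].to_numpy(dtype=float)
    responses = clone_table["rgr_per_day"].to_numpy(dtype=float)
    max_dose = float(doses.max())

    fit = fit_ll5(doses, responses, clone=clone)
    baseline = _baseline(clone_table, fit, baseline_mode)
    point = ec50(fit, baseline, max_dose)

    # sort within each dose so the resampling draws are invariant to the
    # order replicates arrive in
    groups = [
        np.flatnonzero(doses == d)[np.argsort(responses[doses == d], kind="stable")]
        for d in np.unique(doses)
    ]
    boot_values = []
    for _ in range(n_boot):
        idx = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in groups])
        bd, br = doses[idx], responses[idx]
        try:
            bfit = fit_ll5(bd, br, clone=clone)
            if not bfit.converged:
                continue
            if baseline_mode == "fitted":
                bbase = _baseline(None, bfit, "fitted")
            else:
                at_zero = br[bd == 0.0]
                if at_zero.size == 0 or at_zero.mean() <= 0:
                    continue
                bbase = float(at_zero.mean())
            best = ec50(bfit, bbase, max_dose)
        except (ValueError, RuntimeError):
            continue
        if best.ec50_mM is not None:
            boot_values.append(best.ec50_mM)

    n_eff = len(boot_values)
    sd = float(np.std(boot_values, ddof=1)) if n_eff >= 2 else None
    return EC50Estimate(
        clone=clone,
        ec50_mM=point.ec50_mM,
        baseline_rgr=baseline,
        sd_mM=sd,
        n_boot_effective=n_eff,
        extrapolated=point.extrapolated,
        sd_reliable=n_eff >= n_boot / 2,
    )


def clone_panel(
    rgr_table: pd.DataFrame,
    n_boot: int = 500,
    seed: int = 0,
    baseline_mode: str = "observed",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-clone dose-response summary over a whole trial.

    Returns (summary, fits, ec50s):
      * summary — mean and sd RGR per (clone, dose), plot-ready;
      * fits — one LL5 parameter row per clone;
      * ec50s — EC50 point estimate, baseline and bootstrap SD per clone.

    Clones with fewer than three surviving doses are skipped with a
    warning.  Per-clone bootstrap seeds derive deterministically from
    ``seed``.
    """
    if rgr_table.empty:
        empty = pd.DataFrame()
        return empty, empty, empty
    summary = (
        rgr_table.groupby(["clone", "condition_mM"])["rgr_per_day"]
        .agg(mean_rgr="mean", sd_rgr="std", n="count")
        .reset_index()
    )
    fits_rows, ec50_rows = [], []
    clones = sorted(rgr_table["clone"].dropna().unique())
    seeds = np.random.SeedSequence(seed).spawn(len(clones))
    for clone, sub_seed in zip(clones, seeds):
        sub = rgr_table[rgr_table["clone"] == clone]
        if sub["condition_mM"].nunique() < 3:
            logger.warning("clone %s has < 3 surviving doses; skipped", clone)
            continue
        est = bootstrap_ec50(
            sub, n_boot=n_boot, seed=np.random.default_rng(sub_seed),
            baseline_mode=baseline_mode,
        )
        fit = fit_ll5(
            sub["condition_mM"].to_numpy(float),
            sub["rgr_per_day"].to_numpy(float),
            clone=clone,
        )
        fits_rows.append(
            {"clone": clone, "b": fit.b, "c": fit.c, "d": fit.d, "e": fit.e,
             "f": fit.f, "sse": fit.sse, "converged": fit.converged}
        )
        ec50_rows.append(
            {"clone": clone, "ec50_mM": est.ec50_mM, "sd_mM": est.sd_mM,
             "baseline_rgr": est.baseline_rgr, "n_boot_effective": est.n_boot_effective,
             "extrapolated": est.extrapolated}
        )
    fits_df = pd.DataFrame(
        fits_rows, columns=["clone", "b", "c", "d", "e", "f", "sse", "converged"]
    )
    ec50_df = pd.DataFrame(
        ec50_rows,
        columns=["clone", "ec50_mM", "sd_mM", "baseline_rgr",
                 "n_boot_effective", "extrapolated"],
    )
    return summary, fits_df, ec50_df


def plot_panel(summary: pd.DataFrame, fits: pd.DataFrame, ec50s: pd.DataFrame, out_dir):
    """Dose-response line plots per clone and an EC50 bar chart."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(7, 5))
    for clone, sub in summary.groupby("clone"):
        ax.errorbar(sub["condition_mM"], sub["mean_rgr"], yerr=sub["sd_rgr"],
                    marker="o", capsize=3, label=clone)
        row = fits[fits["clone"] == clone]
        if len(row) and bool(row["converged"].iloc[0]):
            b, c, d, e, f = row.iloc[0][["b", "c", "d", "e", "f"]]
            xs = np.linspace(0, sub["condition_mM"].max(), 200)
            ax.plot(xs, ll5(xs, b, c, d, e, f), lw=1, alpha=0.6)
    ax.set_xlabel("added sodium (mM)")
    ax.set_ylabel("RGR (day$^{-1}$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "dose_response.png", dpi=150)
    plt.close(fig)

    if not ec50s.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(ec50s["clone"], ec50s["ec50_mM"],
               yerr=ec50s["sd_mM"].fillna(0.0), capsize=4)
        ax.set_ylabel("EC50 (mM added sodium)")
        fig.tight_layout()
        fig.savefig(out_dir / "ec50_bar.png", dpi=150)
        plt.close(fig)
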