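"""Five-parameter log-logistic fitting, EC50 root finding and bootstrap."""

import numpy as np
import pandas as pd
import pytest

from lemnaquant.doseresponse import (
    DoseResponseFit,
    bootstrap_ec50,
    clone_panel,
    ec50,
    fit_ll5,
    ll5,
)

DOSES = np.repeat([0.0, 50.0, 100.0, 150.0, 200.0], 6)


def _clone_table(doses, responses, clone="X"):
    return pd.DataFrame({
        "clone": clone,
        "condition_mM": doses,
        "rgr_per_day": responses,
    })


class TestLl5:
    def test_half_response_at_inflection_when_symmetric(self):
        assert ll5(80.0, b=3.0, c=0.0, d=0.24, e=80.0, f=1.0) == pytest.approx(0.12)

    def test_zero_dose_limit_is_upper_asymptote(self):
        assert ll5(0.0, b=3.0, c=0.0, d=0.25, e=90.0, f=1.5) == pytest.approx(0.25)

    def test_zero_dose_limit_negative_slope(self):
        assert ll5(0.0, b=-3.0, c=0.02, d=0.25, e=90.0, f=1.5) == pytest.approx(0.02)

    def test_closed_form_asymmetric_point(self):
        # at x = e the logistic term is 1, so response = d / 2^f
        assert ll5(80.0, b=3.0, c=0.0, d=0.2, e=80.0, f=2.0) == pytest.approx(0.05)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ll5(10.0, b=1.0, c=0.0, d=0.2, e=-5.0, f=1.0)
        with pytest.raises(ValueError):
            ll5(10.0, b=1.0, c=0.0, d=0.2, e=5.0, f=0.0)

    def test_monotone_when_bf_positive(self):
        xs = np.linspace(0.01, 400, 500)
        ys = ll5(xs, b=2.0, c=0.0, d=0.3, e=100.0, f=1.3)
        assert (np.diff(ys) <= 1e-12).all()


class TestFitLl5:
    TRUE = dict(b=2.5, c=0.0, d=0.25, e=90.0, f=1.5)

    def test_exact_data_recovers_parameters(self):
        responses = ll5(DOSES, **self.TRUE)
        fit = fit_ll5(DOSES, responses)
        assert fit.converged
        assert fit.d == pytest.approx(self.TRUE["d"], rel=1e-4)
        assert fit.e == pytest.approx(self.TRUE["e"], rel=1e-4)
        assert fit.b == pytest.approx(self.TRUE["b"], rel=1e-3)
        assert fit.f == pytest.approx(self.TRUE["f"], rel=1e-3)
        assert fit.sse < 1e-12

    def test_noisy_data_sse_at_noise_floor(self):
        sigma = 0.01
        rng = np.random.default_rng(42)
        responses = ll5(DOSES, **self.TRUE) + rng.normal(0, sigma, DOSES.size)
        fit = fit_ll5(DOSES, responses)
        assert fit.converged
        # five fitted parameters absorb part of the scatter
        assert 0.4 * DOSES.size * sigma**2 < fit.sse < 1.6 * DOSES.size * sigma**2

    def test_flat_data_degenerates_to_flat_curve(self):
        responses = np.full(DOSES.size, 0.2)
        fit = fit_ll5(DOSES, responses)
        assert fit.converged
        preds = ll5(np.unique(DOSES), *fit.params)
        assert np.allclose(preds, 0.2, atol=1e-6)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            fit_ll5([0, 50, 100], [0.2, 0.1, 0.05])
        with pytest.raises(ValueError):
            fit_ll5([0, 0, 0, 50, 50, 50], [0.2] * 6)


def _grid_oracle(fit, target, max_dose, resolution=1e-4):
    """Brute-force minimizer of |ll5(x) - target| on a fine dose grid."""
    xs = np.arange(resolution, 2 * max_dose + resolution, resolution)
    return xs[np.argmin(np.abs(ll5(xs, *fit.params) - target))]


class TestEc50:
    def test_symmetric_case_equals_inflection(self):
        fit = DoseResponseFit("X", b=2.0, c=0.0, d=0.3, e=120.0, f=1.0,
                              sse=0.0, converged=True)
        est = ec50(fit, baseline_rgr=0.3, max_dose=200.0)
        assert est.ec50_mM == pytest.approx(120.0, rel=1e-6)
        assert not est.extrapolated

    def test_asymmetric_case_matches_grid_oracle(self):
        fit = DoseResponseFit("X", b=3.0, c=0.0, d=0.2, e=80.0, f=2.0,
                              sse=0.0, converged=True)
        est = ec50(fit, baseline_rgr=0.2, max_dose=200.0)
        oracle = _grid_oracle(fit, 0.1, 200.0)
        assert est.ec50_mM == pytest.approx(oracle, abs=1e-3)

    def test_bisection_matches_analytic_inversion_f1(self):
        b, c, d, e = 2.2, 0.0, 0.28, 95.0
        fit = DoseResponseFit("X", b=b, c=c, d=d, e=e, f=1.0,
                              sse=0.0, converged=True)
        target = 0.5 * (c + d)  # midway between the asymptotes
        analytic = e * ((d - c) / (target - c) - 1) ** (1 / b)
        est = ec50(fit, baseline_rgr=2 * target, max_dose=200.0)
        assert est.ec50_mM == pytest.approx(analytic, rel=1e-6)

    def test_no_crossing_flagged(self):
        fit = DoseResponseFit("X", b=2.0, c=0.2, d=0.3, e=100.0, f=1.0,
                              sse=0.0, converged=True)
        # half-baseline target 0.4 exceeds the upper asymptote d = 0.3
        est = ec50(fit, baseline_rgr=0.8, max_dose=200.0)
        assert est.ec50_mM is None

    def test_unconverged_fit_gives_no_estimate(self):
        fit = DoseResponseFit("X", b=2.0, c=0.0, d=0.3, e=100.0, f=1.0,
                              sse=1.0, converged=False)
        assert ec50(fit, baseline_rgr=0.3, max_dose=200.0).ec50_mM is None

    def test_grid_oracle_equivalence_on_fitted_curves(self, rng):
        for _ in range(5):
            true = dict(b=float(rng.uniform(1.5, 4)), c=0.0,
                        d=float(rng.uniform(0.15, 0.35)),
                        e=float(rng.uniform(60, 140)), f=float(rng.uniform(0.7, 2.5)))
            responses = ll5(DOSES, **true) + rng.normal(0, 0.005, DOSES.size)
            fit = fit_ll5(DOSES, responses)
            if not fit.converged:
                continue
            baseline = responses[DOSES == 0].mean()
            est = ec50(fit, baseline, max_dose=200.0)
            if est.ec50_mM is None:
                continue
            oracle = _grid_oracle(fit, 0.5 * baseline, 200.0)
            assert est.ec50_mM == pytest.approx(oracle, abs=1e-3)


class TestBootstrap:
    TRUE = dict(b=2.5, c=0.0, d=0.25, e=90.0, f=1.2)

    def test_zero_noise_bootstrap_sd_near_zero(self):
        responses = ll5(DOSES, **self.TRUE)
        est = bootstrap_ec50(_clone_table(DOSES, responses), n_boot=30, seed=5)
        assert est.n_boot_effective == 30
        assert est.sd_mM == pytest.approx(0.0, abs=1e-6)

    def test_fixed_seed_reproducible_to_last_bit(self):
        rng = np.random.default_rng(7)
        responses = ll5(DOSES, **self.TRUE) + rng.normal(0, 0.02, DOSES.size)
        a = bootstrap_ec50(_clone_table(DOSES, responses), n_boot=40, seed=123)
        b = bootstrap_ec50(_clone_table(DOSES, responses), n_boot=40, seed=123)
        assert a.sd_mM == b.sd_mM
        assert a.ec50_mM == b.ec50_mM

    def test_replicate_order_invariance(self):
        rng = np.random.default_rng(8)
        responses = ll5(DOSES, **self.TRUE) + rng.normal(0, 0.02, DOSES.size)
        table = _clone_table(DOSES, responses)
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = bootstrap_ec50(table, n_boot=40, seed=11)
        b = bootstrap_ec50(shuffled, n_boot=40, seed=11)
        assert a.sd_mM == pytest.approx(b.sd_mM, rel=1e-9)

    def test_bootstrap_sd_calibrated_against_monte_carlo(self):
        """Bootstrap SD within a factor of two of the sampling SD of EC50."""
        sigma = 0.02
        mc_ec50s = []
        for i in range(60):
            rng = np.random.default_rng(1000 + i)
            responses = ll5(DOSES, **self.TRUE) + rng.normal(0, sigma, DOSES.size)
            fit = fit_ll5(DOSES, responses)
            if not fit.converged:
                continue
            baseline = responses[DOSES == 0].mean()
            est = ec50(fit, baseline, max_dose=200.0)
            if est.ec50_mM is not None:
                mc_ec50s.append(est.ec50_mM)
        empirical_sd = np.std(mc_ec50s, ddof=1)
        rng = np.random.default_rng(77)
        responses = ll5(DOSES, **self.TRUE) + rng.normal(0, sigma, DOSES.size)
        est = bootstrap_ec50(_clone_table(DOSES, responses), n_boot=100, seed=7)
        assert est.sd_mM is not None
        assert empirical_sd / 2 < est.sd_mM < empirical_sd * 2


class TestParameterRecovery:
    def test_median_ec50_error_under_10pct(self):
        """Trial-scale design: 4 surviving doses, 6 reps, sigma = 0.02."""
        doses = np.repeat([0.0, 50.0, 100.0, 200.0], 6)
        true = dict(b=2.5, c=0.0, d=0.27, e=110.0, f=1.0)
        true_ec50 = true["e"]  # symmetric: half of d at x = e
        errors = []
        for i in range(20):
            rng = np.random.default_rng(300 + i)
            responses = np.clip(ll5(doses, **true) + rng.normal(0, 0.02, doses.size), 0, None)
            fit = fit_ll5(doses, responses)
            baseline = responses[doses == 0].mean()
            est = ec50(fit, baseline, max_dose=200.0)
            if est.ec50_mM is not None:
                errors.append(abs(est.ec50_mM - true_ec50) / true_ec50)
        assert len(errors) >= 15
        assert np.median(errors) < 0.10


class TestClonePanel:
    def _trial_table(self, e_by_clone, sigma=0.005, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for clone, e in e_by_clone.items():
            doses = np.repeat([0.0, 50.0, 100.0, 200.0], 6)
            resp = ll5(doses, b=2.5, c=0.0, d=0.25, e=e, f=1.0)
            resp = resp + rng.normal(0, sigma, doses.size)
            for dose, r in zip(doses, resp):
                rows.append({"clone": clone, "condition_mM": dose,
                             "rgr_per_day": max(r, 0.0), "replicate": 1})
        return pd.DataFrame(rows)

    def test_one_fit_and_ec50_per_clone(self):
        table = self._trial_table({"A": 90.0, "B": 110.0, "C": 130.0})
        summary, fits, ec50s = clone_panel(table, n_boot=10, seed=1)
        assert len(fits) == 3 and len(ec50s) == 3
        assert set(ec50s["clone"]) == {"A", "B", "C"}

    def test_rank_of_true_tolerance_preserved_at_low_noise(self):
        table = self._trial_table({"lo": 80.0, "mid": 110.0, "hi": 140.0}, sigma=0.003)
        _, _, ec50s = clone_panel(table, n_boot=5, seed=2)
        by_clone = ec50s.set_index("clone")["ec50_mM"]
        assert by_clone["lo"] < by_clone["mid"] < by_clone["hi"]

    def test_empty_table_no_crash(self):
        summary, fits, ec50s = clone_panel(pd.DataFrame(), n_boot=5, seed=0)
        assert summary.empty and fits.empty and ec50s.empty

    def test_clone_with_too_few_doses_skipped(self, caplog):
        import logging
        table = self._trial_table({"A": 90.0})
        table = table[table["condition_mM"].isin([0.0, 50.0])]
        with caplog.at_level(logging.WARNING):
            _, fits, ec50s = clone_panel(table, n_boot=5, seed=0)
        assert fits.empty and ec50s.empty
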