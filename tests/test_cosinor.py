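import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhythmpower import cosinor, preprocess, simulate
from rhythmpower.cosinor import (
    IndividualCosinorFit,
    fit_individual_cosinor,
    population_cosinor_test,
    screen_rhythmic,
)
from rhythmpower.errors import DegenerateCovarianceError, FitError


def _fit_from_coefs(beta, gamma, period=24.0, protein="X", pid="P"):
    amp = math.hypot(beta, gamma)
    acro = (period / (2 * math.pi)) * math.atan2(gamma, beta) % period
    return IndividualCosinorFit(
        participant_id=pid, protein_id=protein, period=period,
        mesor=0.0, beta_coef=beta, gamma_coef=gamma,
        amplitude=amp, acrophase=acro, n_points=16, residual_ss=1.0,
    )


class TestIndividualFit:
    def test_noiseless_unit_cosine(self, times_2h_30h):
        y = np.cos(2 * np.pi * times_2h_30h / 24)
        fit = fit_individual_cosinor(times_2h_30h, y, 24.0)
        assert fit.mesor == pytest.approx(0.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-9)
        assert fit.acrophase == pytest.approx(0.0, abs=1e-9)

    def test_analytic_construction(self, times_2h_30h):
        y = 3 + 0.3 * np.cos(2 * np.pi * (times_2h_30h - 5) / 24)
        fit = fit_individual_cosinor(times_2h_30h, y, 24.0)
        assert fit.mesor == pytest.approx(3.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(0.3, abs=1e-9)
        assert fit.acrophase == pytest.approx(5.0, abs=1e-9)

    def test_matches_independent_least_squares(self, times_2h_30h):
        import statsmodels.api as sm

        rng = np.random.default_rng(123)
        y = 1.5 + 0.4 * np.cos(2 * np.pi * (times_2h_30h - 7) / 24) + rng.normal(
            0, 0.5, times_2h_30h.size
        )
        fit = fit_individual_cosinor(times_2h_30h, y, 24.0)
        w = 2 * np.pi / 24
        design = np.column_stack(
            [np.ones_like(times_2h_30h), np.cos(w * times_2h_30h), np.sin(w * times_2h_30h)]
        )
        oracle = sm.OLS(y, design).fit()
        np.testing.assert_allclose(
            [fit.mesor, fit.beta_coef, fit.gamma_coef], oracle.params, atol=1e-9
        )
        assert fit.residual_ss == pytest.approx(oracle.ssr, abs=1e-9)

    def test_reconstruction_identity(self, times_2h_30h):
        rng = np.random.default_rng(5)
        y = rng.normal(size=times_2h_30h.size)
        fit = fit_individual_cosinor(times_2h_30h, y, 24.0)
        w = 2 * np.pi / 24
        via_polar = fit.mesor + fit.amplitude * np.cos(
            w * (times_2h_30h - fit.acrophase)
        )
        np.testing.assert_allclose(fit.predict(times_2h_30h), via_polar, atol=1e-9)

    def test_nan_values_dropped(self, times_2h_30h):
        y = np.cos(2 * np.pi * times_2h_30h / 24)
        y[3] = np.nan
        fit = fit_individual_cosinor(times_2h_30h, y, 24.0)
        assert fit.n_points == 15
        assert fit.amplitude == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(FitError, match=">= 4"):
            fit_individual_cosinor([0, 2, 4], [1, 2, 3], 24.0)

    def test_rank_deficient_design(self):
        # all times congruent modulo the period
        times = [0.0, 24.0, 48.0, 72.0]
        with pytest.raises(FitError, match="rank-deficient"):
            fit_individual_cosinor(times, [1.0, 2.0, 3.0, 4.0], 24.0)

    @settings(derandomize=True, max_examples=50)
    @given(shift=st.floats(-48, 48, allow_nan=False))
    def test_acrophase_shift_equivariance(self, shift):
        times = np.arange(0.0, 31.0, 2.0)
        rng = np.random.default_rng(7)
        y = 0.5 * np.cos(2 * np.pi * (times - 3) / 24) + rng.normal(0, 0.3, times.size)
        base = fit_individual_cosinor(times, y, 24.0)
        shifted = fit_individual_cosinor(times + shift, y, 24.0)
        assert shifted.acrophase == pytest.approx(
            (base.acrophase + shift) % 24, abs=1e-6
        )
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(0.01, 100, allow_nan=False))
    def test_scale_equivariance(self, scale):
        times = np.arange(0.0, 31.0, 2.0)
        rng = np.random.default_rng(11)
        y = 2 + 0.4 * np.cos(2 * np.pi * (times - 9) / 24) + rng.normal(0, 0.3, times.size)
        base = fit_individual_cosinor(times, y, 24.0)
        scaled = fit_individual_cosinor(times, scale * y, 24.0)
        assert scaled.mesor == pytest.approx(scale * base.mesor, rel=1e-9)
        assert scaled.amplitude == pytest.approx(scale * base.amplitude, rel=1e-9)
        assert scaled.acrophase == pytest.approx(base.acrophase, abs=1e-6)

    def test_cross_period_leakage_matches_design_matrix_bound(self, times_2h_30h):
        # 12 h fit of a pure 24 h cosine: leakage computed independently
        # from the normal equations of the same design.
        y = np.cos(2 * np.pi * times_2h_30h / 24)
        fit12 = fit_individual_cosinor(times_2h_30h, y, 12.0)
        w = 2 * np.pi / 12
        X = np.column_stack(
            [np.ones_like(times_2h_30h), np.cos(w * times_2h_30h), np.sin(w * times_2h_30h)]
        )
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        leak = float(np.hypot(oracle[1], oracle[2]))
        assert fit12.amplitude == pytest.approx(leak, abs=1e-9)
        assert leak < 0.25  # small relative to the true 24 h amplitude of 1


class TestPopulationTest:
    def test_needs_three_subjects(self):
        fits = [_fit_from_coefs(0.3, 0.0, pid=f"P{i}") for i in range(2)]
        with pytest.raises(FitError, match="k >= 3"):
            population_cosinor_test(fits)

    def test_mixed_periods_rejected(self):
        fits = [
            _fit_from_coefs(0.3, 0.0, period=24.0),
            _fit_from_coefs(0.3, 0.0, period=12.0),
            _fit_from_coefs(0.3, 0.0, period=24.0),
        ]
        with pytest.raises(FitError, match="mix"):
            population_cosinor_test(fits)

    def test_identical_subjects_degenerate(self):
        fits = [_fit_from_coefs(0.3, 0.1, pid=f"P{i}") for i in range(5)]
        with pytest.raises(DegenerateCovarianceError):
            population_cosinor_test(fits)

    def test_tight_coefficients_give_near_zero_p(self):
        rng = np.random.default_rng(2)
        fits = [
            _fit_from_coefs(0.3 + rng.normal(0, 1e-4), rng.normal(0, 1e-4), pid=f"P{i}")
            for i in range(10)
        ]
        res = population_cosinor_test(fits)
        assert res.p_value < 1e-10
        assert res.pop_amplitude == pytest.approx(0.3, abs=1e-3)
        assert min(res.pop_acrophase, 24 - res.pop_acrophase) < 0.05

    def test_antiphase_subjects_cancel(self):
        rng = np.random.default_rng(3)
        fits = [
            _fit_from_coefs(s * 0.3, rng.normal(0, 1e-6), pid=f"P{i}")
            for i, s in enumerate([1, -1] * 5)
        ]
        res = population_cosinor_test(fits)
        assert res.pop_amplitude == pytest.approx(0.0, abs=1e-5)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_population_amplitude_below_mean_individual_amplitude(self, seed):
        rng = np.random.default_rng(seed)
        fits = [
            _fit_from_coefs(rng.normal(0.2, 0.3), rng.normal(0, 0.3), pid=f"P{i}")
            for i in range(8)
        ]
        res = population_cosinor_test(fits)
        mean_indiv = np.mean([f.amplitude for f in fits])
        assert res.pop_amplitude <= mean_indiv + 1e-12

    def test_screen_gates_are_strict(self):
        rng = np.random.default_rng(4)
        fits = [
            _fit_from_coefs(0.3 + rng.normal(0, 0.02), rng.normal(0, 0.02), pid=f"P{i}")
            for i in range(10)
        ]
        res = population_cosinor_test(fits)
        assert res.passes_screen
        # thresholds set exactly at the achieved values: strict < and > fail
        at_amp = population_cosinor_test(fits, amp_threshold=res.pop_amplitude)
        assert not at_amp.passes_screen
        at_p = population_cosinor_test(fits, p_threshold=res.p_value)
        assert not at_p.passes_screen


class TestScreen:
    def test_planted_rhythms_recovered_and_dual_period_rows(self):
        specs = (
            simulate.RhythmSpec("C24", (simulate.RhythmComponent(24.0, 0.7, 5.0),)),
            simulate.RhythmSpec("U12", (simulate.RhythmComponent(12.0, 0.7, 3.0),)),
            simulate.RhythmSpec(
                "DUAL",
                (
                    simulate.RhythmComponent(24.0, 0.65, 2.0),
                    simulate.RhythmComponent(12.0, 0.65, 8.0),
                ),
            ),
        ) + tuple(simulate.RhythmSpec(f"N{i}") for i in range(10))
        cfg = simulate.CohortConfig(rhythm_specs=specs, seed=21)
        ds = simulate.generate_cohort(cfg)
        filt, _ = preprocess.filter_missing_proteins(preprocess.average_replicates(ds))
        outcome = screen_rhythmic(preprocess.zscore_per_participant(filt))
        assert not outcome.failures
        # one row per protein x period
        assert len(outcome.results) == 2 * len(specs)
        passing = {(r.protein_id, r.period) for r in outcome.passing()}
        assert ("C24", 24.0) in passing
        assert ("U12", 12.0) in passing
        assert {("DUAL", 24.0), ("DUAL", 12.0)} <= passing

    def test_failures_reported_not_raised(self):
        # one protein with a single sampled timepoint cannot be fit
        import pandas as pd

        from rhythmpower.preprocess import ScaledSeriesSet

        good_t = np.arange(0.0, 31.0, 2.0)
        rng = np.random.default_rng(6)
        rows = []
        for pid in ("P1", "P2", "P3"):
            for t in good_t:
                rows.append((pid, "OK", t, rng.normal()))
            for t in (0.0, 24.0, 48.0, 72.0):  # degenerate modulo 24
                rows.append((pid, "BAD", t, rng.normal()))
        series = pd.DataFrame(
            rows, columns=["participant_id", "protein_id", "dlmo_time", "z_value"]
        )
        outcome = screen_rhythmic(ScaledSeriesSet(series=series, provenance=pd.DataFrame()))
        assert {f["protein_id"] for f in outcome.failures} == {"BAD"}
        assert {r.protein_id for r in outcome.results} == {"OK"}

    def test_results_frame_and_polar_export_columns(self):
        rng = np.random.default_rng(8)
        fits = [
            _fit_from_coefs(
                0.3 + rng.normal(0, 0.05), rng.normal(0, 0.05), pid=f"P{i}", protein="X"
            )
            for i in range(5)
        ]
        res = population_cosinor_test(fits)
        frame = cosinor.results_to_frame([res], add_bh_column=True)
        assert {"protein_id", "period", "acrophase_dlmo_h", "p_value", "amplitude_z", "p_bh"} <= set(
            frame.columns
        )
        polar = cosinor.polar_export([res])
        assert polar["angle_rad"].iloc[0] == pytest.approx(
            2 * np.pi * res.pop_acrophase / 24
        )
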