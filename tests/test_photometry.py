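"""Spectral unmixing, fading correction and the ratio-increase metric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnctest import photometry, synthetic
from dnctest.photometry import (
    CoefficientTrace,
    fit_fading_baseline,
    percent_ratio_increase,
    unmix_frame,
    unmix_series,
)

from conftest import normal_equations_oracle


def _trace(t, c_signal, c_ref, names=("dLight1.1", "tdTomato")):
    coeffs = np.column_stack([c_signal, c_ref])
    return CoefficientTrace(
        timestamps=np.asarray(t, dtype=float),
        coefficients=coeffs,
        names=names,
        residual_norm=np.zeros(len(t)),
    )


class TestUnmixFrame:
    def test_basis_column_recovered_exactly(self, basis):
        for k, name in enumerate(basis.names):
            coeffs, resid = unmix_frame(basis.spectra[:, k], basis)
            expected = np.zeros(2)
            expected[k] = 1.0
            np.testing.assert_allclose(coeffs, expected, atol=1e-10)
            assert resid == pytest.approx(0.0, abs=1e-10)

    def test_known_mixture_matches_normal_equations_oracle(self, basis):
        measured = 0.3 * basis.spectra[:, 0] + 0.7 * basis.spectra[:, 1]
        coeffs, _ = unmix_frame(measured, basis)
        np.testing.assert_allclose(coeffs, [0.3, 0.7], atol=1e-10)
        oracle = normal_equations_oracle(basis.spectra, measured)
        np.testing.assert_allclose(coeffs, oracle, atol=1e-10)

    def test_zero_spectrum_gives_zero_coefficients(self, basis):
        coeffs, resid = unmix_frame(np.zeros(basis.wavelengths.size), basis)
        np.testing.assert_allclose(coeffs, 0.0, atol=1e-12)
        assert resid == pytest.approx(0.0)

    def test_grid_mismatch_rejected(self, basis):
        with pytest.raises(ValueError, match="grid"):
            unmix_frame(np.zeros(10), basis)

    def test_ill_conditioned_basis_rejected_by_name(self, grid):
        twin = synthetic.make_basis(
            [
                synthetic.FluorophoreSpec("a", 510.0, 20.0),
                synthetic.FluorophoreSpec("b", 510.0, 20.0),
            ],
            grid,
            reference="b",
        )
        with pytest.raises(ValueError, match="ill-conditioned"):
            unmix_frame(np.ones(grid.size), twin)

    def test_nonnegative_mode_agrees_on_interior_solutions(self, basis):
        measured = 0.4 * basis.spectra[:, 0] + 0.6 * basis.spectra[:, 1]
        free, _ = unmix_frame(measured, basis)
        constrained, _ = unmix_frame(measured, basis, nonnegative=True)
        np.testing.assert_allclose(free, constrained, atol=1e-8)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        alpha=st.floats(min_value=1e-3, max_value=1e3),
        c1=st.floats(min_value=0.0, max_value=5.0),
        c2=st.floats(min_value=0.0, max_value=5.0),
    )
    def test_scale_equivariance(self, basis, alpha, c1, c2):
        measured = c1 * basis.spectra[:, 0] + c2 * basis.spectra[:, 1]
        base, _ = unmix_frame(measured, basis)
        scaled, _ = unmix_frame(alpha * measured, basis)
        np.testing.assert_allclose(scaled, alpha * base, rtol=1e-8, atol=1e-10)

    def test_random_bases_match_oracle(self, grid):
        """Unmixing equals the closed-form normal-equations solution to 1e-8
        relative error on randomly perturbed well-conditioned bases."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            peaks = rng.uniform(480, 650, 2)
            while abs(peaks[0] - peaks[1]) < 30:
                peaks = rng.uniform(480, 650, 2)
            b = synthetic.make_basis(
                [
                    synthetic.FluorophoreSpec("s", peaks[0], rng.uniform(10, 30)),
                    synthetic.FluorophoreSpec("r", peaks[1], rng.uniform(10, 30)),
                ],
                grid,
                reference="r",
            )
            measured = rng.uniform(0, 2, 2) @ b.spectra.T + rng.normal(0, 0.01, grid.size)
            coeffs, _ = unmix_frame(measured, b)
            oracle = normal_equations_oracle(b.spectra, measured)
            np.testing.assert_allclose(coeffs, oracle, rtol=1e-8, atol=1e-10)


class TestUnmixSeries:
    def test_noiseless_session_recovers_ground_truth(self, basis):
        params = synthetic.SessionParams(
            frame_rate=5, duration=60, bleach_slope=0.02, transient_onset=30,
            transient_amplitude=0.4, noise_sd=0, seed=0,
        )
        series, truth = synthetic.simulate_session(basis, params)
        trace = unmix_series(series, basis)
        np.testing.assert_allclose(trace.coefficients, truth.coefficients, atol=1e-8)
        np.testing.assert_allclose(trace.residual_norm, 0.0, atol=1e-8)

    def test_constant_frames_give_constant_trace(self, basis):
        frames = np.tile(basis.spectra.sum(axis=1), (10, 1))
        series = photometry.EmissionFrameSeries(
            wavelengths=basis.wavelengths,
            frames=frames,
            timestamps=np.arange(10.0),
            frame_rate=1.0,
        )
        trace = unmix_series(series, basis)
        np.testing.assert_allclose(trace.coefficients, 1.0, atol=1e-10)

    def test_matches_frame_by_frame_oracle_under_noise(self, basis):
        params = synthetic.SessionParams(
            frame_rate=5, duration=30, noise_sd=0.05, transient_onset=15, seed=2,
        )
        series, _ = synthetic.simulate_session(basis, params)
        trace = unmix_series(series, basis)
        for i in (0, 50, 149):
            oracle = normal_equations_oracle(basis.spectra, series.frames[i])
            np.testing.assert_allclose(trace.coefficients[i], oracle, atol=1e-8)


class TestFadingBaseline:
    def test_constant_trace_gives_zero_dff(self):
        t = np.arange(0, 700.0, 1.0)
        dff = fit_fading_baseline(_trace(t, np.full(t.size, 2.0), np.ones(t.size)), "dLight1.1")
        np.testing.assert_allclose(dff.dff_percent, 0.0, atol=1e-10)
        np.testing.assert_allclose(dff.baseline_f0, 2.0, atol=1e-10)

    def test_pure_linear_decay_fits_itself(self):
        t = np.arange(0, 900.0, 0.5)
        f = 1.0 - 1e-4 * t
        dff = fit_fading_baseline(_trace(t, f, np.ones(t.size)), "dLight1.1")
        np.testing.assert_allclose(dff.dff_percent, 0.0, atol=1e-10)

    def test_transient_after_window_recovered(self, basis):
        params = synthetic.SessionParams(
            frame_rate=5, duration=1000, bleach_slope=0.01, transient_onset=900,
            transient_amplitude=0.3, transient_decay=60, noise_sd=0, seed=0,
        )
        series, _ = synthetic.simulate_session(basis, params)
        trace = unmix_series(series, basis)
        dff = fit_fading_baseline(trace, "dLight1.1", 600.0)
        peak = dff.dff_percent[dff.timestamps >= 900].max()
        assert peak == pytest.approx(30.0, abs=0.3)  # amplitude x 100, within 1%

    def test_short_trace_rejected(self):
        t = np.arange(0, 100.0)
        with pytest.raises(ValueError, match="fit window"):
            fit_fading_baseline(_trace(t, np.ones(t.size), np.ones(t.size)), "dLight1.1")

    def test_baseline_crossing_zero_rejected(self):
        t = np.arange(0, 1000.0)
        f = 1.0 - 0.002 * t  # hits zero at t=500
        with pytest.raises(ValueError, match="crosses zero"):
            fit_fading_baseline(_trace(t, f, np.ones(t.size)), "dLight1.1", 400.0)


class TestPercentRatioIncrease:
    def test_constant_ratio_gives_zero(self):
        t = np.arange(0, 600.0)
        assert percent_ratio_increase(
            _trace(t, 2.0 * np.ones(t.size), np.ones(t.size)), 300.0
        ) == pytest.approx(0.0, abs=1e-10)

    def test_step_increase_recovered(self):
        t = np.arange(0, 600.0)
        sig = np.where(t > 300, 1.5, 1.0)
        rise = percent_ratio_increase(
            _trace(t, sig, np.ones(t.size)), 300.0, pre_window_s=200,
            post_window_s=250, smoothing_s=5,
        )
        assert rise == pytest.approx(50.0, abs=1.0)

    def test_larger_transient_ranks_higher(self, basis):
        """A stronger challenge agent (larger evoked transient) always yields a
        larger ratio-increase metric, the basis of the agent ranking."""
        rises = []
        for amplitude in (0.3, 0.8):
            params = synthetic.SessionParams(
                frame_rate=5, duration=800, transient_onset=650,
                transient_amplitude=amplitude, noise_sd=0.02, seed=5,
            )
            series, _ = synthetic.simulate_session(basis, params)
            trace = unmix_series(series, basis)
            rises.append(
                percent_ratio_increase(trace, 650.0, pre_window_s=300, post_window_s=150)
            )
        assert rises[1] > rises[0]

    def test_nonpositive_reference_rejected(self):
        t = np.arange(0, 600.0)
        ref = np.ones(t.size)
        ref[350] = 0.0
        with pytest.raises(ValueError, match="reference"):
            percent_ratio_increase(_trace(t, np.ones(t.size), ref), 300.0)
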