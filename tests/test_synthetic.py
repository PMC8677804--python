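"""Generators: construction, determinism, moment fidelity, ground-truth linkage."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from dnctest import studyparams, synthetic
from dnctest.studyparams import GroupStats


class TestMakeBasis:
    def test_two_gaussians_unimodal_columns(self, grid, basis):
        assert basis.spectra.shape == (grid.size, 2)
        assert np.all(basis.spectra >= 0)
        for k in range(2):
            col = basis.spectra[:, k]
            peak = np.argmax(col)
            assert np.all(np.diff(col[: peak + 1]) >= 0)
            assert np.all(np.diff(col[peak:]) <= 0)
        # reference channel normalised to unit peak
        assert basis.column("tdTomato").max() == pytest.approx(1.0)

    def test_single_fluorophore_identity(self, grid):
        b = synthetic.make_basis([synthetic.DLIGHT], grid)
        expected = synthetic.DLIGHT.shape(grid)
        np.testing.assert_allclose(b.spectra[:, 0], expected / expected.max())

    def test_identical_specs_flagged_vs_svd_oracle(self, grid):
        twin = synthetic.FluorophoreSpec("twin", 510.0, 20.0)
        twin2 = synthetic.FluorophoreSpec("twin2", 510.0, 20.0)
        b = synthetic.make_basis([twin, twin2], grid, reference="twin2")
        sv = np.linalg.svd(b.spectra, compute_uv=False)
        oracle_cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        assert b.ill_conditioned
        assert b.condition_number == pytest.approx(oracle_cond, rel=1e-6) or np.isinf(
            oracle_cond
        )

    def test_peak_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError, match="outside the grid"):
            synthetic.make_basis(
                [synthetic.FluorophoreSpec("ir", 900.0, 20.0)], grid
            )


class TestSimulateSession:
    def test_static_mixture_without_dynamics(self, basis):
        params = synthetic.SessionParams(
            frame_rate=5, duration=10, bleach_slope=0, transient_onset=5,
            transient_amplitude=0, noise_sd=0, seed=0,
        )
        series, truth = synthetic.simulate_session(basis, params)
        assert np.all(series.frames == series.frames[0])
        np.testing.assert_allclose(truth.coefficients, 1.0)

    def test_linear_bleach_slope_recovered_by_least_squares(self, basis):
        params = synthetic.SessionParams(
            frame_rate=5, duration=300, bleach_slope=0.01, transient_onset=299,
            transient_amplitude=0, noise_sd=0, seed=0,
        )
        _, truth = synthetic.simulate_session(basis, params)
        c = truth.channel("dLight1.1")
        slope, intercept = np.polyfit(truth.timestamps, c, 1)
        assert slope == pytest.approx(-0.01 / 60.0, abs=1e-10)
        assert intercept == pytest.approx(1.0, abs=1e-10)

    def test_seeded_runs_bit_identical(self, basis):
        params = synthetic.SessionParams(frame_rate=5, duration=20, noise_sd=0.05,
                                         transient_onset=10, seed=42)
        a, _ = synthetic.simulate_session(basis, params)
        b, _ = synthetic.simulate_session(basis, params)
        assert np.array_equal(a.frames, b.frames)


class TestSimulateChromatogram:
    def test_empty_flat_zero(self):
        c = synthetic.simulate_chromatogram([], duration=30.0)
        np.testing.assert_array_equal(c.signal, 0.0)

    def test_true_area_matches_trapezoid_oracle(self):
        c = synthetic.simulate_chromatogram([("x", 30.0, 1.0, 2.0)], dt=0.01, duration=60)
        mask = np.abs(c.time_s - 30.0) <= 12.0  # +/- 6 sigma
        oracle = np.trapezoid(c.signal[mask], c.time_s[mask])
        assert c.true_areas["x"] == pytest.approx(2 * np.sqrt(2 * np.pi), rel=1e-6)
        assert oracle == pytest.approx(c.true_areas["x"], rel=1e-3)

    def test_negative_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            synthetic.simulate_chromatogram([("x", 10.0, 1.0, -1.0)])

    def test_overlap_flagged(self):
        c = synthetic.simulate_chromatogram([("a", 30.0, 1.0, 2.0), ("b", 33.0, 1.0, 2.0)])
        assert c.overlapping_peaks

    def test_seeded_runs_bit_identical(self):
        kwargs = dict(noise_sd=0.3, drift_slope=0.01, seed=7, duration=50)
        a = synthetic.simulate_chromatogram([("x", 20.0, 1.0, 2.0)], **kwargs)
        b = synthetic.simulate_chromatogram([("x", 20.0, 1.0, 2.0)], **kwargs)
        assert np.array_equal(a.signal, b.signal)


class TestSimulateCohort:
    def test_published_plasma_cell_means_recovered(self):
        spec = synthetic.CohortSpec.from_study("early", seed=11)
        table = synthetic.simulate_cohort(spec)
        for group, mean, sem in (("control", 17.91, 1.04), ("PD", 9.39, 0.46)):
            vals = table[
                (table.analyte == "HVA_ng_ml")
                & (table.state == "challenged")
                & (table.genotype_group == group)
            ].value
            assert abs(vals.mean() - mean) < 3 * sem * np.sqrt(len(vals))

    def test_cell_sizes_match_spec(self):
        table = synthetic.simulate_cohort(synthetic.CohortSpec.from_study("early", seed=0))
        for (stage, analyte, group, state), cell in studyparams.COHORT_STATS.items():
            if stage != "early":
                continue
            n = len(
                table[
                    (table.analyte == analyte)
                    & (table.genotype_group == group)
                    & (table.state == state)
                ]
            )
            assert n == cell.n

    def test_tiny_sem_degenerates_to_mean(self):
        cells = {
            (g, s, "HVA_ng_ml", "plasma"): GroupStats(10.0, 1e-12, 5)
            for g in studyparams.GROUPS
            for s in studyparams.STATES
        }
        table = synthetic.simulate_cohort(synthetic.CohortSpec(cells=cells, seed=1))
        np.testing.assert_allclose(table.value, 10.0, atol=1e-9)

    def test_oversampled_cell_sd_matches_sem_scaling(self):
        cells = {
            (g, s, "HVA_ng_ml", "plasma"): GroupStats(10.0, 2.0, 1000)
            for g in studyparams.GROUPS
            for s in studyparams.STATES
        }
        table = synthetic.simulate_cohort(synthetic.CohortSpec(cells=cells, seed=3))
        vals = table[(table.genotype_group == "control") & (table.state == "resting")].value
        assert abs(vals.std(ddof=1) - 2.0 * np.sqrt(1000)) < 0.05 * 2.0 * np.sqrt(1000)

    def test_missing_cell_error_names_cell(self):
        cells = {("control", "resting", "HVA_ng_ml", "plasma"): GroupStats(10.0, 1.0, 5)}
        with pytest.raises(ValueError, match="PD.*challenged|missing cells"):
            synthetic.simulate_cohort(synthetic.CohortSpec(cells=cells))

    def test_subject_ids_unique_and_deterministic(self):
        spec = synthetic.CohortSpec.from_study("ultra_early", seed=9)
        a = synthetic.simulate_cohort(spec)
        b = synthetic.simulate_cohort(spec)
        assert a.subject_id.is_unique
        pd.testing.assert_frame_equal(a, b)

    def test_moment_fidelity_across_seeds(self):
        """Empirical mean within 4*SEM and SD within [0.6, 1.4]*SEM*sqrt(n),
        failing in under 5% of 100 seeded cohorts for an n=30 cell."""
        cell = GroupStats(17.91, 1.04, 30)
        cells = {
            (g, s, "HVA_ng_ml", "plasma"): cell
            for g in studyparams.GROUPS
            for s in studyparams.STATES
        }
        failures = 0
        for seed in range(100):
            table = synthetic.simulate_cohort(synthetic.CohortSpec(cells=cells, seed=seed))
            vals = table[
                (table.genotype_group == "PD") & (table.state == "challenged")
            ].value.to_numpy()
            mean_ok = abs(vals.mean() - cell.mean) < 4 * cell.sem
            sd_ok = 0.6 * cell.sd <= vals.std(ddof=1) <= 1.4 * cell.sd
            failures += not (mean_ok and sd_ok)
        assert failures < 5


class TestSimulateHistology:
    def test_empty_image_is_textured_background(self):
        sim = synthetic.simulate_histology(
            synthetic.ImageSpec(shape=(64, 64), n_cells=0, seed=0)
        )
        assert sim.count == 0
        assert sim.label_mask.max() == 0
        assert sim.image.pixels.std() > 0  # texture present

    def test_disjoint_cells_ground_truth(self):
        sim = synthetic.simulate_histology(
            synthetic.ImageSpec(shape=(256, 256), n_cells=12, seed=4)
        )
        n_components, _ = ndi.label(sim.label_mask > 0)[1], None
        assert sim.count == 12
        assert ndi.label(sim.label_mask > 0)[1] == 12
        areas = np.bincount(sim.label_mask.ravel())[1:]
        assert np.all(areas > 200)  # radius 8-10 px disks

    def test_overlapping_pair_merges_in_naive_labeling(self):
        r = 9.0
        sim = synthetic.simulate_histology(
            synthetic.ImageSpec(shape=(96, 96), n_cells=2, seed=8),
            centers=[(48.0, 40.0), (48.0, 40.0 + 1.85 * r)],
            radii=[r, r],
        )
        _, n_naive = ndi.label(sim.label_mask > 0)
        assert sim.count == 2
        assert n_naive == 1  # connected-components oracle sees one blob

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="could not place"):
            synthetic.simulate_histology(
                synthetic.ImageSpec(shape=(64, 64), n_cells=50, seed=0)
            )

    def test_seeded_runs_bit_identical(self):
        spec = synthetic.ImageSpec(shape=(96, 96), n_cells=5, seed=13)
        a = synthetic.simulate_histology(spec)
        b = synthetic.simulate_histology(spec)
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert np.array_equal(a.label_mask, b.label_mask)
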