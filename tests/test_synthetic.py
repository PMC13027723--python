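"""Generators: determinism, planted ground truth, and stationarity."""

import numpy as np
import pytest

from flickerscope.contour import FluctuationField, uniform_angles
from flickerscope.errors import SpecValidationError
from flickerscope.synthetic import (BLANK_TRUE, LYSIS_TRUE, EnsembleSpec,
                                    OuSpec, PlantedCell, SceneSpec,
                                    VideoOptics, generate_absorbance,
                                    generate_angle_dynamics,
                                    generate_field_scene,
                                    generate_static_ensemble,
                                    render_contour_video)
from flickerscope.thermal import BOLTZMANN


class TestFieldScene:
    def test_empty_scene_is_uniform_background(self):
        img, manifest = generate_field_scene(
            SceneSpec(image_size=64, cells=[], noise_sd=0.0))
        assert manifest == []
        assert np.ptp(img) == 0

    def test_rim_trough_sits_at_planted_radius(self):
        """Radial intensity profile has its minimum on the planted ring."""
        cell = PlantedCell(center=(128.0, 128.0), radius=3.7)
        img, _ = generate_field_scene(
            SceneSpec(image_size=256, pixel_size=0.103,
                      cells=[cell], noise_sd=0.0))
        rho = np.linspace(1.0, 60.0, 600)
        profile = [img[128, int(round(128 + r))] for r in rho]
        r_min_px = rho[int(np.argmin(profile))]
        assert r_min_px * 0.103 == pytest.approx(3.7, abs=0.15)

    def test_same_seed_bitwise_identical(self):
        spec = SceneSpec(image_size=128, cells=[
            PlantedCell(center=(64.0, 64.0), radius=3.0)], noise_sd=0.02, seed=7)
        img1, _ = generate_field_scene(spec)
        img2, _ = generate_field_scene(spec)
        assert np.array_equal(img1, img2)

    def test_overlapping_clean_cells_rejected(self):
        cells = [PlantedCell(center=(100.0, 100.0), radius=5.0),
                 PlantedCell(center=(110.0, 100.0), radius=5.0)]
        with pytest.raises(SpecValidationError, match="overlap"):
            generate_field_scene(SceneSpec(image_size=256, cells=cells))

    def test_defect_plants_marked_not_accepted(self):
        for defect in ("border", "aggregate", "blurred", "small", "large",
                       "elongated"):
            cell = PlantedCell(center=(50.0, 50.0), radius=5.0, defect=defect)
            assert not cell.expected_accept
            assert cell.expected_reason


class TestAngleDynamics:
    def test_stiff_limit_kills_variance(self):
        field, _ = generate_angle_dynamics(
            OuSpec(n_angles=8, n_frames=500, stiffness_true=1e-2,
                   friction_true=1e-3, seed=0))
        assert field.h.var(axis=1).max() < 1e-18

    def test_lag1_autocorrelation_matches_ou_closed_form(self):
        spec = OuSpec(n_angles=32, n_frames=6000, seed=11)
        field, truth = generate_angle_dynamics(spec)
        expected = np.exp(-truth["omega_true"] / spec.fps)
        r1 = np.array([np.corrcoef(s[:-1], s[1:])[0, 1] for s in field.h])
        # SE of lag-1 autocorrelation of a near-unit-root AR(1)
        se = np.sqrt((1 - expected**2) / spec.n_frames)
        assert abs(r1.mean() - expected) < 3 * se / np.sqrt(spec.n_angles)

    def test_angle_series_mutually_uncorrelated(self):
        # fast-mixing parameters so the correlation SE at n=6000 is small
        field, _ = generate_angle_dynamics(
            OuSpec(n_angles=2, n_frames=6000, stiffness_true=1.5e-5,
                   friction_true=1e-7, seed=4))
        r = np.corrcoef(field.h[0], field.h[1])[0, 1]
        assert abs(r) < 0.1

    def test_stationary_halves_agree(self):
        """First- and second-half variances agree within 3 SE (seed-averaged)."""
        diffs = []
        for seed in range(5):
            field, truth = generate_angle_dynamics(
                OuSpec(n_angles=16, n_frames=6000, seed=seed))
            half = field.n_frames // 2
            v1 = field.h[:, :half].var(axis=1).mean()
            v2 = field.h[:, half:].var(axis=1).mean()
            diffs.append((v1 - v2) / truth["stationary_variance"])
        # each half-variance has relative SE ~ sqrt(2 / n_eff) per angle
        omega = OuSpec().stiffness_true / OuSpec().friction_true
        n_eff = 3000 / (2 * 2000 / omega / 2)
        se = np.sqrt(2 * 2 / n_eff / 16 / 5)
        assert abs(np.mean(diffs)) < 3 * se

    def test_unresolved_relaxation_rejected(self):
        with pytest.raises(SpecValidationError, match="fps"):
            OuSpec(stiffness_true=1.0, friction_true=1e-3, fps=100)


class TestStaticEnsemble:
    def test_infinite_tension_gives_perfect_circles(self):
        contours, _ = generate_static_ensemble(
            EnsembleSpec(n_cells=3, tension_true=np.inf, seed=0))
        for c in contours:
            assert np.allclose(c.radii, c.mean_radius, atol=1e-20)

    def test_mode3_power_matches_closed_form(self, thermal):
        sigma = 5e-7
        spec = EnsembleSpec(n_cells=1000, n_angles=128, tension_true=sigma,
                            mode_band=(3,), seed=9)
        contours, truth = generate_static_ensemble(spec)
        powers = []
        for c in contours:
            coef = np.fft.fft(c.h) / c.n_angles
            powers.append(abs(coef[3]) ** 2)
        expected = thermal.kBT / (6 * np.pi * sigma)
        assert np.mean(powers) == pytest.approx(expected, rel=0.10)
        assert truth["expected_power"][3] == pytest.approx(expected, rel=1e-12)

    def test_no_dc_component(self):
        contours, _ = generate_static_ensemble(EnsembleSpec(n_cells=5, seed=2))
        for c in contours:
            assert abs(c.h.mean()) < 1e-12 * c.mean_radius


class TestVideoRendering:
    def test_zero_field_no_drift_frames_identical(self):
        field = FluctuationField(h=np.zeros((32, 5)), fps=2000, pixel_size=50e-9)
        stack = render_contour_video(field, VideoOptics())
        assert all(np.array_equal(stack[0], f) for f in stack[1:])

    def test_planted_drift_recovered_from_binarized_centroids(self):
        field = FluctuationField(h=np.zeros((32, 10)), fps=2000, pixel_size=50e-9)
        stack = render_contour_video(
            field, VideoOptics(drift_px_per_frame=(0.5, -0.3)))
        centroids = []
        for frame in stack:
            mask = frame < 0.6
            rows, cols = np.nonzero(mask)
            centroids.append((rows.mean(), cols.mean()))
        steps = np.diff(np.array(centroids), axis=0)
        assert np.allclose(steps.mean(axis=0), (0.5, -0.3), atol=0.1)

    def test_mode3_oscillation_amplitude_in_rendered_rim(self):
        amp_px = 4.0
        theta = uniform_angles(64)
        t_grid = np.arange(24)
        h = amp_px * 50e-9 * np.outer(np.cos(3 * theta),
                                      np.cos(2 * np.pi * t_grid / 12))
        field = FluctuationField(h=h - h.mean(axis=1, keepdims=True),
                                 fps=2000, pixel_size=50e-9)
        stack = render_contour_video(field, VideoOptics())
        # rim radius at theta = 0: argmin of intensity along +x from center
        radii = []
        for frame in stack:
            row = frame[128, 128:200]
            radii.append(np.argmin(row))
        swing = max(radii) - min(radii)
        assert swing == pytest.approx(2 * amp_px, rel=0.12, abs=1.0)

    def test_contour_exiting_frame_names_frame(self):
        h = np.zeros((16, 4))
        h[:, 2] = 3e-6   # frame 2 balloons outward
        field = FluctuationField(h=h - h.mean(axis=1, keepdims=True),
                                 fps=2000, pixel_size=50e-9)
        # use a base radius close to the frame edge so frame 2 exits
        with pytest.raises(SpecValidationError, match="frame 2"):
            render_contour_video(field, VideoOptics(base_radius=5.0e-6))


class TestAbsorbance:
    def test_zero_level_zero_noise_sample_equals_blank(self):
        df = generate_absorbance(0.0, 0.0, seed=0)
        blank = df[df.role == "blank"][["A415", "A380", "A450"]].iloc[0]
        sample = df[df.role == "sample"][["A415", "A380", "A450"]].iloc[0]
        assert np.allclose(blank.to_numpy(), sample.to_numpy())
        assert np.allclose(blank.to_numpy(), BLANK_TRUE)

    def test_full_lysis_sample_equals_reference(self):
        df = generate_absorbance(0.0, 1.0, seed=0)
        sample = df[df.role == "sample"][["A415", "A380", "A450"]].iloc[0]
        assert np.allclose(sample.to_numpy(), LYSIS_TRUE)

    def test_blank_read_noise_has_requested_scale(self):
        df = generate_absorbance(0.01, 0.0, seed=5)
        sd = df[df.role == "blank"]["A415"].std(ddof=1)
        assert 0.005 < sd < 0.015  # within 50% at 15 reads
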