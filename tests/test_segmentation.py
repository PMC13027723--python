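"""Segmentation: preprocessing, Otsu, acceptance filter, contour extraction."""

import numpy as np
import pytest
from skimage import filters as skfilters

from flickerscope.contour import FluctuationField, uniform_angles
from flickerscope.errors import (DegenerateInputError, NonStarConvexError,
                                 TrackingError)
from flickerscope.segmentation import (AcceptanceCriteria, ComponentRecord,
                                       TrackParams, detect_and_filter,
                                       extract_contour, otsu_threshold,
                                       preprocess, track_video)
from flickerscope.synthetic import (OuSpec, PlantedCell, SceneSpec,
                                    VideoOptics, generate_angle_dynamics,
                                    generate_field_scene, generate_mode_series,
                                    render_contour_video)

from .conftest import PIXEL_SIZE_FIELD, match_log_to_manifest


def brute_force_otsu(values, nbins=256):
    """Exhaustive between-class-variance scan over every split (oracle).

    Ties keep the lowest split. Splits inside a run of empty bins define the
    same pixel partition and are exactly tied in exact arithmetic, so the
    comparison uses a relative tolerance to keep float summation order from
    breaking such ties.
    """
    hist, edges = np.histogram(values, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_var, best_split = -1.0, None
    total = hist.sum()
    for split in range(nbins - 1):
        w0 = hist[:split + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:split + 1] * centers[:split + 1]).sum() / w0
        mu1 = (hist[split + 1:] * centers[split + 1:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var * (1 + 1e-12):
            best_var, best_split = var, split
    return centers[best_split]


def disk_mask(size, radius, center=None):
    center = center or (size // 2, size // 2)
    yy, xx = np.mgrid[0:size, 0:size]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


def component_from_mask(mask):
    rows, cols = np.nonzero(mask)
    bbox = (rows.min(), cols.min(), rows.max() + 1, cols.max() + 1)
    return ComponentRecord(
        label=1, centroid=(rows.mean(), cols.mean()), bbox=bbox,
        mask=mask[bbox[0]:bbox[2], bbox[1]:bbox[3]], area_px=float(mask.sum()),
        equivalent_radius_um=0.0, circularity=0.0, solidity=1.0,
        focus_metric=1.0)


class TestPreprocess:
    def test_affine_normalization_to_unit_interval(self):
        frame = np.linspace(10, 20, 100).reshape(10, 10)
        out = preprocess(frame)
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)

    def test_pixel_noise_is_smoothed(self):
        rng = np.random.default_rng(0)
        frame = 0.5 + rng.normal(0, 0.05, (64, 64))
        out = preprocess(frame)
        ref = (frame - frame.min()) / np.ptp(frame)
        # high-frequency content shrinks relative to the overall contrast
        assert np.abs(np.diff(out, axis=1)).mean() < np.abs(np.diff(ref, axis=1)).mean()

    def test_constant_frame_rejected(self):
        with pytest.raises(DegenerateInputError):
            preprocess(np.full((16, 16), 3.0))


class TestOtsu:
    def test_bimodal_values_split_into_separate_classes(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([np.full(40, 0.2), np.full(60, 0.8)])
        rng.shuffle(values)
        t = otsu_threshold(values.reshape(10, 10))
        assert 0.2 <= t < 0.8

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan_on_gaussian_mixtures(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate([rng.normal(0.3, 0.05, 600),
                                 rng.normal(0.7, 0.08, 400)])
        assert otsu_threshold(values) == brute_force_otsu(values)

    def test_near_skimage_on_mixture(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0.25, 0.05, 500),
                                 rng.normal(0.75, 0.05, 500)])
        ours = otsu_threshold(values)
        theirs = skfilters.threshold_otsu(values, nbins=256)
        assert abs(ours - theirs) < np.ptp(values) / 256 + 1e-12

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.ones((8, 8)))


class TestDetectAndFilter:
    def test_fixture_scene_matches_manifest(self, segmented_scene):
        _, manifest, accepted, log = segmented_scene
        assert len(accepted) == sum(m["expected_accept"] for m in manifest)
        got = match_log_to_manifest(log, manifest)
        for i, m in enumerate(manifest):
            expected = "accepted" if m["expected_accept"] else m["expected_reason"]
            assert got[i] == expected, f"{m['defect']}: {got[i]} != {expected}"

    def test_in_window_circular_component_accepted(self):
        cell = PlantedCell(center=(256.0, 256.0), radius=7.0)
        img, _ = generate_field_scene(
            SceneSpec(image_size=512, cells=[cell], noise_sd=0.0))
        frame = preprocess(img)
        accepted, log = detect_and_filter(frame, AcceptanceCriteria(),
                                          PIXEL_SIZE_FIELD)
        assert len(accepted) == 1 and len(log) == 1
        assert 7.0 <= accepted[0].equivalent_radius_um <= 8.0

    def test_axis_ratio_2_ellipse_rejected_by_circularity(self):
        cell = PlantedCell(center=(256.0, 256.0), radius=7.0,
                           defect="elongated")
        img, _ = generate_field_scene(
            SceneSpec(image_size=512, cells=[cell], noise_sd=0.0))
        accepted, log = detect_and_filter(preprocess(img),
                                          AcceptanceCriteria(),
                                          PIXEL_SIZE_FIELD)
        assert not accepted
        assert log[0].status == "circularity"
        assert log[0].circularity < 0.9

    @pytest.mark.parametrize("defect", ["small", "large"])
    def test_missized_cells_rejected_by_size(self, defect):
        radius = 5.0 if defect == "small" else 10.0
        cell = PlantedCell(center=(256.0, 256.0), radius=radius, defect=defect)
        img, _ = generate_field_scene(
            SceneSpec(image_size=512, cells=[cell], noise_sd=0.0))
        accepted, log = detect_and_filter(preprocess(img),
                                          AcceptanceCriteria(),
                                          PIXEL_SIZE_FIELD)
        assert not accepted and log[0].status == "size"

    def test_deterministic_given_frame(self, segmented_scene):
        frame, _, accepted, log = segmented_scene
        accepted2, log2 = detect_and_filter(frame, AcceptanceCriteria(),
                                            PIXEL_SIZE_FIELD)
        assert [r.label for r in accepted] == [r.label for r in accepted2]
        assert [r.status for r in log] == [r.status for r in log2]


class TestExtractContour:
    def test_binarized_disk_recovers_radius(self):
        mask = disk_mask(128, 40)
        frame = np.where(mask, 0.1, 0.9)
        contour = extract_contour(frame, component_from_mask(mask),
                                  n_angles=720, spline_degree=12,
                                  pixel_size=1.0)
        assert np.all(np.abs(contour.radii - 40) < 0.5)

    def test_planted_mode3_amplitude_recovered(self):
        amp_um = 0.25
        cell = PlantedCell(center=(256.0, 256.0), radius=7.0,
                           mode_amplitudes={3: amp_um})
        img, _ = generate_field_scene(
            SceneSpec(image_size=512, cells=[cell], noise_sd=0.0))
        frame = preprocess(img)
        level = otsu_threshold(frame)
        accepted, _ = detect_and_filter(frame, AcceptanceCriteria(),
                                        PIXEL_SIZE_FIELD)
        contour = extract_contour(frame, accepted[0],
                                  pixel_size=PIXEL_SIZE_FIELD, level=level)
        coef = np.fft.fft(contour.h) / contour.n_angles
        recovered_um = 2 * abs(coef[3]) * 1e6
        assert recovered_um == pytest.approx(amp_um, rel=0.10)

    def test_rotation_equivariance(self):
        """Rotating the frame by 90 degrees shifts h(theta) by pi/2."""
        cell = PlantedCell(center=(256.0, 256.0), radius=7.0,
                           mode_amplitudes={3: 0.25})
        img, _ = generate_field_scene(
            SceneSpec(image_size=513, cells=[cell], noise_sd=0.0))

        def get_h(image):
            frame = preprocess(image)
            level = otsu_threshold(frame)
            accepted, _ = detect_and_filter(frame, AcceptanceCriteria(),
                                            PIXEL_SIZE_FIELD)
            return extract_contour(frame, accepted[0], n_angles=720,
                                   pixel_size=PIXEL_SIZE_FIELD, level=level).h

        # a 90-degree frame rotation shifts theta by pi/2 = 180 grid steps
        h0 = get_h(img)
        h90 = get_h(np.rot90(img).copy())
        rms0 = np.sqrt(np.mean(h0 ** 2))
        rms_err = min(
            np.sqrt(np.mean((h90 - np.roll(h0, shift)) ** 2))
            for shift in (180, -180))
        assert rms_err < 0.05 * rms0

    def test_crescent_raises_non_star_convex(self):
        mask = disk_mask(128, 40) & ~disk_mask(128, 32, center=(64, 80))
        frame = np.where(mask, 0.1, 0.9)
        with pytest.raises(NonStarConvexError):
            extract_contour(frame, component_from_mask(mask), pixel_size=1.0)


class TestTrackVideo:
    def test_rigid_drift_removed_by_recentering(self):
        field = FluctuationField(h=np.zeros((64, 40)), fps=2000,
                                 pixel_size=50e-9)
        stack = render_contour_video(
            field, VideoOptics(drift_px_per_frame=(0.5, -0.3)))
        rec = track_video(stack, TrackParams(n_angles=64, spline_degree=18))
        assert np.abs(rec.h).max() / 50e-9 < 0.2

    def test_band_limited_field_variance_recovered(self):
        theta = uniform_angles(64)
        T, fps = 150, 2000.0
        h = np.zeros((64, T))
        for i, n in enumerate((2, 3, 4, 5, 6)):
            c = generate_mode_series(T, fps, (120e-9) ** 2, omega=30.0,
                                     seed=100 + i)
            h += 2 * (np.outer(np.cos(n * theta), c.real)
                      - np.outer(np.sin(n * theta), c.imag))
        field = FluctuationField(h=h - h.mean(axis=1, keepdims=True),
                                 fps=fps, pixel_size=50e-9)
        stack = render_contour_video(field, VideoOptics(noise_sd=0.01))
        rec = track_video(stack, TrackParams(n_angles=64, spline_degree=18))
        ratio = rec.h.var(axis=1).mean() / field.h.var(axis=1).mean()
        assert ratio == pytest.approx(1.0, abs=0.15)

    def test_blank_frame_names_frame_index(self):
        field = FluctuationField(h=np.zeros((32, 6)), fps=2000,
                                 pixel_size=50e-9)
        stack = render_contour_video(field, VideoOptics(noise_sd=0.005))
        stack[3] = 0.85 + np.random.default_rng(0).normal(0, 0.005, stack[3].shape)
        with pytest.raises(TrackingError) as err:
            track_video(stack, TrackParams(n_angles=32, spline_degree=12))
        assert err.value.frame_index == 3

    def test_recentering_is_idempotent(self):
        spec = OuSpec(n_angles=16, n_frames=64, seed=1)
        field, _ = generate_angle_dynamics(spec)
        again = field.h - field.h.mean(axis=1, keepdims=True)
        assert np.allclose(again, field.h)
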