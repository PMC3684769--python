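import numpy as np
import pytest
from oracles import grid_argmax

from radonflow import (
    SyntheticSpec,
    add_motion_artifact,
    add_static_band,
    generate_sequence,
    generate_streak_image,
    iterative_radon,
    sobel_filter_time,
    vertical_demean,
)


class TestGenerateStreakImage:
    def test_deterministic_for_fixed_seed(self):
        spec = SyntheticSpec(theta_true=30.0, noise_sd=5.0, seed=42)
        a = generate_streak_image(spec)
        b = generate_streak_image(spec)
        assert a.pixels.tobytes() == b.pixels.tobytes()

    def test_different_seeds_differ(self):
        a = generate_streak_image(SyntheticSpec(theta_true=30.0, noise_sd=5.0, seed=1))
        b = generate_streak_image(SyntheticSpec(theta_true=30.0, noise_sd=5.0, seed=2))
        assert not np.array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize("theta_true", [-88.0, -45.0, -12.5, 2.0, 33.7, 60.0, 88.0])
    def test_ground_truth_recovered_on_fine_grid(self, theta_true):
        # tall geometry: longer streaks sharpen the variance peak enough
        # to resolve the near-vertical and near-horizontal extremes
        img = generate_streak_image(
            SyntheticSpec(theta_true=theta_true, width=160, height=320)
        )
        f = sobel_filter_time(img)
        found = grid_argmax(f.pixels, resolution=0.01, span=1.0)
        assert found == pytest.approx(theta_true, abs=0.05)

    def test_vertical_streaks_are_degenerate(self):
        # stagnant flow: any vertical operator suppresses the streaks
        img = generate_streak_image(SyntheticSpec(theta_true=0.0))
        np.testing.assert_allclose(sobel_filter_time(img).pixels, 0.0, atol=1e-9)
        np.testing.assert_allclose(vertical_demean(img).pixels, 0.0, atol=1e-9)

    def test_phase_offset_shifts_pattern(self):
        spec = SyntheticSpec(theta_true=45.0)
        a = generate_streak_image(spec, phase_offset=0.0)
        b = generate_streak_image(spec, phase_offset=spec.streak_spacing / 2)
        assert not np.array_equal(a.pixels, b.pixels)
        # a full period of phase is an exact identity
        c = generate_streak_image(spec, phase_offset=spec.streak_spacing)
        np.testing.assert_allclose(a.pixels, c.pixels, atol=1e-9)

    def test_streaks_darker_than_background(self):
        spec = SyntheticSpec(theta_true=45.0)
        img = generate_streak_image(spec)
        assert img.pixels.max() == pytest.approx(spec.background_level)
        assert img.pixels.min() == pytest.approx(
            spec.background_level - spec.contrast
        )
        inv = generate_streak_image(
            SyntheticSpec(theta_true=45.0, inverted=True)
        )
        assert inv.pixels.max() == pytest.approx(spec.background_level + spec.contrast)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(theta_true=45.0, streak_width=5.0, streak_spacing=4.0).validate()
        with pytest.raises(ValueError, match="no streak"):
            generate_streak_image(
                SyntheticSpec(theta_true=45.0, width=10, height=10, streak_spacing=200.0)
            )

    def test_streak_count_matches_packing_prediction(self):
        # number of distinct bands crossing a row vs floor(w*dx/ds)
        import math

        from radonflow import max_streak_count, streak_extents

        theta, spacing = 30.0, 12.0
        # geometry where streaks span the full height (spatial packing branch)
        spec = SyntheticSpec(
            theta_true=theta, width=200, height=100, streak_spacing=spacing
        )
        img = generate_streak_image(spec)
        # ds: spacing along the space axis converted to physical units
        s_x = spacing / math.cos(math.radians(theta))
        ws, hs = streak_extents(theta, spec.width, spec.height)
        predicted = max_streak_count(
            spec.width, spec.height, spec.dx, spec.dt, ws, hs, ds=s_x * spec.dx
        )
        row = img.pixels[spec.height // 2]
        in_band = row < spec.background_level - spec.contrast / 2
        n_bands = int(np.sum(np.diff(in_band.astype(int)) == 1) + in_band[0])
        assert abs(n_bands - predicted) <= 1


class TestArtifacts:
    def test_static_band_is_time_invariant_and_removable(self):
        img = generate_streak_image(SyntheticSpec(theta_true=45.0))
        banded = add_static_band(img, (10, 20), level=5.0)
        assert (banded.pixels[:, 10:20] == 5.0).all()
        # a pure band image is annihilated by both vertical filters
        flat = add_static_band(
            generate_streak_image(SyntheticSpec(theta_true=45.0, contrast=1e-9)),
            (10, 20),
            level=5.0,
        )
        np.testing.assert_allclose(vertical_demean(flat).pixels, 0.0, atol=1e-6)
        np.testing.assert_allclose(sobel_filter_time(flat).pixels, 0.0, atol=1e-6)

    def test_static_band_empty_range_is_identity(self):
        img = generate_streak_image(SyntheticSpec(theta_true=45.0))
        np.testing.assert_array_equal(
            add_static_band(img, (10, 10), level=5.0).pixels, img.pixels
        )

    def test_static_band_range_checked(self):
        img = generate_streak_image(SyntheticSpec(theta_true=45.0))
        with pytest.raises(ValueError):
            add_static_band(img, (90, 120), level=5.0)

    def test_motion_artifact_zero_amplitude_is_identity(self):
        img = generate_streak_image(SyntheticSpec(theta_true=45.0))
        out = add_motion_artifact(img, period_lines=50, amplitude_level=0.0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_motion_artifact_reproducible(self):
        img = generate_streak_image(SyntheticSpec(theta_true=45.0))
        a = add_motion_artifact(img, 50, 20.0, seed=9)
        b = add_motion_artifact(img, 50, 20.0, seed=9)
        assert a.pixels.tobytes() == b.pixels.tobytes()

    def test_sobel_suppresses_motion_bands_vdemean_does_not(self):
        # artifact on a flat background: slow horizontal bands
        flat = generate_streak_image(
            SyntheticSpec(theta_true=45.0, contrast=1e-9, width=60, height=400)
        )
        banded = add_motion_artifact(flat, period_lines=100, amplitude_level=30.0)
        residual_sobel = np.abs(sobel_filter_time(banded).pixels).max() / 8.0
        residual_vdemean = np.abs(vertical_demean(banded).pixels).max()
        assert residual_sobel < 0.2 * residual_vdemean

    def test_motion_artifact_parameters_checked(self):
        img = generate_streak_image(SyntheticSpec(theta_true=45.0))
        with pytest.raises(ValueError):
            add_motion_artifact(img, period_lines=1, amplitude_level=1.0)
        with pytest.raises(ValueError):
            add_motion_artifact(img, period_lines=50, amplitude_level=1.0, duty=1.5)


class TestGenerateSequence:
    def test_single_epoch_equals_direct_generation(self):
        spec = SyntheticSpec(theta_true=40.0, height=77)
        seq = generate_sequence([(spec, 77)])
        np.testing.assert_allclose(
            seq.pixels, generate_streak_image(spec).pixels, atol=1e-12
        )

    def test_constant_angle_epochs_are_seamless(self):
        # two epochs at the same angle must equal one long image
        spec = SyntheticSpec(theta_true=35.0, height=100)
        seq = generate_sequence([(spec, 60), (spec, 40)])
        np.testing.assert_allclose(
            seq.pixels, generate_streak_image(spec).pixels, atol=1e-9
        )

    def test_step_change_has_both_angles(self):
        spec30 = SyntheticSpec(theta_true=30.0)
        spec50 = SyntheticSpec(theta_true=50.0)
        seq = generate_sequence([(spec30, 300), (spec50, 300)])
        top = sobel_filter_time(seq.crop_rows(0, 250))
        bottom = sobel_filter_time(seq.crop_rows(350, 600))
        assert iterative_radon(top, target_delta=0.1).theta == pytest.approx(30, abs=0.3)
        assert iterative_radon(bottom, target_delta=0.1).theta == pytest.approx(
            50, abs=0.3
        )

    def test_mismatched_widths_rejected(self):
        with pytest.raises(ValueError, match="width"):
            generate_sequence(
                [
                    (SyntheticSpec(theta_true=30.0, width=100), 50),
                    (SyntheticSpec(theta_true=30.0, width=80), 50),
                ]
            )

    def test_empty_epoch_list_rejected(self):
        with pytest.raises(ValueError):
            generate_sequence([])
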