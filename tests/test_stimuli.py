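import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periacuity import (
    Condition,
    DisplayGeometry,
    NoiseSpec,
    OptotypeSpec,
    StimulusError,
    UnrenderableSizeError,
    compose_trial,
    flip_contrast,
    make_noise_background,
    make_temporal_profile,
    radial_power_spectrum,
    render_optotype,
    spectral_slope,
)
from periacuity.stimuli import ORIENTATION_RESPONSE


class TestDisplayGeometry:
    def test_degree_and_time_conversions(self, geometry):
        # 1.5 deg at 0.98 arcmin/px -> 92 px; 530 ms at 85 Hz -> 45 frames
        assert geometry.degrees_to_pixels(1.5) == 92
        assert geometry.seconds_to_frames(0.530) == 45
        assert geometry.pixels_to_degrees(geometry.degrees_to_pixels(1.0)) == pytest.approx(
            1.0, abs=geometry.pixel_pitch_deg
        )

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            DisplayGeometry(arcmin_per_pixel=-1)
        with pytest.raises(ValueError):
            DisplayGeometry(mean_luminance=100, luminance_max=90)


class TestOptotype:
    def test_patch_size_matches_diameter(self, geometry):
        img, mask = render_optotype(OptotypeSpec(1.5, 45), geometry)
        assert img.shape == (92, 92)
        rows, cols = np.nonzero(mask)
        assert rows.max() - rows.min() + 1 >= 90  # annulus spans the patch
        assert cols.max() - cols.min() + 1 >= 90

    def test_mask_identifies_exactly_the_departing_pixels(self, geometry):
        for polarity, value in (("black", 0.0), ("white", 90.0)):
            img, mask = render_optotype(OptotypeSpec(0.5, 135, polarity), geometry)
            departs = img != geometry.mean_luminance
            assert np.array_equal(departs, mask)
            assert np.all(img[mask] == value)

    @pytest.mark.parametrize("orientation", [45, 135, 225, 315])
    def test_gap_points_toward_orientation(self, geometry, orientation):
        _, mask = render_optotype(OptotypeSpec(1.0, orientation), geometry)
        # gap pixels = annulus of a gapless ring minus the letter mask
        d = mask.shape[0]
        c = (d - 1) / 2
        rows, cols = np.mgrid[0:d, 0:d]
        x, y = cols - c, c - rows
        r = np.hypot(x, y)
        ring = (r <= d / 2) & (r > d / 2 - 0.2 * d)
        gap = ring & ~mask
        assert gap.sum() > 0
        gx, gy = x[gap].mean(), y[gap].mean()
        theta = math.radians(orientation)
        dot = (gx * math.cos(theta) + gy * math.sin(theta)) / math.hypot(gx, gy)
        assert dot > 0.95  # gap centroid lies along the gap direction

    def test_gap_width_is_one_fifth_of_diameter(self):
        spec = OptotypeSpec(0.5, 45)
        assert spec.gap_fraction * spec.diameter_deg == pytest.approx(0.1)

    def test_response_mapping(self):
        assert ORIENTATION_RESPONSE[45] == "upper-right"
        assert ORIENTATION_RESPONSE[135] == "upper-left"
        assert ORIENTATION_RESPONSE[225] == "lower-left"
        assert ORIENTATION_RESPONSE[315] == "lower-right"

    def test_subpixel_size_and_bad_orientation_rejected(self, geometry):
        with pytest.raises(UnrenderableSizeError):
            render_optotype(OptotypeSpec(0.01, 45), geometry)
        with pytest.raises(StimulusError):
            OptotypeSpec(0.5, 90)


class TestNoise:
    def test_determinism(self, geometry):
        spec = NoiseSpec(extent_deg=3.0, seed=7)
        a = make_noise_background(spec, geometry)
        b = make_noise_background(spec, geometry)
        assert np.array_equal(a, b)
        c = make_noise_background(NoiseSpec(extent_deg=3.0, seed=8), geometry)
        assert not np.array_equal(a, c)

    def test_mean_luminance_preserved(self, geometry):
        img = make_noise_background(NoiseSpec(extent_deg=6.0, seed=3), geometry)
        assert abs(img.mean() - geometry.mean_luminance) < 0.005 * geometry.mean_luminance

    def test_luminance_within_display_range(self, geometry):
        img = make_noise_background(NoiseSpec(extent_deg=6.0, seed=3), geometry)
        assert img.min() >= geometry.luminance_min
        assert img.max() <= geometry.luminance_max

    def test_band_limit_and_brownian_slope(self, geometry):
        img = make_noise_background(NoiseSpec(seed=11), geometry)  # 16.7 deg extent
        slope = spectral_slope(img, geometry, 0.5, 6.0)
        assert slope == pytest.approx(-2.0, abs=0.3)
        # at 90% contrast a handful of tail pixels clip, leaking a little
        # (< -30 dB) broadband power past the cutoff
        freqs, power = radial_power_spectrum(img, geometry)
        in_band = np.nanmean(power[(freqs > 0.5) & (freqs < 6.0)])
        out_band = np.nansum(power[freqs > 6.2])
        assert out_band < 1e-3 * in_band

    def test_band_limit_exact_without_clipping(self, geometry):
        # at lower contrast no pixel clips and the synthesis filter is exact:
        # zero power above the upper bound to numerical precision
        img = make_noise_background(
            NoiseSpec(extent_deg=6.0, contrast_fraction=0.5, seed=11), geometry
        )
        freqs, power = radial_power_spectrum(img, geometry)
        in_band = np.nanmean(power[(freqs > 0.5) & (freqs < 6.0)])
        out_band = np.nansum(power[freqs > 6.2])
        assert out_band < 1e-12 * in_band

    def test_invalid_specs_rejected(self, geometry):
        with pytest.raises(StimulusError):
            make_noise_background(NoiseSpec(sf_upper_cpd=100.0), geometry)
        with pytest.raises(StimulusError):
            NoiseSpec(contrast_fraction=0.0)
        with pytest.raises(StimulusError):
            NoiseSpec(sf_lower_cpd=7.0, sf_upper_cpd=6.0)

    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=10, deadline=None)
    def test_flip_contrast_is_an_involution(self, seed):
        geometry = DisplayGeometry()
        img = make_noise_background(NoiseSpec(extent_deg=1.5, seed=seed), geometry)
        assert np.array_equal(flip_contrast(flip_contrast(img, geometry), geometry), img)


class TestTemporalProfile:
    @pytest.mark.parametrize("rate,fps", [(17.0, 5), (8.5, 10)])
    def test_flip_periods_on_the_85hz_grid(self, geometry, rate, fps):
        prof = make_temporal_profile("reversing", rate, 45, "black", geometry)
        assert prof.frames_per_state == fps
        changes = np.flatnonzero(np.diff(prof.signs))
        assert np.all(np.diff(changes) == fps)

    def test_17hz_gives_nine_states_over_45_frames(self, geometry):
        prof = make_temporal_profile("reversing", 17.0, 45, "black", geometry)
        n_states = 1 + int(np.sum(np.diff(prof.signs) != 0))
        assert n_states == 9

    def test_static_profile_is_constant(self, geometry):
        prof = make_temporal_profile("static_black", 0.0, 30, "black", geometry)
        assert set(prof.polarities()) == {"black"}
        assert np.all(prof.signs == 1)

    def test_incompatible_rate_rejected(self, geometry):
        with pytest.raises(StimulusError, match="rate incompatible"):
            make_temporal_profile("reversing", 12.0, 45, "black", geometry)


class TestComposeTrial:
    def test_duration_maps_to_45_frames(self, geometry, small_noise):
        seq = compose_trial(Condition("B", "U"), 0.5, 45, geometry, 0, noise_spec=small_noise)
        assert seq.n_frames == 45

    @given(duration=st.floats(0.1, 1.0))
    @settings(max_examples=20, deadline=None)
    def test_frame_count_identity(self, duration):
        geometry = DisplayGeometry()
        seq = compose_trial(
            Condition("B", "U"), 0.5, 45, geometry, 0,
            duration_s=duration, noise_spec=NoiseSpec(extent_deg=1.0),
        )
        assert seq.n_frames == round(duration * geometry.frame_rate)

    def test_static_black_on_uniform_is_constant(self, geometry, small_noise):
        seq = compose_trial(Condition("B", "U"), 0.5, 45, geometry, 1, noise_spec=small_noise)
        assert len(seq.unique_frames) == 1
        frame = seq.frame(0)
        patch = seq.target_patch(frame)
        assert np.all(patch[seq.target_mask] == geometry.luminance_min)
        assert set(seq.target_polarity_timeline) == {"black"}

    def test_asynchronous_condition_has_independent_timelines(self, geometry, small_noise):
        seq = compose_trial(Condition("H", "L"), 0.5, 45, geometry, 2, noise_spec=small_noise)
        pol = np.array([1 if p == seq.target_polarity_timeline[0] else -1
                        for p in seq.target_polarity_timeline])
        target_changes = np.flatnonzero(np.diff(pol))
        bg_changes = np.flatnonzero(np.diff(seq.background_polarity_timeline))
        assert np.all(np.diff(target_changes) == 5)
        assert np.all(np.diff(bg_changes) == 10)
        assert len(seq.unique_frames) == 4

    def test_all_luminances_within_display_range(self, geometry, small_noise):
        for label in ("BN", "WH", "LL", "HU"):
            seq = compose_trial(
                Condition(label[0], label[1]), 0.5, 135, geometry, 3, noise_spec=small_noise
            )
            stack = seq.frames
            assert stack.min() >= geometry.luminance_min
            assert stack.max() <= geometry.luminance_max

    def test_full_reversal_cycle_averages_to_mean_luminance(self, geometry, small_noise):
        # static black target on a 17 Hz reversing background: over one full
        # background cycle (10 frames) every non-target pixel averages to the
        # mean luminance
        seq = compose_trial(Condition("B", "H"), 0.5, 45, geometry, 4, noise_spec=small_noise)
        cycle = np.stack([seq.frame(i) for i in range(10)])
        temporal_mean = cycle.mean(axis=0)
        outside = np.ones_like(temporal_mean, bool)
        outside[seq.target_slices] = False
        assert np.allclose(temporal_mean[outside], geometry.mean_luminance, atol=1e-10)

    def test_background_centered_on_target(self, geometry, small_noise):
        seq = compose_trial(Condition("B", "N"), 0.5, 45, geometry, 5, noise_spec=small_noise)
        m = seq.shape[0]
        d = geometry.degrees_to_pixels(0.5)
        r0 = seq.target_slices[0].start
        assert abs((r0 + d / 2) - m / 2) <= 1

    def test_trial_noise_is_fresh_but_seed_deterministic(self, geometry, small_noise):
        a = compose_trial(Condition("B", "N"), 0.5, 45, geometry, 6, noise_spec=small_noise)
        b = compose_trial(Condition("B", "N"), 0.5, 45, geometry, 6, noise_spec=small_noise)
        c = compose_trial(Condition("B", "N"), 0.5, 45, geometry, 7, noise_spec=small_noise)
        assert np.array_equal(a.frame(0), b.frame(0))
        assert not np.array_equal(a.frame(0), c.frame(0))

    def test_reversing_uniform_background_is_unrepresentable(self):
        # the condition type itself forbids a reversing uniform background:
        # background states L/H always carry the noise texture
        assert Condition("B", "L").background_has_noise
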