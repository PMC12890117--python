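"""Front localization, profile cleanup, onset detection, windowed velocity."""

import numpy as np
import pytest

from atflow import (
    ChannelGeometry,
    ConfigurationError,
    FlowProfile,
    FlowVideoSpec,
    InvalidInputError,
    NoFlowError,
    QualityFailureError,
    analyze_video,
    build_profile,
    clean_profile,
    detect_front,
    detect_inflection,
    estimate_velocity,
)
from atflow.synthetic import generate_flow_video

from _oracles import ols_slope_oracle


def make_shifted_profile(distances, fps=30.0, length=200):
    """A FlowProfile already shifted to onset, for direct velocity tests."""
    return FlowProfile(
        distances=np.asarray(distances, dtype=float),
        fps=fps,
        channel_length_px=length,
        f0=0,
        shifted=True,
    )


class TestDetectFront:
    def setup_method(self):
        self.spec = FlowVideoSpec(n_frames=80, idle_frames=0, channel_length_px=150)
        self.geom = self.spec.geometry()
        self.stack, self.truth = generate_flow_video(self.spec, 2.0, seed=0)
        self.ref = self.stack.gray(0)

    def test_planted_front_recovered_on_all_lines(self):
        f = 60  # front at 120 px
        d = detect_front(self.stack.gray(f), self.geom, self.ref)
        assert np.all(np.abs(d - self.truth[f]) <= 1.0)
        assert self.truth[f] == 120.0

    def test_dry_frame_gives_zero(self):
        d = detect_front(self.ref, self.geom, self.ref)
        assert np.all(d == 0.0)

    def test_fully_wet_frame_gives_channel_length(self):
        spec = FlowVideoSpec(n_frames=10, channel_length_px=50)
        stack, _ = generate_flow_video(spec, 50.0, seed=0)
        d = detect_front(stack.gray(5), spec.geometry(), stack.gray(0))
        assert np.all(d == 50.0)

    @pytest.mark.parametrize("k", [1, 4, 10])
    def test_translation_equivariance(self, k):
        """Shifting the planted front by 2k px shifts all reported distances
        by 2k (frame f+k of a v=2 noise-free video)."""
        a = detect_front(self.stack.gray(20), self.geom, self.ref)
        b = detect_front(self.stack.gray(20 + k), self.geom, self.ref)
        assert np.all(b - a == 2 * k)

    def test_geometry_outside_frame_rejected(self):
        geom = ChannelGeometry(roi=(10, 10, 500, 40), entry_line=10, channel_length_px=500)
        with pytest.raises(ConfigurationError):
            detect_front(self.stack.gray(0), geom, self.ref)

    def test_mismatched_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            detect_front(self.stack.gray(0), self.geom, self.ref[:-1])


class TestBuildProfile:
    def test_constant_velocity_profile_matches_truth(self):
        spec = FlowVideoSpec(n_frames=50, idle_frames=5, channel_length_px=120)
        stack, truth = generate_flow_video(spec, 2.0, seed=0)
        profile = build_profile(stack, spec.geometry())
        assert profile.distances.shape == (4, 50)
        assert np.all(np.abs(profile.distances - truth[None, :]) <= 1.0)

    def test_idle_only_video_gives_zero_profile(self):
        spec = FlowVideoSpec(n_frames=20, idle_frames=19)
        stack, _ = generate_flow_video(spec, 2.0, seed=0)
        profile = build_profile(stack, spec.geometry())
        assert np.all(profile.distances == 0.0)

    def test_corrupted_frame_shows_extreme_distance(self):
        spec = FlowVideoSpec(n_frames=40, idle_frames=0, corrupt_frames=(15,),
                             channel_length_px=100)
        stack, _ = generate_flow_video(spec, 2.0, seed=3)
        profile = build_profile(stack, spec.geometry())
        assert np.all(np.isin(profile.distances[:, 15], [0.0, 100.0]))

    def test_too_few_frames_rejected(self):
        spec = FlowVideoSpec(n_frames=5)
        stack, _ = generate_flow_video(spec, 1.0, seed=0)
        stack.frames = stack.frames[:1]
        with pytest.raises(InvalidInputError):
            build_profile(stack, spec.geometry())


class TestCleanProfile:
    def test_midflow_zero_removed_neighbors_kept(self):
        d = np.tile(np.arange(40, dtype=float) + 1.0, (4, 1))
        d[:, 20] = 0.0
        p = FlowProfile(distances=d, fps=30, channel_length_px=200)
        cleaned = clean_profile(p)
        assert cleaned.provenance == [20]
        assert np.all(np.isnan(cleaned.distances[:, 20]))
        interior = np.delete(cleaned.distances, 20, axis=1)
        assert not np.any(np.isnan(interior))

    def test_clean_profile_idempotent_and_preserves_interior(self):
        d = np.tile(np.arange(1.0, 31.0), (4, 1))
        p = FlowProfile(distances=d, fps=30, channel_length_px=100)
        once = clean_profile(p)
        assert once.provenance == []
        assert np.array_equal(once.distances, d)
        twice = clean_profile(once)
        assert np.array_equal(
            np.nan_to_num(twice.distances), np.nan_to_num(once.distances)
        )

    def test_generator_corrupt_frames_land_in_provenance(self):
        spec = FlowVideoSpec(n_frames=50, idle_frames=5, corrupt_frames=(10, 11),
                             channel_length_px=300)
        stack, _ = generate_flow_video(spec, 2.0, seed=1)
        profile = build_profile(stack, spec.geometry())
        cleaned = clean_profile(profile)
        assert cleaned.provenance == [10, 11]

    def test_leading_zeros_not_removed(self):
        """Pre-flow zeros are genuine, not acquisition errors."""
        d = np.tile(np.concatenate([np.zeros(10), np.arange(1.0, 21.0)]), (4, 1))
        cleaned = clean_profile(FlowProfile(distances=d, fps=30, channel_length_px=100))
        assert cleaned.provenance == []

    def test_majority_removed_raises_quality_error(self):
        d = np.tile(np.arange(20, dtype=float) + 1.0, (4, 1))
        d[:, 3:18:2] = 0.0  # interleaved dropouts on every line
        with pytest.raises(QualityFailureError, match="line"):
            clean_profile(
                FlowProfile(distances=d, fps=30, channel_length_px=100),
                max_removed_fraction=0.3,
            )

    def test_isotonic_pass_enforces_monotonicity(self):
        d = np.tile(np.array([1.0, 5.0, 3.0, 7.0, 6.0, 9.0]), (4, 1))
        cleaned = clean_profile(
            FlowProfile(distances=d, fps=30, channel_length_px=100), isotonic=True
        )
        assert np.all(np.diff(cleaned.distances, axis=1) >= 0)


class TestDetectInflection:
    def test_idle_frames_locate_onset(self):
        spec = FlowVideoSpec(n_frames=60, idle_frames=15, channel_length_px=150)
        stack, _ = generate_flow_video(spec, 2.0, seed=0)
        profile = clean_profile(build_profile(stack, spec.geometry()))
        shifted = detect_inflection(profile)
        assert shifted.f0 == 15
        assert shifted.shifted

    def test_flow_from_frame_zero(self):
        spec = FlowVideoSpec(n_frames=50, idle_frames=0, channel_length_px=150)
        stack, _ = generate_flow_video(spec, 2.0, seed=0)
        profile = clean_profile(build_profile(stack, spec.geometry()))
        assert detect_inflection(profile).f0 == 0

    def test_all_zero_profile_raises_no_flow(self):
        d = np.zeros((4, 30))
        with pytest.raises(NoFlowError):
            detect_inflection(FlowProfile(distances=d, fps=30, channel_length_px=100))

    def test_shift_reindexes_frames(self):
        spec = FlowVideoSpec(n_frames=60, idle_frames=10, channel_length_px=150)
        stack, truth = generate_flow_video(spec, 2.0, seed=0)
        shifted = detect_inflection(clean_profile(build_profile(stack, spec.geometry())))
        # frame 1 after shifting is the first moving frame: distance v
        assert shifted.distances[0, 1] == pytest.approx(2.0, abs=1.0)


class TestEstimateVelocity:
    def test_exact_line_gives_exact_slope(self):
        d = np.tile(2.0 * np.arange(40), (4, 1))
        est = estimate_velocity(make_shifted_profile(d), window_frames=35)
        assert est.velocity == pytest.approx(2.0, abs=1e-12)
        assert est.se == 0.0

    def test_constant_profile_gives_zero_velocity(self):
        d = np.full((4, 40), 40.0)
        est = estimate_velocity(make_shifted_profile(d), window_frames=35)
        assert est.velocity == 0.0

    def test_window_duration_is_frames_over_fps(self):
        d = np.tile(1.0 * np.arange(40), (4, 1))
        est = estimate_velocity(make_shifted_profile(d, fps=30.0), window_frames=35)
        assert round(est.window_seconds, 2) == 1.17

    def test_slope_matches_closed_form_oracle(self, rng):
        """OLS slope equals Σ(f−f̄)(d−d̄)/Σ(f−f̄)² to 1e-12, missing frames
        skipped."""
        for _ in range(20):
            d = np.cumsum(rng.uniform(0, 3, size=(4, 35)), axis=1)
            d[0, rng.integers(5, 30)] = np.nan
            est = estimate_velocity(make_shifted_profile(d), window_frames=35)
            slopes = []
            for line in range(4):
                y = d[line]
                ok = np.isfinite(y)
                slopes.append(ols_slope_oracle(np.arange(35)[ok], y[ok]))
            assert est.velocity == pytest.approx(np.mean(slopes), abs=1e-12)
            assert est.per_line == pytest.approx(tuple(slopes), abs=1e-12)

    def test_se_is_sd_of_line_slopes_over_two(self):
        d = np.stack([k * np.arange(40.0) for k in (1.0, 2.0, 3.0, 4.0)])
        est = estimate_velocity(make_shifted_profile(d), window_frames=35)
        assert est.velocity == pytest.approx(2.5)
        assert est.se == pytest.approx(np.std([1, 2, 3, 4], ddof=1) / 2)

    def test_insufficient_points_raise_quality_error(self):
        d = np.tile(1.0 * np.arange(40), (4, 1))
        d[2, :34] = np.nan
        with pytest.raises(QualityFailureError, match="line 2"):
            estimate_velocity(make_shifted_profile(d), window_frames=35)

    def test_unshifted_profile_rejected(self):
        p = FlowProfile(distances=np.zeros((4, 40)), fps=30, channel_length_px=100)
        with pytest.raises(InvalidInputError):
            estimate_velocity(p, window_frames=35)


class TestPipeline:
    def test_noise_free_round_trip_exact(self):
        """Planted v recovered to 1e-9 px/frame from a noise-free video."""
        spec = FlowVideoSpec(n_frames=60, idle_frames=8, channel_length_px=150)
        stack, _ = generate_flow_video(spec, 2.0, seed=0)
        est, prof = analyze_video(stack, spec.geometry(), window_frames=35)
        assert abs(est.velocity - 2.0) < 1e-9
        assert prof.f0 == 8

    def test_pipeline_deterministic(self):
        spec = FlowVideoSpec(n_frames=60, idle_frames=5, jitter_sd_px=1.0,
                             channel_length_px=150)
        stack, _ = generate_flow_video(spec, 1.2, seed=9)
        a, _ = analyze_video(stack, spec.geometry())
        b, _ = analyze_video(stack, spec.geometry())
        assert a == b

    def test_jittered_estimates_statistically_unbiased(self):
        """Monte-Carlo parameter recovery for v=0.6 under 1 px jitter."""
        spec = FlowVideoSpec(n_frames=55, idle_frames=5, jitter_sd_px=1.0,
                             channel_length_px=120)
        estimates = []
        for seed in range(100):
            stack, _ = generate_flow_video(spec, 0.6, seed=seed)
            est, _ = analyze_video(stack, spec.geometry(), window_frames=35)
            estimates.append(est.velocity)
        mean = np.mean(estimates)
        mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - 0.6) < 2 * mc_se + 1e-3
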