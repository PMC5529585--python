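"""Stimulus generation: band tiling, dot kinematics, matched cues, form streaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from segscale.stimuli import (
    FORM_POLARITIES,
    LEFTWARD,
    RIGHTWARD,
    StimulusParameterError,
    StimulusParams,
    advance_frame,
    build_segment_layout,
    form_params,
    model_params,
    render_form_pattern,
    sample_comparison_stimulus,
    sample_test_stimulus,
)


class TestStimulusParams:
    def test_derived_speed_and_duration(self):
        p = StimulusParams()
        assert p.speed == pytest.approx(3.5)
        assert p.duration == pytest.approx(0.43)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_dots=0), dict(n_frames=1), dict(dot_lifetime=0),
         dict(window_width=-1.0), dict(displacement_per_update=0.0)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(StimulusParameterError):
            StimulusParams(**kwargs)


class TestSegmentLayout:
    def test_exact_halving_tiling(self):
        layout = build_segment_layout(7.0, 3.5, jitter_offset=0.0, first_polarity=RIGHTWARD)
        assert np.allclose(layout.band_edges, [0.0, 3.5, 7.0])
        assert np.allclose(layout.band_polarities, [RIGHTWARD, LEFTWARD])

    def test_eight_full_bands_alternate(self):
        layout = build_segment_layout(7.0, 0.875, jitter_offset=0.0, first_polarity=LEFTWARD)
        assert layout.n_bands == 8
        assert np.allclose(np.diff(layout.band_edges), 0.875)
        assert np.allclose(layout.band_polarities[::2], LEFTWARD)
        assert np.allclose(layout.band_polarities[1::2], RIGHTWARD)

    def test_jittered_partial_bands_follow_cyclic_tiling(self):
        # brute-force expectation: tiling from y0 = 1.75 - 3.5 gives bands
        # [-1.75, 1.75), [1.75, 5.25), [5.25, 8.75) -> window edges
        # {0, 1.75, 5.25, 7} with polarities [first, other, first]
        layout = build_segment_layout(7.0, 3.5, jitter_offset=1.75, first_polarity=RIGHTWARD)
        assert np.allclose(layout.band_edges, [0.0, 1.75, 5.25, 7.0])
        assert np.allclose(layout.band_polarities, [RIGHTWARD, LEFTWARD, RIGHTWARD])

    @pytest.mark.parametrize("segment_size", [0.0, -1.0, 7.5])
    def test_invalid_segment_size(self, segment_size):
        with pytest.raises(StimulusParameterError):
            build_segment_layout(7.0, segment_size, jitter_offset=0.0, first_polarity=RIGHTWARD)

    @given(
        segment=st.floats(0.05, 7.0),
        jitter_frac=st.floats(0.0, 0.999),
        first=st.sampled_from([RIGHTWARD, LEFTWARD]),
    )
    @settings(max_examples=100, deadline=None)
    def test_tiling_invariants(self, segment, jitter_frac, first):
        layout = build_segment_layout(
            7.0, segment, jitter_offset=jitter_frac * segment, first_polarity=first
        )
        edges = layout.band_edges
        assert edges[0] == 0.0 and edges[-1] == pytest.approx(7.0)
        heights = np.diff(edges)
        assert np.all(heights > 0)
        # interior bands are full-height; only the two edge bands may be partial
        if layout.n_bands > 2:
            assert np.allclose(heights[1:-1], segment, rtol=1e-6)
        # sub-tolerance jitter merges a sliver into an edge band, so edge
        # bands may exceed the segment height by at most the edge tolerance
        assert np.all(heights <= segment * (1 + 1e-6) + 1e-8)
        # adjacent bands alternate polarity
        assert np.all(layout.band_polarities[:-1] != layout.band_polarities[1:])


class TestMotionSequences:
    def test_full_coherence_directions_match_band_polarity(self, rng, two_frame_params):
        layout = build_segment_layout(7.0, 0.875, rng)
        seq = sample_test_stimulus(two_frame_params, layout, 1.0, rng)
        frame = seq.frames[0]
        assert frame.signal.all()
        expected = layout.band_polarities[layout.band_index(frame.y)]
        assert np.array_equal(frame.theta, expected)
        # within-band direction variance 0, adjacent bands differ by pi
        assert abs(layout.band_polarities[0] - layout.band_polarities[1]) == pytest.approx(np.pi)

    def test_zero_coherence_has_uniform_directions(self, rng):
        params = model_params(n_dots=4096)
        layout = build_segment_layout(7.0, 1.75, rng)
        seq = sample_test_stimulus(params, layout, 0.0, rng)
        assert seq.n_signal == 0
        # chi-square goodness of fit against uniform over 8 direction bins
        counts, _ = np.histogram(seq.frames[0].theta, bins=8, range=(0, 2 * np.pi))
        p = sps.chisquare(counts).pvalue
        assert p > 0.001

    def test_default_sequence_shape(self, rng, default_params):
        layout = build_segment_layout(7.0, 1.75, rng)
        seq = sample_test_stimulus(default_params, layout, 0.5, rng)
        assert len(seq.frames) == 43
        assert all(f.n_dots == 256 for f in seq.frames)

    @pytest.mark.parametrize("coherence", [0.0, 0.33, 0.5, 1.0])
    def test_signal_count_is_exact_round(self, rng, two_frame_params, coherence):
        layout = build_segment_layout(7.0, 1.75, rng)
        seq = sample_test_stimulus(two_frame_params, layout, coherence, rng)
        assert seq.n_signal == round(coherence * 256)
        assert int(seq.frames[0].signal.sum()) == seq.n_signal

    def test_test_constructor_requires_layout(self, rng, two_frame_params):
        with pytest.raises(StimulusParameterError):
            sample_test_stimulus(two_frame_params, None, 0.5, rng)

    def test_comparison_counts_must_sum(self, rng, two_frame_params):
        with pytest.raises(StimulusParameterError):
            sample_comparison_stimulus(two_frame_params, (100, 100), 100, rng)

    def test_comparison_matches_test_cues(self, rng, two_frame_params):
        layout = build_segment_layout(7.0, 0.875, rng)
        test = sample_test_stimulus(two_frame_params, layout, 0.4, rng)
        nr, nl = test.signal_counts
        comp = sample_comparison_stimulus(two_frame_params, (nr, nl), 256 - nr - nl, rng)
        assert comp.signal_counts == test.signal_counts
        assert comp.layout is None
        f = comp.frames[0]
        assert int(np.sum(f.signal & (f.theta == RIGHTWARD))) == nr
        assert int(np.sum(f.signal & (f.theta == LEFTWARD))) == nl

    def test_all_signal_comparison_split(self, rng, two_frame_params):
        comp = sample_comparison_stimulus(two_frame_params, (128, 128), 0, rng)
        f = comp.frames[0]
        assert f.signal.all()
        assert int(np.sum(f.theta == RIGHTWARD)) == 128

    def test_direction_distribution_matches_paired_test(self, rng):
        """Marginal direction histograms of test and comparison agree."""
        params = model_params()
        test_dirs, comp_dirs = [], []
        for _ in range(40):
            layout = build_segment_layout(7.0, 0.875, rng)
            test = sample_test_stimulus(params, layout, 0.5, rng)
            nr, nl = test.signal_counts
            comp = sample_comparison_stimulus(params, (nr, nl), 256 - nr - nl, rng)
            test_dirs.append(test.frames[0].theta)
            comp_dirs.append(comp.frames[0].theta)
        bins = np.linspace(0, 2 * np.pi, 13)
        h_test, _ = np.histogram(np.concatenate(test_dirs), bins=bins)
        h_comp, _ = np.histogram(np.concatenate(comp_dirs), bins=bins)
        # two-sample chi-square on the pooled histograms
        table = np.vstack([h_test, h_comp])
        p = sps.chi2_contingency(table).pvalue
        assert p > 0.001


class TestAdvanceFrame:
    def test_rightward_displacement(self, rng, two_frame_params):
        layout = build_segment_layout(7.0, 3.5, jitter_offset=0.0, first_polarity=RIGHTWARD)
        seq = sample_test_stimulus(two_frame_params, layout, 1.0, rng)
        f0 = seq.frames[0]
        f0.x[:] = 1.0
        f0.age[:] = 1
        f1 = advance_frame(f0, two_frame_params, layout, rng)
        moved = f1.x - f0.x
        expected = np.where(f0.theta == RIGHTWARD, 0.035, -0.035)
        assert np.allclose(moved, expected)
        assert np.all(f1.age == 2)

    def test_horizontal_wraparound(self, rng, two_frame_params):
        layout = build_segment_layout(7.0, 3.5, jitter_offset=0.0, first_polarity=RIGHTWARD)
        seq = sample_test_stimulus(two_frame_params, layout, 1.0, rng)
        f0 = seq.frames[0]
        f0.x[:] = 6.99
        f0.theta[:] = RIGHTWARD
        f0.age[:] = 1
        f1 = advance_frame(f0, two_frame_params, layout, rng)
        assert np.allclose(f1.x, 0.025)

    def test_expired_dots_replot_within_band(self, rng, two_frame_params):
        layout = build_segment_layout(7.0, 0.875, jitter_offset=0.0, first_polarity=RIGHTWARD)
        seq = sample_test_stimulus(two_frame_params, layout, 1.0, rng)
        f0 = seq.frames[0]
        f0.age[:] = two_frame_params.dot_lifetime  # all expire on next update
        f1 = advance_frame(f0, two_frame_params, layout, rng)
        assert np.all(f1.age == 1)
        lo = layout.band_edges[f0.band]
        hi = layout.band_edges[f0.band + 1]
        assert np.all((f1.y >= lo) & (f1.y < hi))
        assert f1.n_dots == f0.n_dots

    def test_dot_count_conserved_over_full_sequence(self, rng, default_params):
        layout = build_segment_layout(7.0, 0.438, rng)
        seq = sample_test_stimulus(default_params, layout, 0.5, rng)
        for f in seq.frames:
            assert f.n_dots == default_params.n_dots
            assert np.all((f.x >= 0) & (f.x < 7.0))
            assert np.all((f.y >= 0) & (f.y < 7.0))
            assert np.all((f.age >= 1) & (f.age <= default_params.dot_lifetime))

    def test_mean_displacement_magnitude(self, rng, default_params):
        """Every non-replotted dot moves exactly one displacement unit."""
        layout = build_segment_layout(7.0, 3.5, rng)
        seq = sample_test_stimulus(default_params, layout, 0.3, rng)
        f0, f1 = seq.frames[0], seq.frames[1]
        kept = f1.age > 1  # replotted dots have age 1
        dx = f1.x[kept] - f0.x[kept]
        dx = np.where(dx > 3.5, dx - 7.0, np.where(dx < -3.5, dx + 7.0, dx))  # unwrap
        dy = f1.y[kept] - f0.y[kept]
        d = np.hypot(dx, dy)
        # clamping at band edges can only shorten a step
        assert np.all(d <= 0.035 + 1e-12)
        assert np.median(d) == pytest.approx(0.035, rel=1e-9)


class TestFormPatterns:
    def test_signal_streak_extent_and_collinearity(self, rng):
        params = form_params()
        layout = build_segment_layout(7.0, 0.875, rng, polarities=FORM_POLARITIES)
        pattern = render_form_pattern(params, layout, 1.0, rng)
        assert pattern.signal.all()
        expected = params.dot_diameter + 3 * params.displacement_per_update
        for i in range(0, pattern.n_elements, 16):
            assert pattern.element_extent(i) == pytest.approx(expected)
            pts = pattern.centres[i]
            # collinear along the orientation axis with spacing 0.035
            steps = np.diff(pts, axis=0)
            assert np.allclose(np.hypot(steps[:, 0], steps[:, 1]), 0.035)
            axis = pattern.axis[i]
            along = steps @ np.array([np.cos(axis), np.sin(axis)])
            assert np.allclose(np.abs(along), 0.035)

    def test_orientations_alternate_across_bands(self, rng):
        params = form_params()
        layout = build_segment_layout(
            7.0, 0.875, jitter_offset=0.0, first_polarity=FORM_POLARITIES[0],
            polarities=FORM_POLARITIES,
        )
        pattern = render_form_pattern(params, layout, 1.0, rng)
        start_y = pattern.centres[:, 0, 1]
        band = layout.band_index(start_y)
        assert np.array_equal(pattern.axis, layout.band_polarities[band])

    def test_noise_clusters_bounded_random_walk(self, rng):
        params = form_params()
        pattern = render_form_pattern(params, None, 0.0, rng)
        assert not pattern.signal.any()
        # maximum random-walk excursion after 3 steps of 0.035
        start = pattern.centres[:, 0, :]
        spread = np.linalg.norm(pattern.centres - start[:, None, :], axis=-1).max(axis=1)
        assert np.all(spread <= 3 * 0.035 + 1e-12)

    def test_comparison_pattern_mixes_orientations(self, rng):
        params = form_params(n_dots=512)
        pattern = render_form_pattern(params, None, 1.0, rng)
        counts = [int(np.sum(pattern.axis == a)) for a in FORM_POLARITIES]
        assert sum(counts) == 512
        assert min(counts) > 180  # both axes well represented
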