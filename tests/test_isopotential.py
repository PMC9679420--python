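"""IDW interpolation, frame rendering and sequence construction/resizing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bspmaf.errors import AmbiguityError, ConfigurationError, DataError, EmptyInputError
from bspmaf.isopotential import (
    build_sequence,
    idw_interpolate,
    render_frame,
    resize_sequence,
)
from bspmaf.preprocess import Segment


def brute_force_idw(known_xy, known_values, q, u=2.0):
    """Independent weight-sum oracle (plain loop over known points)."""
    num = den = 0.0
    for (x, y), z in zip(known_xy, known_values):
        d = np.hypot(q[0] - x, q[1] - y)
        if d == 0:
            return z
        w = d**-u
        num += w * z
        den += w
    return num / den


class TestIdw:
    def test_exact_hit_returns_known_value(self):
        out = idw_interpolate([(0, 0), (1, 1)], [3.0, 7.0], [(1, 1)])
        assert out[0] == 7.0

    def test_constant_field_everywhere(self, rng):
        pts = rng.uniform(0, 10, (12, 2))
        out = idw_interpolate(pts, np.full(12, 4.2), rng.uniform(0, 10, (20, 2)))
        np.testing.assert_allclose(out, 4.2)

    def test_hand_computed_two_point_example(self):
        # knowns at distance 1 (value 0) and 2 (value 4), u=2:
        # (0*1 + 4*0.25) / (1 + 0.25) = 0.8
        out = idw_interpolate([(0.0, 0.0), (3.0, 0.0)], [0.0, 4.0], [(1.0, 0.0)], u=2)
        assert out[0] == pytest.approx(0.8, abs=1e-12)

    def test_conflicting_coincident_points_raise(self):
        with pytest.raises(AmbiguityError):
            idw_interpolate([(0, 0), (0, 0)], [1.0, 2.0], [(0, 0)])

    def test_empty_known_set_raises(self):
        with pytest.raises(EmptyInputError):
            idw_interpolate(np.empty((0, 2)), [], [(0, 0)])

    @settings(max_examples=60, deadline=None)
    @given(
        n=st.integers(1, 20),
        seed=st.integers(0, 10_000),
        u=st.sampled_from([1.0, 2.0, 3.0]),
    )
    def test_matches_brute_force_oracle_and_convex_bound(self, n, seed, u):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 5, (n, 2))
        vals = rng.uniform(-3, 3, n)
        queries = rng.uniform(0, 5, (5, 2))
        out = idw_interpolate(pts, vals, queries, u=u)
        for q, o in zip(queries, out):
            assert o == pytest.approx(brute_force_idw(pts, vals, q, u), rel=1e-9)
        assert np.all(out >= vals.min() - 1e-12)
        assert np.all(out <= vals.max() + 1e-12)


def make_segment(layout, data):
    return Segment(np.asarray(data, float), 1000.0, "P01", 0, "unlabeled",
                   list(layout.names))


class TestRenderFrame:
    def test_uniform_voltage_fills_mask(self, layout, grid):
        seg = make_segment(layout, np.full((128, 10), 0.7))
        frame = render_frame(seg, 3, grid)
        np.testing.assert_allclose(frame.pixels[grid.mask], 0.7)
        np.testing.assert_allclose(frame.pixels[~grid.mask], 0.0)

    def test_values_outside_unit_interval_rejected(self, layout, grid):
        seg = make_segment(layout, np.full((128, 4), 2.0))
        with pytest.raises(DataError):
            render_frame(seg, 0, grid)

    def test_t_index_out_of_range(self, layout, grid):
        seg = make_segment(layout, np.zeros((128, 4)))
        with pytest.raises(IndexError):
            render_frame(seg, 4, grid)

    def test_hot_electrode_intensity_decays_with_distance(self, layout, grid):
        data = np.zeros((128, 1))
        hot = layout.index("3")  # mid-chest anterior electrode
        data[hot, 0] = 1.0
        frame = render_frame(make_segment(layout, data), 0, grid)
        k = grid.electrode_names.index("3")
        r0, c0 = grid.electrode_px[k]
        # the brightest pixel sits at the hot electrode
        rmax, cmax = np.unravel_index(np.argmax(frame.pixels), frame.pixels.shape)
        assert np.hypot(rmax - r0, cmax - c0) < 1.0
        # walking away along the row, intensity falls monotonically until the
        # next (zero-valued) electrode pins the field back down
        others = [c for n, (r, c) in zip(grid.electrode_names, grid.electrode_px)
                  if n != "3" and abs(r - r0) < 1.5 and c > c0]
        row, stop = int(round(r0)), int(min(others))
        vals = [frame.pixels[row, c] for c in range(int(round(c0)), stop)
                if grid.mask[row, c]]
        assert len(vals) >= 3
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_channel_permutation_equivariance(self, layout, grid, rng):
        data = rng.uniform(0, 1, (128, 5))
        seg = make_segment(layout, data)
        perm = rng.permutation(128)
        seg_p = Segment(data[perm], 1000.0, "P01", 0, "unlabeled",
                        [layout.names[i] for i in perm])
        f1 = render_frame(seg, 2, grid)
        f2 = render_frame(seg_p, 2, grid)
        np.testing.assert_allclose(f1.pixels, f2.pixels, atol=1e-12)


class TestSequences:
    def test_two_second_window_gives_2000_frames(self, layout, grid):
        seg = make_segment(layout, np.full((128, 2000), 0.5))
        seq = build_sequence(seg, grid)
        assert seq.frames.shape == (grid.height, grid.width, 2000)
        assert seq.dt_s == pytest.approx(1e-3)

    def test_single_sample_gives_one_frame(self, layout, grid):
        seq = build_sequence(make_segment(layout, np.full((128, 1), 0.2)), grid)
        assert seq.frames.shape[2] == 1

    def test_time_constant_segment_gives_identical_frames(self, layout, grid, rng):
        col = rng.uniform(0, 1, (128, 1))
        seg = make_segment(layout, np.repeat(col, 50, axis=1))
        seq = build_sequence(seg, grid)
        for t in range(1, 50):
            np.testing.assert_array_equal(seq.frames[:, :, t], seq.frames[:, :, 0])

    def test_sequence_matches_frame_by_frame_rendering(self, layout, grid, rng):
        seg = make_segment(layout, rng.uniform(0, 1, (128, 8)))
        seq = build_sequence(seg, grid)
        for t in (0, 3, 7):
            np.testing.assert_allclose(
                seq.frames[:, :, t], render_frame(seg, t, grid).pixels, atol=1e-12
            )

    def test_empty_segment_raises(self, layout, grid):
        with pytest.raises(EmptyInputError):
            build_sequence(make_segment(layout, np.zeros((128, 0))), grid)

    def test_determinism(self, layout, grid, rng):
        seg = make_segment(layout, rng.uniform(0, 1, (128, 20)))
        s1 = build_sequence(seg, grid)
        s2 = build_sequence(seg, grid)
        np.testing.assert_array_equal(s1.frames, s2.frames)


class TestResize:
    def test_identity_resize(self, layout, grid, rng):
        seq = build_sequence(make_segment(layout, rng.uniform(0, 1, (128, 16))), grid)
        out = resize_sequence(seq, grid.width, grid.height, 16)
        np.testing.assert_allclose(out.frames, seq.frames, atol=1e-6)

    def test_temporal_reduction_to_128_frames(self, layout, grid):
        seq = build_sequence(make_segment(layout, np.full((128, 2000), 0.4)), grid)
        out = resize_sequence(seq, 16, 16, 128)
        assert out.frames.shape == (16, 16, 128)

    def test_constant_sequence_stays_constant(self):
        from bspmaf.isopotential import IsopotentialSequence

        seq = IsopotentialSequence(frames=np.full((32, 32, 64), 0.3), dt_s=1e-3)
        out = resize_sequence(seq, 8, 8, 16)
        np.testing.assert_allclose(out.frames, 0.3, atol=1e-9)

    def test_values_stay_in_unit_interval(self, layout, grid, rng):
        seq = build_sequence(make_segment(layout, rng.uniform(0, 1, (128, 64))), grid)
        out = resize_sequence(seq, 16, 16, 16)
        assert out.frames.min() >= 0.0 and out.frames.max() <= 1.0

    def test_temporal_upsampling_refused(self, layout, grid):
        seq = build_sequence(make_segment(layout, np.full((128, 8), 0.5)), grid)
        with pytest.raises(ConfigurationError):
            resize_sequence(seq, 16, 16, 9)

    def test_temporal_blocks_are_averaged(self, layout, grid):
        data = np.zeros((128, 4))
        data[:, :2] = 0.2
        data[:, 2:] = 0.8
        seq = build_sequence(make_segment(layout, data), grid)
        out = resize_sequence(seq, grid.width, grid.height, 2)
        np.testing.assert_allclose(out.frames[grid.mask][:, 0], 0.2, atol=1e-12)
        np.testing.assert_allclose(out.frames[grid.mask][:, 1], 0.8, atol=1e-12)
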