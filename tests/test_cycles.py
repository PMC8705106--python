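import numpy as np
import pytest

from gaitid.cycles import (
    DistanceSeries,
    GaitCycle,
    Provenance,
    ankle_distance,
    extract_cycles,
    find_extrema,
    interpolate,
    prune_extrema,
    segment_cycles,
    smooth,
)
from gaitid.skeleton import H36M_JOINTS, JointSequence3D, h36m_column

from _oracles import brute_force_extrema, random_smooth_signal


def _seq_with_ankles(right, left, fps=25.0):
    T = len(right)
    pos = np.zeros((T, len(H36M_JOINTS), 3))
    pos[:, h36m_column(3), :] = right
    pos[:, h36m_column(8), :] = left
    return JointSequence3D(positions=pos, fps=fps)


class TestAnkleDistance:
    def test_coincident_ankles_give_zero(self):
        pts = np.tile([1.0, 2.0, 3.0], (5, 1))
        d = ankle_distance(_seq_with_ankles(pts, pts))
        assert (d.values == 0).all()

    def test_three_four_five_triangle(self):
        r = np.tile([3.0, 4.0, 0.0], (5, 1))
        l = np.zeros((5, 3))
        d = ankle_distance(_seq_with_ankles(r, l))
        assert np.allclose(d.values, 5.0)

    def test_rotation_invariance(self, rng):
        r = rng.normal(size=(8, 3))
        l = rng.normal(size=(8, 3))
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        d1 = ankle_distance(_seq_with_ankles(r, l))
        d2 = ankle_distance(_seq_with_ankles(r @ R.T, l @ R.T))
        assert np.allclose(d1.values, d2.values, atol=1e-9)


def _full_seq(track_fn, T, fps=25.0):
    pos = np.zeros((T, len(H36M_JOINTS), 3))
    t = np.arange(T) / fps
    for c in range(len(H36M_JOINTS)):
        pos[:, c, :] = track_fn(t, c)
    return JointSequence3D(positions=pos, fps=fps)


class TestInterpolate:
    def test_factor_one_is_identity(self, rng):
        seq = _full_seq(lambda t, c: rng.normal(size=(len(t), 3)), 6)
        out = interpolate(seq, factor=1)
        assert np.array_equal(out.positions, seq.positions)
        assert out.fps == seq.fps

    def test_linear_data_reproduced_exactly(self):
        seq = _full_seq(lambda t, c: np.outer(t, [1.0, 2.0, -0.5]) + c, 8)
        out = interpolate(seq, factor=5)
        assert out.n_frames == (8 - 1) * 5 + 1
        t_new = np.arange(out.n_frames) / out.fps
        for c in range(3):
            expected = np.outer(t_new, [1.0, 2.0, -0.5]) + c
            assert np.abs(out.positions[:, c, :] - expected).max() < 1e-9

    def test_knots_bit_exact(self, rng):
        seq = _full_seq(lambda t, c: rng.normal(size=(len(t), 3)), 10)
        out = interpolate(seq, factor=5)
        assert np.array_equal(out.positions[::5], seq.positions)

    def test_sine_against_analytic_oracle(self):
        # 1 Hz sine sampled at 25 fps: cubic-spline interpolants must track
        # the analytic curve to within the classical (h^4) error bound
        fps, f = 25.0, 1.0
        T = 51
        seq = _full_seq(
            lambda t, c: np.stack([np.sin(2 * np.pi * f * t)] * 3, axis=1), T, fps
        )
        out = interpolate(seq, factor=5)
        t_new = np.arange(out.n_frames) / out.fps
        analytic = np.sin(2 * np.pi * f * t_new)
        err = np.abs(out.positions[:, 0, 0] - analytic).max()
        # (5/384) * (2*pi*f/fps)**4 = 5.2e-5 for these settings
        assert err < 1e-4

    def test_too_short_raises(self):
        seq = _full_seq(lambda t, c: np.zeros((len(t), 3)), 3)
        with pytest.raises(ValueError, match="4 frames"):
            interpolate(seq, factor=5)


class TestSmooth:
    def test_constant_series_unchanged(self):
        d = DistanceSeries(values=np.full(50, 3.3), fps_effective=125.0)
        out = smooth(d, M=12)
        assert np.allclose(out.values, 3.3)
        assert out.provenance is Provenance.SMOOTHED

    def test_identity_filter(self, rng):
        v = np.abs(rng.normal(size=30)) + 0.1
        d = DistanceSeries(values=v, fps_effective=125.0)
        assert np.array_equal(smooth(d, M=1).values, v)

    def test_impulse_becomes_unit_plateau(self):
        M = 12
        v = np.zeros(60)
        v[30] = float(M)
        out = smooth(DistanceSeries(values=v, fps_effective=125.0), M=M)
        # hand convolution: 1/M * M over an M-sample span covering the impulse
        plateau = out.values[out.values > 0.999]
        assert len(plateau) == M
        assert np.allclose(plateau, 1.0)

    def test_output_stays_within_input_range(self, rng):
        v = np.abs(rng.normal(size=80)) + 0.5
        out = smooth(DistanceSeries(values=v, fps_effective=125.0), M=12)
        assert out.values.min() >= v.min() - 1e-12
        assert out.values.max() <= v.max() + 1e-12

    def test_shorter_than_filter_raises(self):
        d = DistanceSeries(values=np.ones(5), fps_effective=125.0)
        with pytest.raises(ValueError, match="shorter"):
            smooth(d, M=12)


class TestFindExtrema:
    def test_monotone_series_has_no_extrema(self):
        d = DistanceSeries(values=np.linspace(0.0, 1.0, 40), fps_effective=1.0)
        mx, mn = find_extrema(d, N=7)
        assert mx == [] and mn == []

    def test_single_sine_period_gives_one_of_each(self):
        n = 200
        t = np.linspace(0.0, 1.0, n, endpoint=False)
        v = 1.5 + np.sin(2 * np.pi * (t + 0.13))
        d = DistanceSeries(values=v, fps_effective=float(n))
        mx, mn = find_extrema(d, N=7)
        assert len(mx) == 1 and len(mn) == 1
        assert mx[0] == int(np.argmax(v))
        assert mn[0] == int(np.argmin(v))

    def test_even_window_rejected(self):
        d = DistanceSeries(values=np.ones(20), fps_effective=1.0)
        with pytest.raises(ValueError, match="odd"):
            find_extrema(d, N=6)

    def test_matches_brute_force_oracle_on_random_signals(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            v = random_smooth_signal(rng)
            d = DistanceSeries(values=v, fps_effective=100.0)
            got = find_extrema(d, N=7)
            exp = brute_force_extrema(v, N=7)
            # oracle has no plateau merging; merging only drops same-type
            # neighbors, which band-limited signals here do not produce
            assert got == tuple(exp)


def _cycle_pattern_series(n_max):
    """Alternating extrema: n_max maxima interleaved with n_max-1 minima."""
    n = n_max * 40
    t = np.arange(n)
    v = 1.5 + np.sin(2 * np.pi * t / 40.0 + 0.3)
    return DistanceSeries(values=v, fps_effective=40.0)


class TestSegmentCycles:
    def _seq(self, n):
        pos = np.zeros((n, len(H36M_JOINTS), 3))
        pos[:, :, 0] = np.arange(n)[:, None]
        return JointSequence3D(positions=pos, fps=40.0)

    def test_minimal_pattern_yields_one_cycle(self):
        seq = self._seq(100)
        cycles = segment_cycles(seq, maxima=[10, 50, 90], minima=[30, 70])
        assert len(cycles) == 1
        c = cycles[0]
        assert c.phase_times["ta"] == 10 and c.phase_times["td"] == 50 and c.phase_times["th"] == 90
        assert c.phase_times["tb"] == 20 and c.phase_times["te"] == 60 and c.phase_times["tg"] == 80

    @pytest.mark.parametrize("k", [1, 2, 3, 5])
    def test_interleaved_pattern_counting(self, k):
        # 2k+1 maxima with 2k interleaved minima -> k full cycles
        maxima = [20 * i for i in range(0, 2 * k + 1, 1)]
        maxima = [40 * i for i in range(2 * k + 1)]
        minima = [40 * i + 20 for i in range(2 * k)]
        cycles = segment_cycles(self._seq(40 * (2 * k + 1) + 1), maxima, minima)
        assert len(cycles) == k
        for a, b in zip(cycles, cycles[1:]):
            assert a.phase_times["th"] == b.phase_times["ta"]

    def test_fewer_than_three_maxima_yields_empty(self):
        assert segment_cycles(self._seq(50), maxima=[10, 40], minima=[25]) == []


class TestPruneExtrema:
    def test_clean_alternation_untouched(self):
        d = _cycle_pattern_series(5)
        mx, mn = find_extrema(d)
        assert prune_extrema(d, mx, mn) == (mx, mn)

    def test_shallow_wiggle_pair_removed(self):
        # hand-built structure: a true peak carrying a shallow min-max wiggle
        # (drop 0.01-0.02 vs real swings of ~1.0)
        v = np.full(600, 1.5)
        for i, val in ((100, 2.0), (110, 1.98), (120, 1.99), (200, 1.0),
                       (300, 2.0), (400, 1.0), (500, 2.0)):
            v[i] = val
        d = DistanceSeries(values=v, fps_effective=100.0)
        pm, pn = prune_extrema(d, [100, 120, 300, 500], [110, 200, 400])
        assert pm == [100, 300, 500]
        assert pn == [200, 400]


class TestPipeline:
    def test_walker_cycle_count_matches_generator(self, default_walk):
        seq, events = default_walk
        cycles = extract_cycles(seq)
        assert len(cycles) == events.n_cycles

    def test_cycle_duration_matches_stride_period(self, default_walk):
        seq, events = default_walk
        for c in extract_cycles(seq):
            dur = (c.th - c.ta) / c.source.fps
            # within one smoothed-sample spacing of the true period
            assert abs(dur - events.stride_period) <= 1.0 / c.source.fps * 12

    def test_pipeline_rigid_transform_invariance(self, default_walk):
        seq, _ = default_walk
        th = 1.1
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        )
        moved = seq.with_positions(seq.positions @ R.T + np.array([3.0, -2.0, 1.0]))
        c1 = extract_cycles(seq)
        c2 = extract_cycles(moved)
        assert len(c1) == len(c2)
        for a, b in zip(c1, c2):
            assert a.phase_times == b.phase_times


def test_gait_cycle_phase_ordering_enforced():
    pos = np.zeros((10, len(H36M_JOINTS), 3))
    pos[:, :, 0] = np.arange(10)[:, None]
    seq = JointSequence3D(positions=pos, fps=25.0)
    good = {"ta": 0, "tb": 1, "tc": 2, "td": 3, "te": 4, "tf": 5, "tg": 6, "th": 7}
    GaitCycle(source=seq, phase_times=good, cycle_index=0)
    bad = dict(good, td=1.5)
    with pytest.raises(ValueError, match="increasing"):
        GaitCycle(source=seq, phase_times=bad, cycle_index=0)
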