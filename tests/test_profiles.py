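"""Line profiles, the 5% peak rule, track metrics, cohesion time."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellcoloc import (
    FocusTrack,
    cohesion_time,
    coloc_call_timelapse,
    detect_cohesion_events,
    detect_peaks,
    family_total_distance,
    foci_pairwise_distances,
    line_profile,
    link_tracks,
    make_cell,
    simulate_cohesion_series,
    track_total_distance,
)
from cellcoloc.profiles import LineProfile
from cellcoloc.synthetic import _add_gaussian


def _profile(values):
    y = np.asarray(values, dtype=float)
    return LineProfile(1, "x", np.arange(len(y), dtype=float), y)


class TestLineProfile:
    def _cell(self):
        return make_cell(3.0, 1.0, (40, 40), np.pi / 2, image_shape=(80, 80))

    def test_uniform_intensity_all_bins_100(self):
        cell = self._cell()
        img = np.zeros((80, 80))
        img[cell.mesh.pixels[:, 0], cell.mesh.pixels[:, 1]] = 7.0
        prof = line_profile(img, cell.mesh, n_bins=10)
        assert np.allclose(prof.intensity_pct, 100.0)

    def test_spot_at_midpoint_peaks_in_middle_bin(self):
        cell = self._cell()
        img = np.full((80, 80), 10.0)
        _add_gaussian(img, cell.mesh.centroid, 500.0, 1.3)
        prof = line_profile(img, cell.mesh, n_bins=11)
        assert int(np.argmax(prof.intensity_pct)) == 5

    def test_invariant_under_positive_scaling(self):
        cell = self._cell()
        rng = np.random.default_rng(2)
        img = rng.random((80, 80)) * 100
        a = line_profile(img, cell.mesh, n_bins=15)
        b = line_profile(img * 37.5, cell.mesh, n_bins=15)
        assert np.allclose(a.intensity_pct, b.intensity_pct)

    def test_all_zero_profile_flagged_degenerate(self):
        cell = self._cell()
        prof = line_profile(np.zeros((80, 80)), cell.mesh, n_bins=10)
        assert prof.degenerate and np.all(prof.intensity_pct == 0)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            line_profile(np.zeros((80, 80)), self._cell().mesh, n_bins=2)


class TestDetectPeaks:
    def test_monotone_profile_has_no_peaks(self):
        assert detect_peaks(_profile(np.linspace(0, 100, 20))) == []

    def test_two_bumps_detected_at_spot_bins(self):
        x = np.arange(30, dtype=float)
        y = 60 * np.exp(-0.5 * ((x - 8) / 2) ** 2) + 90 * np.exp(-0.5 * ((x - 21) / 2) ** 2)
        y = y / y.max() * 100
        peaks = detect_peaks(_profile(y))
        assert sorted(p.bin_index for p in peaks) == [8, 21]

    def test_three_percent_bump_rejected_five_accepted(self):
        # prominences measured on the normalized 0-100% scale
        small = np.full(21, 97.0)
        small[10] = 100.0
        big = np.full(21, 95.0)
        big[10] = 100.0
        assert detect_peaks(_profile(small)) == []
        peaks = detect_peaks(_profile(big))
        assert len(peaks) == 1 and peaks[0].bin_index == 10

    def test_short_profile_yields_nothing(self):
        assert detect_peaks(_profile([0, 50, 100, 10])) == []

    def test_invariant_under_prenormalization_scaling(self):
        x = np.arange(25, dtype=float)
        raw = 40 + 200 * np.exp(-0.5 * ((x - 12) / 2) ** 2)
        a = detect_peaks(_profile(raw / raw.max() * 100))
        scaled = raw * 13.7
        b = detect_peaks(_profile(scaled / scaled.max() * 100))
        assert [p.bin_index for p in a] == [p.bin_index for p in b] == [12]


class TestFociPairwiseDistances:
    def test_identical_sets_all_zero(self):
        f = {1: np.array([[2.0, 3.0], [7.0, 1.0]])}
        out = foci_pairwise_distances(f, f)
        assert np.allclose(out[1], 0.0)

    def test_three_four_five(self):
        out = foci_pairwise_distances({1: np.array([[0.0, 0.0]])}, {1: np.array([[6.0, 8.0]])})
        assert out[1][0] == pytest.approx(10.0)

    def test_empty_reference_marks_absent(self):
        out = foci_pairwise_distances({1: np.array([[0.0, 0.0]])}, {1: np.empty((0, 2))})
        assert out[1] is None

    def test_summary_matches_hand_computation(self):
        # 5-cell toy table, nearest-B distance per A focus computed by hand
        a = {i: np.array([[0.0, 0.0]]) for i in range(1, 6)}
        b = {
            1: np.array([[0.0, 1.0]]),          # 1
            2: np.array([[3.0, 4.0], [0, 9]]),  # 5
            3: np.array([[0.0, 2.0]]),          # 2
            4: np.array([[6.0, 8.0]]),          # 10
            5: np.array([[0.0, 2.0], [1, 1]]),  # sqrt(2)
        }
        ds = np.concatenate([v for v in foci_pairwise_distances(a, b).values()])
        expected = np.array([1.0, 5.0, 2.0, 10.0, np.sqrt(2)])
        assert ds.mean() == pytest.approx(expected.mean())
        assert ds.std() == pytest.approx(expected.std())


class TestTrackMetrics:
    def test_toy_track_path_length(self):
        tr = FocusTrack(1, "ori", [0, 5, 10], [2.0, 1.5, 2.1])
        assert track_total_distance(tr) == pytest.approx(1.1)

    def test_stationary_track_zero(self):
        tr = FocusTrack(1, "ori", [0, 5, 10], [1.0, 1.0, 1.0])
        assert track_total_distance(tr) == 0.0

    def test_split_daughters_summed(self):
        parent = FocusTrack(1, "muk", [0, 5], [2.0, 2.0])
        d1 = FocusTrack(2, "muk", [5, 10], [2.0, 2.3], parent_id=1)
        d2 = FocusTrack(3, "muk", [5, 10], [2.0, 1.6], parent_id=1)
        assert family_total_distance([d1, d2]) == pytest.approx(0.7)

    def test_window_restriction(self):
        tr = FocusTrack(1, "ori", [0, 5, 10, 15], [0.0, 1.0, 1.0, 5.0])
        assert track_total_distance(tr, 0, 10) == pytest.approx(1.0)

    def test_single_point_window_rejected(self):
        tr = FocusTrack(1, "ori", [0, 5], [0.0, 1.0])
        with pytest.raises(ValueError):
            track_total_distance(tr, 4, 6)

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=15))
    @settings(deadline=None, max_examples=40)
    def test_path_length_bounds_net_displacement(self, xs):
        tr = FocusTrack(1, "x", np.arange(len(xs)), xs)
        path = track_total_distance(tr)
        net = abs(xs[-1] - xs[0])
        assert path >= net - 1e-9
        steps = np.diff(xs)
        if np.all(steps >= 0) or np.all(steps <= 0):
            assert path == pytest.approx(net)


class TestTimelapseColocCall:
    def test_strict_threshold(self):
        assert coloc_call_timelapse((0, 0), (0, 1.9))
        assert not coloc_call_timelapse((0, 0), (0, 2.0))
        assert coloc_call_timelapse((3, 4), (3, 4))


class TestCohesionTime:
    def test_simple_difference(self):
        assert cohesion_time(10, 28) == 18.0

    def test_same_frame_zero(self):
        assert cohesion_time(15, 15) == 0.0

    def test_out_of_order_rejected(self):
        with pytest.raises(ValueError):
            cohesion_time(30, 10)

    @pytest.mark.parametrize("lag", [10.0, 20.0, 35.0])
    def test_recovers_programmed_lag_within_frame_interval(self, lag):
        interval = 5.0
        rng = np.random.default_rng(int(lag))
        frames = simulate_cohesion_series(lag, interval, rng)
        t_app, t_split = detect_cohesion_events(frames)
        assert abs(cohesion_time(t_app, t_split) - lag) <= interval


class TestLinkTracks:
    def test_two_stable_foci_linked_into_two_tracks(self):
        frames = [np.array([1.0, 8.0]), np.array([1.2, 7.9]), np.array([1.1, 8.2])]
        tracks = link_tracks(frames, [0, 5, 10])
        assert len(tracks) == 2
        assert all(len(t.times_min) == 3 for t in tracks)

    def test_large_jump_starts_new_track(self):
        frames = [np.array([1.0]), np.array([20.0])]
        tracks = link_tracks(frames, [0, 5], max_jump_px=5.0)
        assert len(tracks) == 2
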