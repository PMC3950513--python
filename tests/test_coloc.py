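"""Distance records, cumulative curves, colocalization fractions, nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellcoloc import (
    coloc_fraction,
    compare_to_random,
    cumulative_curve,
    measured_distances,
    mesh_from_pixels,
    random_null_distances,
    random_null_focus_set,
)
from cellcoloc.coloc import DistanceRecord

PX = 129.0


def _records(distances, kind="measured"):
    """Distance list -> records; None marks an ABSENT cell."""
    return [
        DistanceRecord(i + 1, kind, d, None if d is None else d * PX)
        for i, d in enumerate(distances)
    ]


def _rect_mesh(rows, cols, cell_id=1):
    return mesh_from_pixels(cell_id, np.argwhere(np.ones((rows, cols), dtype=bool)))


class TestMeasuredDistances:
    def test_coincident_points_give_zero(self):
        recs = measured_distances({1: np.array([5.0, 5.0])}, {1: np.array([[5.0, 5.0]])}, PX)
        assert recs[0].distance_px == 0.0

    def test_nearest_reference_wins(self):
        recs = measured_distances(
            {1: np.array([0.0, 0.0])}, {1: np.array([[3.0, 4.0], [10.0, 0.0]])}, PX
        )
        assert recs[0].distance_px == pytest.approx(5.0)
        assert recs[0].distance_nm == pytest.approx(5.0 * PX)

    def test_cell_without_reference_focus_is_absent(self):
        recs = measured_distances({1: np.array([2.0, 2.0])}, {1: np.empty((0, 2))}, PX)
        assert recs[0].absent

    def test_cell_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            measured_distances({1: np.zeros(2)}, {2: np.zeros((1, 2))}, PX)


class TestRandomNullDistances:
    def test_single_pixel_mesh_always_zero(self, rng):
        mesh = _rect_mesh(1, 1)
        recs = random_null_distances([mesh], {1: np.array([[0.0, 0.0]])}, 50, rng, PX)
        assert all(r.distance_px == 0.0 for r in recs)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        # 20 x 6 mesh, one focus: exact coloc fraction by enumerating pixels
        mesh = _rect_mesh(6, 20)
        focus = np.array([[2.0, 5.0]])
        exact = np.mean(np.linalg.norm(mesh.pixels - focus[0], axis=1) <= 4.0)
        n = 10_000
        recs = random_null_distances([mesh], {1: focus}, n, np.random.default_rng(5), PX)
        mc = np.mean([r.distance_px <= 4.0 for r in recs])
        se = np.sqrt(exact * (1 - exact) / n)
        assert abs(mc - exact) < 3 * se

    def test_seeded_repeat_identical(self):
        mesh = _rect_mesh(6, 20)
        refs = {1: np.array([[3.0, 7.0]])}
        a = random_null_distances([mesh], refs, 20, np.random.default_rng(9), PX)
        b = random_null_distances([mesh], refs, 20, np.random.default_rng(9), PX)
        assert [r.distance_px for r in a] == [r.distance_px for r in b]


class TestRandomNullFocusSet:
    def test_zero_foci_absent(self, rng):
        recs = random_null_focus_set([_rect_mesh(5, 10)], {1: 0}, {1: np.zeros(2)}, 5, rng, PX)
        assert all(r.absent for r in recs)

    def test_saturated_focus_set_bounded_by_half_diagonal(self, rng):
        mesh = _rect_mesh(5, 10)
        n_px = len(mesh.pixels)
        recs = random_null_focus_set([mesh], {1: n_px * 4}, {1: np.array([2.2, 4.7])}, 30, rng, PX)
        # with ~every pixel drawn, the nearest random point is within the
        # half-diagonal of one pixel almost surely
        assert np.median([r.distance_px for r in recs]) <= np.sqrt(2) / 2 + 0.5

    def test_more_random_foci_shrink_distances(self):
        meshes = [_rect_mesh(8, 25, cell_id=i + 1) for i in range(30)]
        targets = {i + 1: np.array([3.5, 12.0]) for i in range(30)}
        med = {}
        for k in (1, 4):
            rng = np.random.default_rng(31)
            recs = random_null_focus_set(meshes, {i + 1: k for i in range(30)}, targets, 50, rng, PX)
            med[k] = np.median([r.distance_px for r in recs])
        assert med[4] <= med[1]


class TestCumulativeCurve:
    def test_three_cells_step_values(self):
        curve = cumulative_curve(_records([1.0, 2.0, 3.0]), 3)
        d, f = curve[:, 0], curve[:, 1]
        assert f[np.searchsorted(d, 2.0)] == pytest.approx(2 / 3)
        assert f[-1] == pytest.approx(1.0)

    def test_absent_cells_cap_the_asymptote(self):
        curve = cumulative_curve(_records(list(range(1, 10)) + [None]), 10)
        assert curve[-1, 1] == pytest.approx(0.9)

    def test_all_absent_gives_zero_curve(self):
        assert cumulative_curve(_records([None, None]), 2).size == 0

    def test_curve_non_decreasing(self, rng):
        recs = _records(list(rng.uniform(0, 20, size=50)))
        curve = cumulative_curve(recs, 50)
        assert np.all(np.diff(curve[:, 1]) >= 0)


class TestColocFraction:
    def test_boundary_distance_counts_with_le_rule(self):
        res = coloc_fraction(_records([3.2, 4.0, 4.1]), 3, threshold_px=4.0, pixel_size_nm=PX)
        assert res.coloc_fraction == pytest.approx(2 / 3)

    def test_threshold_converts_to_nm(self):
        res = coloc_fraction(_records([1.0]), 1, threshold_px=4.0, pixel_size_nm=PX)
        assert res.threshold_nm == pytest.approx(516.0)

    def test_zero_colocalized_wilson_lower_bound_zero(self):
        res = coloc_fraction(_records([9.0] * 20), 20, threshold_px=4.0)
        assert res.coloc_fraction == 0.0
        assert res.ci_low == 0.0

    def test_fraction_bounded_by_asymptote(self):
        res = coloc_fraction(_records([1.0, 2.0, None, None]), 4, threshold_px=4.0)
        assert res.coloc_fraction == pytest.approx(0.5)
        assert res.asymptote == pytest.approx(0.5)
        assert res.coloc_fraction <= res.asymptote

    def test_strict_rule_excludes_boundary(self):
        res = coloc_fraction(_records([1.9, 2.0]), 2, threshold_px=2.0, comparator="lt")
        assert res.coloc_fraction == pytest.approx(0.5)

    @given(st.lists(st.floats(0, 30), min_size=1, max_size=40), st.floats(0.5, 15), st.floats(0.5, 15))
    @settings(deadline=None, max_examples=40)
    def test_monotone_in_threshold(self, dists, t1, t2):
        lo, hi = sorted((t1, t2))
        recs = _records(dists)
        f_lo = coloc_fraction(recs, len(dists), threshold_px=lo).coloc_fraction
        f_hi = coloc_fraction(recs, len(dists), threshold_px=hi).coloc_fraction
        assert f_lo <= f_hi + 1e-12

    def test_pixel_size_scale_covariance(self):
        recs = _records([1.0, 3.0, 5.0])
        a = coloc_fraction(recs, 3, threshold_px=4.0, pixel_size_nm=129.0)
        b = coloc_fraction(recs, 3, threshold_px=4.0, pixel_size_nm=258.0)
        assert a.coloc_fraction == b.coloc_fraction
        assert b.threshold_nm == 2 * a.threshold_nm


class TestCompareToRandom:
    def test_identical_fractions_not_significant(self):
        m = coloc_fraction(_records([1.0, 9.0]), 2, threshold_px=4.0)
        r = coloc_fraction(_records([1.0, 9.0], kind="random"), 2, threshold_px=4.0)
        p, flag = compare_to_random(m, r)
        assert p == pytest.approx(1.0)
        assert not flag

    def test_separated_proportions_significant(self):
        # 150/200 vs 70/200: pooled p = 0.55,
        # se = sqrt(0.55*0.45*(2/200)) = 0.0497, z = 0.40/0.0497 = 8.04
        m = coloc_fraction(_records([1.0] * 150 + [9.0] * 50), 200, threshold_px=4.0)
        r = coloc_fraction(_records([1.0] * 70 + [9.0] * 130, kind="random"), 200, threshold_px=4.0)
        p, flag = compare_to_random(m, r)
        assert p < 1e-14
        assert flag

    def test_flag_requires_disjoint_intervals(self):
        m = coloc_fraction(_records([1.0] * 150 + [9.0] * 50), 200, threshold_px=4.0)
        r = coloc_fraction(_records([1.0] * 70 + [9.0] * 130, kind="random"), 200, threshold_px=4.0)
        # measured CI ~ [0.69, 0.80], random CI ~ [0.29, 0.42]: disjoint
        assert m.ci_low > r.ci_high

    def test_zero_cells_rejected(self):
        m = coloc_fraction(_records([1.0]), 1, threshold_px=4.0)
        import dataclasses

        broken = dataclasses.replace(m, n_cells=0)
        with pytest.raises(ValueError):
            compare_to_random(broken, m)
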