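"""Convex-hull occupation, overlap, subset ratios, accumulation curves."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from larvamorph import (
    accumulation_curve,
    group_occupation,
    hull_area,
    hull_overlap,
    saturation_slope,
    subset_comparison,
)
from larvamorph.occupation import AccumulationCurve, GroupOccupation, hull_vertices

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def occupation_of(points, name="g"):
    return GroupOccupation(
        group=name,
        hull_vertices=hull_vertices(points),
        area=hull_area(points),
        n=len(points),
    )


class TestHullArea:
    def test_unit_square(self):
        assert hull_area(SQUARE) == pytest.approx(1.0)

    def test_collinear_is_zero(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        assert hull_area(pts) == 0.0
        assert hull_area(SQUARE[:2]) == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            hull_area(np.array([[0.0, 0.0], [np.nan, 1.0], [1.0, 1.0]]))

    def test_matches_monte_carlo_rejection_oracle(self):
        """Shoelace hull area vs a rejection-sampling estimate (1e6 darts
        into the bounding box) on points in the unit disc: within 2%."""
        rng = np.random.default_rng(123)
        th = rng.uniform(0, 2 * np.pi, 200)
        r = np.sqrt(rng.uniform(0, 1, 200))
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        area = hull_area(pts)

        verts = hull_vertices(pts)
        lo, hi = pts.min(0), pts.max(0)
        darts = rng.uniform(lo, hi, size=(1_000_000, 2))
        # point-in-convex-polygon: all cross products non-negative (CCW)
        edges = np.roll(verts, -1, axis=0) - verts
        rel = darts[:, None, :] - verts[None, :, :]
        cross = edges[None, :, 0] * rel[:, :, 1] - edges[None, :, 1] * rel[:, :, 0]
        inside = np.all(cross >= 0, axis=1)
        mc = inside.mean() * np.prod(hi - lo)
        assert area == pytest.approx(mc, rel=0.02)

    @given(seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_adding_a_point_never_shrinks_the_hull(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(12, 2))
        base = hull_area(pts[:-1])
        assert hull_area(pts) >= base - 1e-12


class TestGroupOccupation:
    def test_one_group_per_label_and_containment(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(30, 4))
        labels = ["A"] * 18 + ["B"] * 12
        occs = group_occupation(scores, labels)
        assert [o.group for o in occs] == ["A", "B"]
        assert occs[0].n == 18 and occs[1].n == 12
        a_pts = scores[:18, :2]
        assert occs[0].contains(a_pts).all()

    def test_two_point_group_flagged_degenerate(self):
        scores = np.vstack([np.random.default_rng(1).normal(size=(5, 2)),
                            [[0, 0], [1, 1]]])
        occs = group_occupation(scores, ["A"] * 5 + ["B"] * 2)
        b = occs[1]
        assert b.area == 0.0 and b.n == 2 and b.degenerate

    def test_label_length_mismatch(self):
        with pytest.raises(ValueError):
            group_occupation(np.zeros((4, 2)), ["A"] * 3)


class TestOverlap:
    def test_identity_and_bounds(self):
        rng = np.random.default_rng(2)
        a = occupation_of(rng.normal(size=(20, 2)))
        b = occupation_of(rng.normal(size=(20, 2)) + 0.5)
        assert hull_overlap(a, a) == pytest.approx(a.area, rel=1e-9)
        ov = hull_overlap(a, b)
        assert 0.0 <= ov <= min(a.area, b.area) + 1e-12

    def test_disjoint_hulls(self):
        a = occupation_of(SQUARE)
        b = occupation_of(SQUARE + 10.0)
        assert hull_overlap(a, b) == 0.0

    def test_half_shifted_square(self):
        a = occupation_of(SQUARE)
        b = occupation_of(SQUARE + [0.5, 0.0])
        assert hull_overlap(a, b) == pytest.approx(0.5, abs=1e-12)

    def test_nested_hull_overlap_equals_inner_area(self):
        """A hull entirely inside another overlaps by exactly its own
        area (the configuration reported for Eocene-inside-modern)."""
        outer = occupation_of(SQUARE * 10.0)
        inner = occupation_of(SQUARE + 3.0)
        assert hull_overlap(inner, outer) == pytest.approx(inner.area, rel=1e-12)


class TestSubsetComparison:
    def test_full_subset_ratio_one(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=(15, 2))
        ids = [f"s{i}" for i in range(15)]
        a_sub, a_full, ratio = subset_comparison(scores, ids, ids)
        assert ratio == pytest.approx(1.0)
        assert a_sub == pytest.approx(a_full)

    def test_interior_subset_ratio_below_one(self):
        pts = np.vstack([SQUARE * 4, SQUARE * 0.5 + 1.0])
        ids = [f"c{i}" for i in range(4)] + [f"i{i}" for i in range(4)]
        _, _, ratio = subset_comparison(pts, [f"i{i}" for i in range(4)], ids)
        assert 0.0 < ratio < 1.0

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            subset_comparison(np.zeros((3, 2)), ["nope"], ["a", "b", "c"])

    def test_ratio_rises_with_subset_fraction(self):
        """Random halves of one distribution: expected subset/full area
        ratio increases with the subset fraction."""
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(80, 2))
        ids = [f"s{i}" for i in range(80)]
        means = []
        for frac in (0.25, 0.5, 0.75):
            ratios = []
            for rep in range(30):
                sub = rng.choice(ids, size=int(frac * 80), replace=False)
                ratios.append(subset_comparison(pts, list(sub), ids)[2])
            means.append(np.mean(ratios))
        assert means[0] < means[1] < means[2] < 1.0


class TestAccumulation:
    def test_exact_at_full_sample_and_deterministic(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(25, 2))
        c1 = accumulation_curve(pts, n_resamples=40, seed=9)
        c2 = accumulation_curve(pts, n_resamples=40, seed=9)
        assert np.array_equal(c1.mean_area, c2.mean_area)
        assert c1.mean_area[-1] == pytest.approx(hull_area(pts), abs=0)
        assert c1.ci_high[-1] - c1.ci_low[-1] == 0.0

    def test_mean_area_nondecreasing(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(30, 2))
        c = accumulation_curve(pts, n_resamples=200, seed=1)
        # non-decreasing up to resampling noise on the means
        assert np.all(np.diff(c.mean_area) > -1e-3 * c.mean_area[-1])

    def test_parameter_validation(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError):
            accumulation_curve(rng.normal(size=(2, 2)))
        with pytest.raises(ValueError):
            accumulation_curve(rng.normal(size=(10, 2)), n_resamples=0)

    def test_bounded_uniform_saturates(self):
        """200 points from a bounded square: the accumulation tail is
        nearly flat (relative slope < 0.01)."""
        rng = np.random.default_rng(8)
        pts = rng.uniform(size=(200, 2))
        c = accumulation_curve(pts, n_resamples=50, seed=0)
        assert saturation_slope(c) < 0.01


class TestSaturationSlope:
    def test_flat_curve_zero(self):
        c = AccumulationCurve(
            k=np.arange(1, 11), mean_area=np.full(10, 2.0),
            ci_low=np.full(10, 2.0), ci_high=np.full(10, 2.0),
            n_resamples=1, seed=0, full_area=2.0,
        )
        assert saturation_slope(c) == pytest.approx(0.0, abs=1e-15)

    def test_linear_curve_normalized_slope(self):
        """mean_area = k on k=1..10 with 20% tail: slope 1 normalized by
        the final area 10 gives 0.1."""
        k = np.arange(1, 11)
        c = AccumulationCurve(
            k=k, mean_area=k.astype(float), ci_low=k.astype(float),
            ci_high=k.astype(float), n_resamples=1, seed=0, full_area=10.0,
        )
        assert saturation_slope(c, 0.2) == pytest.approx(0.1)

    def test_heavy_tailed_slope_exceeds_uniform(self):
        """Paired over seeds at n=60: 2-D t(df=2) scores flatten more
        slowly than bounded-uniform scores."""
        wins = 0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            u = accumulation_curve(
                rng.uniform(size=(60, 2)), n_resamples=30, seed=seed
            )
            t = accumulation_curve(
                rng.standard_t(2, size=(60, 2)), n_resamples=30, seed=seed
            )
            wins += saturation_slope(t) > saturation_slope(u)
        assert wins >= 11

    def test_short_tail_rejected(self):
        c = AccumulationCurve(
            k=np.arange(1, 6), mean_area=np.ones(5), ci_low=np.ones(5),
            ci_high=np.ones(5), n_resamples=1, seed=0, full_area=1.0,
        )
        with pytest.raises(ValueError):
            saturation_slope(c, tail_fraction=0.05)
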