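import numpy as np
import pytest

from precurve import (
    ConfusionSeries,
    InterpolationSegment,
    ScoredDataset,
    ValidationError,
    confusion_series,
    dg_interpolate,
    interpolate_to_grid,
    pr_points,
    roc_points,
    roc_to_pr_point,
    support_grid,
    trapezoid_auc,
)
from precurve.testkit import brute_force_series, oracle_pr_auc

from conftest import random_scored_arrays


def fractional_precision(tpA, fpA, tpB, fpB, x):
    """Independent oracle: add x true positives and s*x false positives to the
    2x2 table, recompute precision directly."""
    s = (fpB - fpA) / (tpB - tpA)
    tp = tpA + x
    fp = fpA + s * x
    return tp / (tp + fp)


class TestSupportGrid:
    def test_spacing_half_at_two_bins(self):
        g = support_grid(2)
        assert g.xs.tolist() == [0.0, 0.5, 1.0]

    def test_spacing_one_thousandth_at_default(self):
        g = support_grid()
        assert g.x_bins == 1000
        assert g.xs.size == 1001
        assert np.abs(np.diff(g.xs) - 0.001).max() < 1e-15

    def test_single_bin_is_endpoints_only(self):
        assert support_grid(1).xs.tolist() == [0.0, 1.0]

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            support_grid(0)


class TestDgInterpolate:
    SEG = InterpolationSegment(tpA=1, fpA=0, tpB=2, fpB=2, P=2)

    def test_fractional_count_oracle_at_midpoint(self):
        r, p = dg_interpolate(self.SEG, 0.5)
        assert r == pytest.approx(0.75)
        assert p == pytest.approx(fractional_precision(1, 0, 2, 2, 0.5))  # 0.6
        assert p == pytest.approx(0.6)

    def test_identity_at_segment_endpoints(self):
        r0, p0 = dg_interpolate(self.SEG, 0.0)
        assert (r0, p0) == (0.5, 1.0)
        r1, p1 = dg_interpolate(self.SEG, 1.0)
        assert r1 == 1.0 and p1 == pytest.approx(0.5)

    def test_vertical_segment_is_rejected(self):
        with pytest.raises(ValidationError):
            dg_interpolate(InterpolationSegment(1, 0, 1, 2, P=2), 0.0)


class TestRocPoints:
    def test_direct_ratios_with_anchors(self):
        cs = ConfusionSeries(np.array([3.0, 2.0, 1.0]), [1, 1, 2], [0, 1, 1], P=2, N=1)
        pts = roc_points(cs)
        assert pts.raw_x.tolist() == [0.0, 0.0, 1.0, 1.0]
        assert pts.raw_y.tolist() == [0.0, 0.5, 0.5, 1.0]

    def test_perfect_classifier_hugs_the_corner(self):
        cs = ConfusionSeries(np.array([2.0, 1.0]), [2, 2], [0, 3], P=2, N=3)
        pts = roc_points(cs)
        assert pts.raw_x.tolist() == [0.0, 0.0, 1.0]
        assert pts.raw_y.tolist() == [0.0, 1.0, 1.0]

    def test_matches_brute_force_rates(self, rng):
        for _ in range(25):
            scores, labels = random_scored_arrays(rng, max_n=60, heavy_ties=True)
            ds = ScoredDataset(scores, labels)
            pts = roc_points(confusion_series(ds))
            _, tp, fp = brute_force_series(scores, labels)
            np.testing.assert_allclose(pts.raw_x[1:], fp / ds.n_neg, atol=1e-15)
            np.testing.assert_allclose(pts.raw_y[1:], tp / ds.n_pos, atol=1e-15)


class TestPrPoints:
    def test_top_ranked_positive_forces_first_precision_one(self):
        # P=1: the single positive is recovered at the first threshold, so the
        # curve jumps straight to recall 1 and the first point carries precision 1
        ds = ScoredDataset(np.array([0.9, 0.8]), np.array([True, False]))
        pts = pr_points(confusion_series(ds))
        assert pts.raw_x.tolist() == [0.0, 1.0, 1.0]
        assert pts.raw_y.tolist() == [1.0, 1.0, 0.5]

    def test_first_point_precision_with_two_positives(self):
        # the spec'd shape (0,1),(0.5,1),(1,...) needs two positives
        ds = ScoredDataset(np.array([0.9, 0.8, 0.7]), np.array([True, True, False]))
        pts = pr_points(confusion_series(ds))
        assert pts.raw_x.tolist() == [0.0, 0.5, 1.0, 1.0]
        assert pts.raw_y.tolist() == [1.0, 1.0, 1.0, pytest.approx(2 / 3)]

    def test_leading_false_positive_forces_first_precision_zero(self):
        ds = ScoredDataset(np.array([0.9, 0.8]), np.array([False, True]))
        pts = pr_points(confusion_series(ds))
        assert pts.raw_x[0] == 0.0 and pts.raw_y[0] == 0.0
        assert pts.raw_x[-1] == 1.0 and pts.raw_y[-1] == 0.5

    def test_tied_first_block_uses_block_ratio_as_limit(self):
        # one pos and one neg tied at the top: limit is 1/2, not 1
        ds = ScoredDataset(np.array([0.9, 0.9, 0.1]), np.array([True, False, False]))
        pts = pr_points(confusion_series(ds))
        assert pts.raw_y[0] == pytest.approx(0.5)

    def test_matches_brute_force_tables(self, rng):
        for _ in range(25):
            scores, labels = random_scored_arrays(rng, max_n=40, heavy_ties=True)
            ds = ScoredDataset(scores, labels)
            pts = pr_points(confusion_series(ds))
            _, tp, fp = brute_force_series(scores, labels)
            for t, f in zip(tp, fp):
                r, p = t / ds.n_pos, t / (t + f)
                i = np.flatnonzero(np.isclose(pts.raw_x, r) & np.isclose(pts.raw_y, p))
                assert i.size >= 1, f"missing raw PR point ({r}, {p})"


class TestGridding:
    def test_linear_identity_on_the_diagonal(self):
        cs = ConfusionSeries(np.array([1.0]), [2], [2], P=2, N=2)
        pts = interpolate_to_grid(roc_points(cs), support_grid(2))
        assert pts.grid_y.tolist() == [0.0, 0.5, 1.0]

    def test_nonlinear_pr_value_at_grid_point(self):
        # same segment as the dg_interpolate example, reached through the full path
        cs = ConfusionSeries(np.array([2.0, 1.0]), [1, 2], [0, 2], P=2, N=2)
        pts = interpolate_to_grid(pr_points(cs), support_grid(4))
        assert pts.grid_x[3] == 0.75
        assert pts.grid_y[3] == pytest.approx(fractional_precision(1, 0, 2, 2, 0.5))

    def test_interpolation_passes_through_knots(self, rng):
        """With x_bins equal to the class count every raw knot lies exactly on
        the grid; the gridded value there is the right-hand (last) raw y."""
        for _ in range(10):
            scores, labels = random_scored_arrays(rng, max_n=20, heavy_ties=True)
            ds = ScoredDataset(scores, labels)
            cs = confusion_series(ds)
            for build, bins in ((roc_points, ds.n_neg), (pr_points, ds.n_pos)):
                if bins < 2:
                    continue  # x_bins=1 switches PR to its linear mode
                pts = interpolate_to_grid(build(cs), support_grid(bins))
                for x in np.unique(pts.raw_x):
                    idx = np.flatnonzero(pts.grid_x == x)
                    assert idx.size == 1, f"knot x={x} not on grid"
                    last_at_x = pts.raw_y[pts.raw_x == x][-1]
                    assert pts.grid_y[idx[0]] == pytest.approx(last_at_x, abs=1e-12)

    def test_single_bin_pr_uses_linear_interpolation(self):
        cs = ConfusionSeries(np.array([2.0, 1.0]), [1, 2], [0, 2], P=2, N=2)
        pts = interpolate_to_grid(pr_points(cs), support_grid(1))
        # linear AUC over raw chords, not the non-linear value
        raw_lin = np.trapezoid(pts.raw_y, pts.raw_x)
        assert pts.auc == pytest.approx(float(raw_lin), abs=1e-12)


class TestTrapezoidAuc:
    def test_perfect_classifier_fills_the_unit_square(self):
        cs = ConfusionSeries(np.array([2.0, 1.0]), [2, 2], [0, 3], P=2, N=3)
        pts = interpolate_to_grid(roc_points(cs), support_grid(10))
        assert pts.auc == pytest.approx(1.0, abs=1e-12)

    def test_all_tied_scores_give_the_chance_diagonal(self):
        ds = ScoredDataset(np.full(6, 0.5), np.arange(6) % 2 == 0)
        pts = interpolate_to_grid(roc_points(confusion_series(ds)), support_grid(10))
        assert pts.auc == pytest.approx(0.5, abs=1e-12)

    def test_grid_only_mode_close_to_grid_plus_knots(self, rng):
        scores, labels = random_scored_arrays(rng, max_n=100)
        pts = interpolate_to_grid(
            pr_points(confusion_series(ScoredDataset(scores, labels))), support_grid(1000)
        )
        assert trapezoid_auc(pts, include_knots=False) == pytest.approx(pts.auc, abs=5e-3)

    def test_monotone_refinement_of_pr_auc(self, rng):
        """|AUC(2k) - AUC(k)| shrinks as the support grid is refined."""
        scores, labels = random_scored_arrays(rng, max_n=60, heavy_ties=True)
        raw = pr_points(confusion_series(ScoredDataset(scores, labels)))
        auc = {k: interpolate_to_grid(raw, support_grid(k)).auc for k in (5, 10, 80, 160)}
        assert abs(auc[160] - auc[80]) <= abs(auc[10] - auc[5]) + 1e-12

    def test_linear_vs_nonlinear_gap_bounded_by_segment_spans(self, rng):
        """The linear/non-linear AUC gap cannot exceed the summed
        width x precision-span of the segments (both lie between the chord
        and the endpoint envelope)."""
        for _ in range(10):
            scores, labels = random_scored_arrays(rng, max_n=30, heavy_ties=True)
            raw = pr_points(confusion_series(ScoredDataset(scores, labels)))
            nonlinear = interpolate_to_grid(raw, support_grid(1000)).auc
            linear = float(np.trapezoid(raw.raw_y, raw.raw_x))
            bound = float(
                np.sum(np.abs(np.diff(raw.raw_x)) * np.abs(np.diff(raw.raw_y)))
            )
            assert abs(nonlinear - linear) <= bound + 1e-9


class TestRocToPr:
    @pytest.mark.parametrize(
        "fpr, tpr, P, N, expected",
        [
            (0.0, 1.0, 5, 5, (1.0, 1.0)),
            (1.0, 1.0, 10, 90, (1.0, 0.1)),
            (0.5, 0.5, 7, 7, (0.5, 0.5)),
        ],
    )
    def test_known_correspondences(self, fpr, tpr, P, N, expected):
        r, p = roc_to_pr_point(fpr, tpr, P, N)
        assert (r, p) == pytest.approx(expected)

    def test_origin_is_undefined(self):
        with pytest.raises(ValidationError, match="undefined"):
            roc_to_pr_point(0.0, 0.0, 5, 5)

    def test_round_trip_from_shared_confusion_series(self, rng):
        for _ in range(25):
            scores, labels = random_scored_arrays(rng, max_n=60, heavy_ties=True)
            ds = ScoredDataset(scores, labels)
            cs = confusion_series(ds)
            r, p = roc_to_pr_point(cs.fp / ds.n_neg, cs.tp / ds.n_pos, ds.n_pos, ds.n_neg)
            np.testing.assert_allclose(r, cs.tp / ds.n_pos, atol=1e-12)
            np.testing.assert_allclose(p, cs.tp / (cs.tp + cs.fp), atol=1e-12)


def test_gridded_pr_auc_tracks_subdivision_oracle(rng):
    for _ in range(10):
        scores, labels = random_scored_arrays(rng, max_n=100)
        cs = confusion_series(ScoredDataset(scores, labels))
        pts = interpolate_to_grid(pr_points(cs), support_grid(1000))
        assert pts.auc == pytest.approx(oracle_pr_auc(cs, 10000), abs=1e-3)
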