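import numpy as np
import pytest

from rcspt.geometry import PolygonRegion, square
from rcspt.simulate import simulate_point_pattern
from rcspt.spatial import (
    PointPattern,
    csr_envelope,
    edge_corrected_density,
    inside_arc_fraction,
    pair_weights,
    ripley_l_curve,
    subsample_detections,
)


def arc_fraction_numeric(region, center, rho, n0=720, iters=60):
    """Independent oracle: angular scan with bisection-refined crossings."""
    ang = np.linspace(0, 2 * np.pi, n0, endpoint=False)
    inside = region.contains(
        center[0] + rho * np.cos(ang), center[1] + rho * np.sin(ang)
    )
    total = 0.0
    step = 2 * np.pi / n0
    for i in range(n0):
        a0 = ang[i]
        s0, s1 = inside[i], inside[(i + 1) % n0]
        if s0 and s1:
            total += step
        elif s0 != s1:
            lo, hi = a0, a0 + step
            for _ in range(iters):
                mid = (lo + hi) / 2
                m_in = region.contains_point(
                    center[0] + rho * np.cos(mid), center[1] + rho * np.sin(mid)
                )
                if m_in == s0:
                    lo = mid
                else:
                    hi = mid
            total += (lo - a0) if s0 else (a0 + step - hi)
    return total / (2 * np.pi)


class TestEdgeCorrection:
    def test_pair_deep_inside_has_unit_weight(self, big_square):
        pts = np.array([[4.0, 5.0], [5.0, 5.0]])  # 1 µm apart, far from edges
        pattern = PointPattern(pts, big_square)
        assert edge_corrected_density(pattern, 2.0) == pytest.approx(1.0)

    def test_radius_below_separation_counts_nothing(self, big_square):
        pts = np.array([[4.0, 5.0], [5.0, 5.0]])
        assert edge_corrected_density(PointPattern(pts, big_square), 0.5) == 0.0

    def test_analytic_arclength_matches_numeric_oracle(self, big_square):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0.2, 2.0, 10), rng.uniform(0.2, 2.0, 10)])
        pattern = PointPattern(pts, big_square)
        d, w = pair_weights(pattern, 3.0)
        # recompute every pair weight with the numeric oracle
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        pairs = tree.query_pairs(3.0, output_type="ndarray")
        i_idx = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j_idx = np.concatenate([pairs[:, 1], pairs[:, 0]])
        for i, j, dist, weight in zip(i_idx, j_idx, d, w):
            frac = arc_fraction_numeric(big_square, pts[i], dist)
            assert weight == pytest.approx(1.0 / frac, rel=1e-6)

    def test_arc_fraction_half_on_straight_edge(self, big_square):
        # circle centred on the boundary of a huge square: half inside
        assert inside_arc_fraction(
            big_square, np.array([5.0, 0.0]), 0.5
        ) == pytest.approx(0.5, abs=1e-12)


class TestRipleyCurve:
    radii = np.linspace(0.05, 1.0, 12)

    def test_csr_mean_curve_near_zero(self, big_square):
        curves = []
        for s in range(30):
            pts = simulate_point_pattern(big_square, "csr", n_points=500, seed=s)
            curves.append(ripley_l_curve(PointPattern(pts, big_square), self.radii).l_minus_r)
        curves = np.asarray(curves)
        mean = curves.mean(axis=0)
        sem = curves.std(axis=0, ddof=1) / np.sqrt(len(curves))
        assert (np.abs(mean) <= 4 * sem + 1e-3).all()

    def test_tight_cluster_is_positive_at_cluster_scale(self, big_square):
        pts = simulate_point_pattern(
            big_square, "cluster",
            cluster={"n_parents": 1, "offspring_per_parent": 200, "sigma": 0.1},
            seed=3,
        )
        curve = ripley_l_curve(PointPattern(pts, big_square), self.radii)
        assert curve.l_minus_r[2] > 0.5  # r ~ 0.22 um >> CSR

    def test_regular_lattice_is_negative_below_spacing(self):
        # 25-point lattice, spacing 1: repulsion at sub-spacing radii
        g = np.arange(5) + 0.5
        pts = np.array([(x, y) for x in g for y in g], dtype=float)
        region = square(5.0)
        curve = ripley_l_curve(PointPattern(pts, region), np.array([0.4, 0.8]))
        assert curve.l_minus_r[0] < 0
        # brute-force N(r) at r = 0.8: each point has >= 2 neighbours at d = 1? no:
        # spacing 1 > 0.8, so no pairs at all at r = 0.4 and 0.8
        assert curve.n_r[0] == 0.0

    def test_invariant_under_rigid_motion(self, big_square):
        pts = simulate_point_pattern(big_square, "csr", n_points=300, seed=4)
        base = ripley_l_curve(PointPattern(pts, big_square), self.radii).l_minus_r
        a = 0.3
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        moved_pts = pts @ R.T + np.array([20.0, -7.0])
        moved_region = PolygonRegion(big_square.vertices @ R.T + np.array([20.0, -7.0]))
        moved = ripley_l_curve(PointPattern(moved_pts, moved_region), self.radii).l_minus_r
        np.testing.assert_allclose(moved, base, atol=1e-9)

    def test_edge_correction_beats_uncorrected_near_boundaries(self):
        """On CSR in a small square the corrected estimator is ~unbiased where
        the naive (weight = 1) estimator is badly biased downward."""
        region = square(2.0)
        radii = np.array([0.5, 0.8])
        corr, uncorr = [], []
        for s in range(40):
            pts = simulate_point_pattern(region, "csr", n_points=150, seed=100 + s)
            pattern = PointPattern(pts, region)
            curve = ripley_l_curve(pattern, radii)
            corr.append(curve.l_minus_r)
            d, _ = pair_weights(pattern, radii[-1])
            n_naive = np.array([(d <= r).sum() / pattern.n_points for r in radii])
            uncorr.append(np.sqrt(n_naive / pattern.intensity / np.pi) - radii)
        bias_corr = np.abs(np.mean(corr, axis=0))
        bias_uncorr = np.abs(np.mean(uncorr, axis=0))
        assert (bias_corr * 5 < bias_uncorr).all()


class TestEnvelopeAndSubsampling:
    radii = np.linspace(0.1, 1.0, 8)

    def test_envelope_contains_zero(self, big_square):
        env = csr_envelope(big_square, 400, self.radii, n_sims=40, seed=0)
        assert (env["lo"] <= 0).all() and (env["hi"] >= 0).all()

    def test_band_shrinks_with_point_count(self, big_square):
        e100 = csr_envelope(big_square, 100, self.radii, n_sims=40, seed=1)
        e1000 = csr_envelope(big_square, 1000, self.radii, n_sims=40, seed=1)
        assert (e1000["hi"] - e1000["lo"]).mean() < (e100["hi"] - e100["lo"]).mean()

    def test_envelope_deterministic_given_seed(self, big_square):
        a = csr_envelope(big_square, 200, self.radii, n_sims=20, seed=2)
        b = csr_envelope(big_square, 200, self.radii, n_sims=20, seed=2)
        np.testing.assert_array_equal(a["lo"], b["lo"])
        np.testing.assert_array_equal(a["hi"], b["hi"])

    def test_small_pattern_subsamples_are_degenerate(self, big_square):
        pts = simulate_point_pattern(big_square, "csr", n_points=300, seed=5)
        curve = subsample_detections(
            PointPattern(pts, big_square), self.radii, n_points=25000,
            n_draws=5, seed=0,
        )
        np.testing.assert_allclose(curve.sd, 0.0, atol=1e-12)

    def test_subsample_mean_consistent_with_full_curve(self, big_square):
        pts = simulate_point_pattern(
            big_square, "cluster",
            cluster={"n_parents": 30, "offspring_per_parent": 40, "sigma": 0.2},
            seed=6,
        )
        pattern = PointPattern(pts, big_square)
        full = ripley_l_curve(pattern, self.radii)
        sub = subsample_detections(pattern, self.radii, n_points=600, n_draws=30, seed=1)
        sd = np.maximum(sub.sd, 1e-3)
        assert (np.abs(sub.l_minus_r - full.l_minus_r) <= 2.5 * sd).all()

    def test_subsampling_deterministic(self, big_square):
        pts = simulate_point_pattern(big_square, "csr", n_points=400, seed=7)
        pattern = PointPattern(pts, big_square)
        a = subsample_detections(pattern, self.radii, n_points=200, n_draws=10, seed=3)
        b = subsample_detections(pattern, self.radii, n_points=200, n_draws=10, seed=3)
        np.testing.assert_array_equal(a.l_minus_r, b.l_minus_r)


class TestPointPatternValidation:
    def test_points_outside_region_rejected(self, unit_square):
        with pytest.raises(ValueError, match="outside"):
            PointPattern(np.array([[0.5, 0.5], [2.0, 0.5]]), unit_square)

    def test_intensity_is_count_over_area(self, big_square):
        pts = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        assert PointPattern(pts, big_square).intensity == pytest.approx(4 / 100)
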