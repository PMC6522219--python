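import itertools

import numpy as np
import pandas as pd
import pytest

from rcspt.geometry import regular_polygon, square
from rcspt.io import CellAnnotation
from rcspt.simulate import SpaSptSimConfig, simulate_spaspt
from rcspt.tracking import (
    LinkingConfig,
    PlacementError,
    assign_compartments,
    boundary_crossing_jumps,
    interpolate_annotation,
    link_localizations,
    place_mock_compartments,
)
from tests.conftest import make_trajectory


def locs(rows):
    return pd.DataFrame(rows, columns=["x", "y", "frame"])


class TestLinking:
    cfg = LinkingConfig(d_max=10.0, gap_frames=1, frame_interval=0.007447)

    def test_two_nearby_localizations_link(self):
        trajs = link_localizations(locs([(0, 0, 0), (0.1, 0, 1)]), self.cfg)
        assert len(trajs) == 1 and len(trajs[0]) == 2

    def test_gap_of_one_frame_is_bridged(self):
        r2 = self.cfg.r_max(2)
        trajs = link_localizations(locs([(0, 0, 0), (r2 * 0.9, 0, 2)]), self.cfg)
        assert len(trajs) == 1
        np.testing.assert_array_equal(trajs[0].frames, [0, 2])

    def test_gap_beyond_budget_not_bridged(self):
        trajs = link_localizations(locs([(0, 0, 0), (0.01, 0, 3)]), self.cfg)
        assert len(trajs) == 2

    def test_matches_minimal_assignment_on_two_by_two_instance(self):
        # two particles in frame 0, two candidates in frame 1
        p0 = [(0.0, 0.0), (0.5, 0.0)]
        p1 = [(0.1, 0.0), (0.45, 0.1)]
        table = locs([(x, y, 0) for x, y in p0] + [(x, y, 1) for x, y in p1])
        trajs = link_localizations(table, self.cfg)
        got = {
            (tuple(t.xy[0]), tuple(t.xy[1])) for t in trajs if len(t) == 2
        }
        # brute force: the assignment minimizing total distance
        best = min(
            itertools.permutations(range(2)),
            key=lambda perm: sum(
                np.hypot(p0[i][0] - p1[perm[i]][0], p0[i][1] - p1[perm[i]][1])
                for i in range(2)
            ),
        )
        want = {(p0[i], p1[best[i]]) for i in range(2)}
        assert got == want

    def test_too_many_competitors_terminates_trajectory(self):
        cfg = LinkingConfig(d_max=10.0, gap_frames=0, max_competitors=3,
                            frame_interval=0.007447)
        rows = [(0, 0, 0)] + [(0.01 * k, 0.01, 1) for k in range(4)]
        trajs = link_localizations(locs(rows), cfg)
        lengths = sorted(len(t) for t in trajs)
        assert lengths == [1, 1, 1, 1, 1]  # ambiguous: nothing linked

    def test_never_links_beyond_search_radius(self):
        rng = np.random.default_rng(0)
        rows = [
            (x, y, f)
            for f in range(15)
            for x, y in rng.uniform(0, 3, size=(20, 2))
        ]
        trajs = link_localizations(locs(rows), self.cfg)
        for t in trajs:
            d = np.linalg.norm(np.diff(t.xy, axis=0), axis=1)
            k = np.diff(t.frames)
            assert (d <= np.array([self.cfg.r_max(int(g)) for g in k]) + 1e-12).all()

    def test_duplicate_rows_warn_but_are_kept(self):
        with pytest.warns(UserWarning, match="duplicate"):
            trajs = link_localizations(
                locs([(0, 0, 0), (0, 0, 0), (5, 5, 0)]), self.cfg
            )
        assert sum(len(t) for t in trajs) == 3


class TestAnnotationInterpolation:
    def _drifting(self):
        before = square(2.0)
        after = square(2.0, 1.0, 0.0)  # translated by (1, 0) µm
        return CellAnnotation(
            cell_id="c",
            nucleus_before=square(10.0, -4, -4),
            nucleus_after=square(10.0, -3, -4),
            compartments_before=[before],
            compartments_after=[after],
            n_frames=11,
        )

    def test_endpoints_are_exact(self):
        ann = self._drifting()
        first = interpolate_annotation(ann, 0)["compartments"][0]
        last = interpolate_annotation(ann, 10)["compartments"][0]
        np.testing.assert_allclose(first.vertices, square(2.0).vertices)
        np.testing.assert_allclose(last.vertices, square(2.0, 1.0, 0.0).vertices)

    def test_midpoint_is_half_translated(self):
        mid = interpolate_annotation(self._drifting(), 5)["compartments"][0]
        np.testing.assert_allclose(mid.vertices, square(2.0, 0.5, 0.0).vertices)

    @pytest.mark.parametrize("frame", [2, 7])
    def test_linear_in_frame(self, frame):
        ann = self._drifting()
        poly = interpolate_annotation(ann, frame)["compartments"][0]
        np.testing.assert_allclose(
            poly.vertices, square(2.0, frame / 10, 0.0).vertices
        )

    def test_out_of_range_frame_rejected(self):
        with pytest.raises(ValueError):
            interpolate_annotation(self._drifting(), 11)


class TestAssignCompartments:
    def test_single_localization_inside_labels_trajectory_inside(self, annotation):
        xy = [(-3, -3), (-3.2, -3), (1.0, 0.0), (-3, -2.8), (-2.9, -3)]
        t = make_trajectory("t", range(5), xy, cell_id="cell0")
        [lt] = assign_compartments([t], annotation)
        assert lt.label == "inside"
        assert lt.inside_flags.sum() == 1

    def test_fully_outside_trajectory_labeled_outside(self, annotation):
        t = make_trajectory("t", range(3), [(-3, -3), (-3.1, -3), (-3, -3.1)])
        [lt] = assign_compartments([t], annotation)
        assert lt.label == "outside"

    def test_matches_brute_force_containment(self, annotation):
        rng = np.random.default_rng(1)
        trajs = [
            make_trajectory(f"t{i}", range(4), rng.uniform(-5, 5, (4, 2)))
            for i in range(50)
        ]
        labeled = {lt.trajectory.traj_id: lt for lt in assign_compartments(trajs, annotation)}
        comp = annotation.compartments_before[0]
        nuc = annotation.nucleus_before
        for t in trajs:
            in_nuc = [nuc.contains_point(x, y) for x, y in t.xy]
            if not any(in_nuc):
                assert t.traj_id not in labeled
                continue
            expected = any(
                comp.contains_point(x, y)
                for (x, y), ok in zip(t.xy, in_nuc) if ok
            )
            assert (labeled[t.traj_id].label == "inside") == expected

    def test_localizations_outside_nucleus_discarded(self, annotation):
        t = make_trajectory("t", range(3), [(0, 0), (20, 20), (0.1, 0)])
        [lt] = assign_compartments([t], annotation)
        assert len(lt.trajectory) == 2


class TestMockPlacement:
    def test_small_disc_fits_in_large_nucleus(self, nucleus):
        bare = CellAnnotation.static("c", nucleus)
        mock = place_mock_compartments([regular_polygon(16, 0.5)], 1, bare, seed=0)
        assert len(mock.compartments_before) == 1
        assert nucleus.shapely.covers(mock.compartments_before[0].shapely)

    def test_impossible_placement_raises(self, nucleus):
        # a nucleolus filling the nucleus leaves no room
        nucleolus = regular_polygon(32, 5.9)
        bare = CellAnnotation.static("cellX", nucleus, nucleoli=[nucleolus])
        with pytest.raises(PlacementError, match="cellX"):
            place_mock_compartments(
                [regular_polygon(16, 0.5)], 1, bare, seed=0, max_attempts=50
            )

    def test_mocks_disjoint_from_each_other(self, nucleus):
        bare = CellAnnotation.static("c", nucleus)
        mock = place_mock_compartments(
            [regular_polygon(16, 1.0)], 3, bare, seed=1, max_attempts=2000
        )
        polys = [p.shapely for p in mock.compartments_before]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not polys[i].intersects(polys[j])

    def test_uniform_points_inside_mocks_at_area_fraction(self, nucleus):
        bare = CellAnnotation.static("c", nucleus)
        mock = place_mock_compartments([regular_polygon(24, 1.5)], 2, bare, seed=3)
        area_frac = sum(p.area for p in mock.compartments_before) / nucleus.area
        rng = np.random.default_rng(4)
        pts = nucleus.sample_uniform(4000, rng)
        # single-point trajectories: label frequency is a pure area fraction
        trajs = [
            make_trajectory(f"p{i}", [0], [pt], cell_id="c")
            for i, pt in enumerate(pts)
        ]
        labeled = assign_compartments(trajs, mock)
        frac = np.mean([lt.label == "inside" for lt in labeled])
        sd = np.sqrt(area_frac * (1 - area_frac) / 4000)
        assert abs(frac - area_frac) < 3 * sd


class TestBoundaryCrossings:
    def test_alternating_trajectory_counts_split_evenly(self, nucleus):
        comp = square(2.0, -1, -1)
        ann = CellAnnotation.static("cell0", nucleus, compartments=[comp])
        n = 7  # 7 jumps alternating out-in
        xy = [((-3, 0) if i % 2 == 0 else (0, 0)) for i in range(n + 1)]
        t = make_trajectory("t", range(n + 1), xy)
        cj = boundary_crossing_jumps(assign_compartments([t], ann))
        assert len(cj.entering) + len(cj.exiting) == n
        assert abs(len(cj.entering) - len(cj.exiting)) <= 1

    def test_all_inside_trajectories_give_empty_cdfs(self, nucleus):
        comp = square(4.0, -2, -2)
        ann = CellAnnotation.static("cell0", nucleus, compartments=[comp])
        t = make_trajectory("t", range(3), [(0, 0), (0.1, 0), (0, 0.1)])
        with pytest.warns(UserWarning, match="no boundary-crossing"):
            cj = boundary_crossing_jumps(assign_compartments([t], ann))
        assert len(cj.entering) == 0 and len(cj.exiting) == 0

    def test_free_diffusion_has_symmetric_crossing_distributions(self):
        from scipy.stats import ks_2samp

        nuc = square(20.0, -10, -10)
        comp = square(10.0, -10, -5)  # straight vertical boundary at x = 0
        cfg = SpaSptSimConfig(
            n_trajectories=20000, F_bound=0.0, D_free=3.5, nucleus=nuc, seed=8
        )
        trajs, _ = simulate_spaspt(cfg)
        ann = CellAnnotation.static("simcell", nuc, compartments=[comp])
        cj = boundary_crossing_jumps(assign_compartments(trajs, ann))
        assert len(cj.entering) > 50 and len(cj.exiting) > 50
        assert ks_2samp(cj.entering, cj.exiting).pvalue > 0.01
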