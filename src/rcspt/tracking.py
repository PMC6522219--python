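"""Trajectory linking, annotation drift correction, compartment sorting, and
the mock-compartment null.

Linking is deterministic greedy nearest-neighbor with the same search-radius
and gap rules as multi-target tracking: the search radius for a k-frame gap is
``r_max(k) = sqrt(4·d_max·k·Δt)`` and a trajectory is terminated (rather than
ambiguously linked) when more than ``max_competitors`` candidate detections
fall inside its search radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import PolygonRegion
from .io import CellAnnotation, Trajectory


class PlacementError(RuntimeError):
    """Mock-compartment placement failed within the attempt budget."""


@dataclass
class LinkingConfig:
    """Parameters for greedy nearest-neighbor linking.

    ``d_max`` is the diffusion ceiling (µm²/s) used to derive the search
    radius; up to ``gap_frames`` missing frames may be bridged.
    """

    d_max: float = 10.0  # µm²/s
    gap_frames: int = 1
    max_competitors: int = 3
    frame_interval: float = 0.007447  # s

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if self.gap_frames < 0:
            raise ValueError("gap_frames must be >= 0")

    def r_max(self, k: int) -> float:
        """Search radius (µm) for a k-frame gap."""
        return float(np.sqrt(4.0 * self.d_max * k * self.frame_interval))


def link_localizations(
    locs: pd.DataFrame, config: LinkingConfig, cell_id: str = "cell0"
) -> list[Trajectory]:
    """Link a per-cell localization table (columns x, y, frame) into
    trajectories.

    Assignment is greedy frame-to-frame: candidate (trajectory, detection)
    pairs within the gap-dependent search radius are linked smallest distance
    first, ties broken by lowest detection row index.  A trajectory whose
    search disc contains more than ``max_competitors`` candidates is
    terminated.  Detections that remain unlinked start new trajectories.
    """
    df = locs.sort_values("frame", kind="stable").reset_index(drop=True)
    dup = df.duplicated(subset=["frame", "x", "y"])
    if dup.any():
        warnings.warn(f"{int(dup.sum())} duplicate (frame, x, y) rows kept")

    next_id = 0
    # active trajectory state: list of dicts
    active: list[dict] = []
    done: list[dict] = []

    for frame, grp in df.groupby("frame", sort=True):
        pts = grp[["x", "y"]].to_numpy(float)
        pt_rows = grp.index.to_numpy()
        frame = int(frame)

        # retire trajectories whose gap budget is exhausted
        still = []
        for t in active:
            if frame - t["last_frame"] > 1 + config.gap_frames:
                done.append(t)
            else:
                still.append(t)
        active = still

        # candidate pairs
        pairs = []  # (dist, loc_order, traj_idx, loc_idx)
        n_cand = np.zeros(len(active), dtype=int)
        for ti, t in enumerate(active):
            k = frame - t["last_frame"]
            r = config.r_max(k)
            d = np.hypot(pts[:, 0] - t["x"], pts[:, 1] - t["y"])
            inside = np.flatnonzero(d <= r)
            n_cand[ti] = len(inside)
            for li in inside:
                pairs.append((d[li], int(pt_rows[li]), ti, int(li)))

        # competitor cap: ambiguity terminates the trajectory
        terminated = set(np.flatnonzero(n_cand > config.max_competitors))
        for ti in terminated:
            done.append(active[ti])

        pairs.sort()
        used_t: set[int] = set(terminated)
        used_l: set[int] = set()
        for dist, _, ti, li in pairs:
            if ti in used_t or li in used_l:
                continue
            t = active[ti]
            t["frames"].append(frame)
            t["xy"].append(pts[li])
            t["last_frame"] = frame
            t["x"], t["y"] = pts[li]
            used_t.add(ti)
            used_l.add(li)

        active = [t for ti, t in enumerate(active) if ti not in terminated]

        for li in range(len(pts)):
            if li not in used_l:
                active.append(
                    {
                        "id": next_id,
                        "frames": [frame],
                        "xy": [pts[li]],
                        "last_frame": frame,
                        "x": pts[li, 0],
                        "y": pts[li, 1],
                    }
                )
                next_id += 1

    done.extend(active)
    done.sort(key=lambda t: t["id"])
    return [
        Trajectory(
            traj_id=f"traj{t['id']:06d}",
            cell_id=cell_id,
            frames=np.asarray(t["frames"], dtype=int),
            xy=np.asarray(t["xy"], dtype=float),
            max_gap=config.gap_frames,
        )
        for t in done
    ]


# ---------------------------------------------------------------------------
# drift interpolation and compartment sorting
# ---------------------------------------------------------------------------


def _lerp_polygon(before: PolygonRegion, after: PolygonRegion, frac: float) -> PolygonRegion:
    if frac <= 0:
        return before
    if frac >= 1:
        return after
    return PolygonRegion((1 - frac) * before.vertices + frac * after.vertices)


def interpolate_annotation(ann: CellAnnotation, frame: int) -> dict:
    """Linearly interpolated per-frame polygons.

    Cell movement over the acquisition is assumed linear, so each vertex moves
    from its 'before' to its 'after' position at fraction
    ``frame / (n_frames − 1)``.  Returns ``{"nucleus": PolygonRegion,
    "compartments": [...], "nucleoli": [...]}``.
    """
    if not 0 <= frame < ann.n_frames:
        raise ValueError(f"frame {frame} outside [0, {ann.n_frames})")
    frac = 0.0 if ann.n_frames == 1 else frame / (ann.n_frames - 1)
    return {
        "nucleus": _lerp_polygon(ann.nucleus_before, ann.nucleus_after, frac),
        "compartments": [
            _lerp_polygon(b, a, frac)
            for b, a in zip(ann.compartments_before, ann.compartments_after)
        ],
        "nucleoli": list(ann.nucleoli),
    }


@dataclass
class LabeledTrajectory:
    """A trajectory restricted to the nucleus, with a compartment label.

    ``label`` is "inside" iff at least one retained localization falls within
    any drift-interpolated compartment polygon at its own frame;
    ``inside_flags`` records per-localization containment.
    """

    trajectory: Trajectory
    label: str
    inside_flags: np.ndarray = field(default_factory=lambda: np.empty(0, bool))


def assign_compartments(
    trajs: list[Trajectory], ann: CellAnnotation
) -> list[LabeledTrajectory]:
    """Sort trajectories as inside/outside the annotated compartments.

    Localizations outside the drift-interpolated nucleus at their frame are
    discarded first; a single remaining localization inside a compartment
    labels the whole trajectory "inside".  Trajectories left with no points
    are dropped.
    """
    if not trajs:
        return []
    # flatten all localizations, then vectorize containment per distinct frame
    lengths = np.array([len(t) for t in trajs])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    frames_all = np.concatenate([t.frames for t in trajs])
    xy_all = np.vstack([t.xy for t in trajs])
    keep_all = np.zeros(len(frames_all), dtype=bool)
    inside_all = np.zeros(len(frames_all), dtype=bool)
    for f in np.unique(frames_all):
        sel = frames_all == f
        p = interpolate_annotation(ann, int(min(max(f, 0), ann.n_frames - 1)))
        x, y = xy_all[sel, 0], xy_all[sel, 1]
        in_nuc = p["nucleus"].contains(x, y)
        keep_all[sel] = in_nuc
        in_comp = np.zeros(len(x), dtype=bool)
        for c in p["compartments"]:
            in_comp |= c.contains(x, y)
        inside_all[sel] = in_comp & in_nuc

    out: list[LabeledTrajectory] = []
    for i, t in enumerate(trajs):
        lo, hi = offsets[i], offsets[i + 1]
        keep = keep_all[lo:hi]
        inside = inside_all[lo:hi]
        if not keep.any():
            continue
        sub = Trajectory(
            traj_id=t.traj_id,
            cell_id=t.cell_id,
            frames=t.frames[keep],
            xy=t.xy[keep],
            max_gap=max(t.max_gap, int(np.diff(t.frames[keep]).max() - 1) if keep.sum() > 1 else t.max_gap),
        )
        label = "inside" if inside[keep].any() else "outside"
        out.append(LabeledTrajectory(trajectory=sub, label=label, inside_flags=inside[keep]))
    return out


# ---------------------------------------------------------------------------
# mock-compartment null
# ---------------------------------------------------------------------------


def place_mock_compartments(
    ann_library: list[PolygonRegion],
    count_distribution,
    target: CellAnnotation,
    seed=0,
    max_attempts: int = 1000,
    rotate: bool = False,
    avoid_existing_compartments: bool = False,
) -> CellAnnotation:
    """Place randomly chosen library compartments into a target nucleus.

    The number of mocks is drawn from ``count_distribution`` (an int, or a
    sequence of observed per-cell counts to resample).  Each mock is a library
    polygon translated to a uniform-random interior position (optionally
    rotated), accepted only if fully inside the nucleus and disjoint from the
    nucleoli, the already-placed mocks and (optionally) the real compartments.
    """
    if not ann_library:
        raise ValueError("compartment library is empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if np.isscalar(count_distribution):
        n_mocks = int(count_distribution)
    else:
        n_mocks = int(rng.choice(np.asarray(count_distribution, dtype=int)))

    nucleus = target.nucleus_before
    forbidden = [p.shapely for p in target.nucleoli]
    if avoid_existing_compartments:
        forbidden += [p.shapely for p in target.compartments_before]

    placed: list[PolygonRegion] = []
    for m in range(n_mocks):
        ok = False
        for _ in range(max_attempts):
            src = ann_library[int(rng.integers(len(ann_library)))]
            verts = src.vertices - src.vertices.mean(axis=0)
            if rotate:
                a = rng.uniform(0, 2 * np.pi)
                R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
                verts = verts @ R.T
            cx, cy = nucleus.sample_uniform(1, rng)[0]
            cand = PolygonRegion(verts + np.array([cx, cy]))
            if not nucleus.shapely.covers(cand.shapely):
                continue
            if any(cand.shapely.intersects(f) for f in forbidden):
                continue
            if any(cand.shapely.intersects(p.shapely) for p in placed):
                continue
            placed.append(cand)
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"cell {target.cell_id}: could not place mock compartment "
                f"{m + 1}/{n_mocks} within {max_attempts} attempts"
            )

    return CellAnnotation(
        cell_id=target.cell_id,
        nucleus_before=target.nucleus_before,
        nucleus_after=target.nucleus_after,
        compartments_before=placed,
        compartments_after=placed,
        nucleoli=list(target.nucleoli),
        n_frames=target.n_frames,
    )


# ---------------------------------------------------------------------------
# boundary-crossing jump statistics
# ---------------------------------------------------------------------------


@dataclass
class CrossingJumps:
    """Jump lengths of molecules entering or exiting compartments."""

    entering: np.ndarray
    exiting: np.ndarray
    per_cell: pd.DataFrame  # cell_id, direction, mean, sem, n

    @staticmethod
    def _ecdf(values: np.ndarray):
        x = np.sort(values)
        return x, np.arange(1, len(x) + 1) / len(x)

    def entering_cdf(self):
        return self._ecdf(self.entering)

    def exiting_cdf(self):
        return self._ecdf(self.exiting)


def boundary_crossing_jumps(labeled: list[LabeledTrajectory]) -> CrossingJumps:
    """Empirical jump-length distributions for compartment boundary crossings.

    A single-frame jump is "entering" when it starts outside and ends inside a
    compartment, and "exiting" for the reverse.  Jumps spanning a frame gap
    are excluded.
    """
    entering, exiting = [], []
    rows = []
    by_cell: dict[str, dict[str, list]] = {}
    for lt in labeled:
        t = lt.trajectory
        flags = lt.inside_flags
        d = np.diff(t.frames)
        jumps = np.linalg.norm(np.diff(t.xy, axis=0), axis=1)
        cell = by_cell.setdefault(t.cell_id, {"entering": [], "exiting": []})
        for i in np.flatnonzero(d == 1):
            if not flags[i] and flags[i + 1]:
                entering.append(jumps[i])
                cell["entering"].append(jumps[i])
            elif flags[i] and not flags[i + 1]:
                exiting.append(jumps[i])
                cell["exiting"].append(jumps[i])
    if not entering and not exiting:
        warnings.warn("no boundary-crossing events found; CDFs are empty")
    for cell_id, d in by_cell.items():
        for direction in ("entering", "exiting"):
            v = np.asarray(d[direction])
            if len(v) == 0:
                continue
            rows.append(
                {
                    "cell_id": cell_id,
                    "direction": direction,
                    "mean": float(v.mean()),
                    "sem": float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
                    "n": len(v),
                }
            )
    return CrossingJumps(
        entering=np.asarray(entering),
        exiting=np.asarray(exiting),
        per_cell=pd.DataFrame(rows, columns=["cell_id", "direction", "mean", "sem", "n"]),
    )
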