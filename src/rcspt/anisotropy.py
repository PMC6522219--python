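"""Angular anisotropy of consecutive displacements.

A trajectory of N localizations contains N−2 consecutive three-point sets;
the folded angle θ ∈ [0°, 180°] between the two displacement vectors at each
vertex measures how directionally persistent the motion is.  Ideal Brownian
motion is isotropic (flat θ distribution); transient trapping/rebinding
produces an excess of backward steps.  The fold statistic

    f(180/0) = #{θ within 30° of 180°} / #{θ within 30° of 0°}

is 1 for isotropic motion and > 1 for compartments where molecules revisit
nearby sites.  Only mobile segments enter the statistic: both displacements
must be at least 150 nm, since the localization error of bound molecules
would otherwise make the data spuriously anisotropic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellAnnotation, Trajectory
from .tracking import LabeledTrajectory, interpolate_annotation

MIN_JUMP_UM = 0.150
WEDGE_DEG = 30.0


@dataclass
class Triple:
    """Three consecutive localizations (no frame gap) from one trajectory."""

    traj_id: str
    cell_id: str
    frames: np.ndarray  # (3,)
    xy: np.ndarray  # (3, 2)
    jump1: float
    jump2: float


def _as_trajectories(trajs) -> list[Trajectory]:
    return [t.trajectory if isinstance(t, LabeledTrajectory) else t for t in trajs]


def iter_triples(trajs) -> list[Triple]:
    """All consecutive three-point sets with no intervening frame gap."""
    out = []
    for t in _as_trajectories(trajs):
        if len(t) < 3:
            continue
        d = np.diff(t.frames)
        jumps = np.linalg.norm(np.diff(t.xy, axis=0), axis=1)
        for i in range(len(t) - 2):
            if d[i] != 1 or d[i + 1] != 1:
                continue
            out.append(
                Triple(
                    traj_id=t.traj_id,
                    cell_id=t.cell_id,
                    frames=t.frames[i : i + 3],
                    xy=t.xy[i : i + 3],
                    jump1=float(jumps[i]),
                    jump2=float(jumps[i + 1]),
                )
            )
    return out


def _hmm_bound_trajectories(trajs: list[Trajectory], seed: int = 0) -> set[str]:
    """Classify whole trajectories as bound via a 2-state HMM on log squared
    displacements; returns the ids labeled bound."""
    from hmmlearn.hmm import GaussianHMM

    seqs, lengths, ids = [], [], []
    for t in trajs:
        if len(t) < 2:
            continue
        sq = (np.diff(t.xy, axis=0) ** 2).sum(axis=1)
        obs = np.log(np.maximum(sq, 1e-12))[:, None]
        seqs.append(obs)
        lengths.append(len(obs))
        ids.append(t.traj_id)
    if not seqs:
        return set()
    X = np.vstack(seqs)
    hmm = GaussianHMM(n_components=2, covariance_type="diag", n_iter=100,
                      random_state=seed)
    hmm.fit(X, lengths)
    bound_state = int(np.argmin(hmm.means_[:, 0]))
    bound_ids = set()
    pos = 0
    for tid, ln in zip(ids, lengths):
        states = hmm.predict(X[pos : pos + ln])
        pos += ln
        # a trajectory is "bound" if most of its segments sit in the slow state
        if (states == bound_state).mean() > 0.5:
            bound_ids.add(tid)
    return bound_ids


def filter_mobile_segments(
    trajs,
    min_jump: float = MIN_JUMP_UM,
    classifier: str = "threshold",
    seed: int = 0,
) -> list[Triple]:
    """Retain three-point sets whose both displacements are >= ``min_jump``.

    ``classifier="hmm"`` additionally drops triples from trajectories that a
    2-state displacement HMM labels as bound.  The hard length threshold is
    always applied.
    """
    triples = iter_triples(trajs)
    if classifier == "hmm":
        bound_ids = _hmm_bound_trajectories(_as_trajectories(trajs), seed=seed)
        triples = [tr for tr in triples if tr.traj_id not in bound_ids]
    elif classifier != "threshold":
        raise ValueError(f"unknown classifier {classifier!r}")
    return [tr for tr in triples if tr.jump1 >= min_jump and tr.jump2 >= min_jump]


def compute_angles(
    triples: list[Triple], ann: CellAnnotation | None = None
) -> pd.DataFrame:
    """Folded angles between consecutive displacements.

    θ = arccos(v₁·v₂ / (‖v₁‖‖v₂‖)) in degrees, with v₁ = p₂−p₁ and
    v₂ = p₃−p₂.  The region label ("inside"/"outside") is assigned by the
    vertex p₂'s containment in the drift-interpolated compartments at p₂'s
    own frame; without an annotation all angles are labeled "all".
    """
    rows = []
    poly_cache: dict[int, list] = {}
    for tr in triples:
        v1 = tr.xy[1] - tr.xy[0]
        v2 = tr.xy[2] - tr.xy[1]
        n1 = np.linalg.norm(v1)
        n2 = np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            continue
        cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
        theta = float(np.degrees(np.arccos(cosang)))
        if ann is None:
            region = "all"
        else:
            f = int(min(max(tr.frames[1], 0), ann.n_frames - 1))
            if f not in poly_cache:
                poly_cache[f] = interpolate_annotation(ann, f)["compartments"]
            x, y = tr.xy[1]
            region = (
                "inside"
                if any(c.contains_point(x, y) for c in poly_cache[f])
                else "outside"
            )
        rows.append(
            {
                "theta": theta,
                "vertex_x": tr.xy[1, 0],
                "vertex_y": tr.xy[1, 1],
                "frame": int(tr.frames[1]),
                "jump1": tr.jump1,
                "jump2": tr.jump2,
                "region": region,
                "traj_id": tr.traj_id,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["theta", "vertex_x", "vertex_y", "frame", "jump1", "jump2",
                 "region", "traj_id"],
    )


@dataclass
class AnisotropyFold:
    """Backward/forward fold statistic with bootstrap uncertainty."""

    f_180_0: float
    n_backward: int
    n_forward: int
    bootstrap_sd: float
    wedge: float = WEDGE_DEG
    n_angles: int = 0


def fold_anisotropy(
    angles, wedge: float = WEDGE_DEG, n_boot: int = 1000, seed: int = 0
) -> AnisotropyFold:
    """Ratio of backward (180°±wedge) to forward (0°±wedge) angle counts.

    The bootstrap SD resamples angles with replacement (seeded).  Raises when
    the forward wedge is empty (undefined ratio).
    """
    theta = np.asarray(angles["theta"] if isinstance(angles, pd.DataFrame) else angles,
                       dtype=float)
    back = theta >= 180.0 - wedge
    fwd = theta <= wedge
    n_b, n_f = int(back.sum()), int(fwd.sum())
    if n_f == 0:
        raise ZeroDivisionError("no angles in the forward wedge; fold undefined")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(theta)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        tb = theta[idx]
        nf = max(int((tb <= wedge).sum()), 1)
        boots[b] = (tb >= 180.0 - wedge).sum() / nf
    return AnisotropyFold(
        f_180_0=n_b / n_f,
        n_backward=n_b,
        n_forward=n_f,
        bootstrap_sd=float(boots.std(ddof=1)),
        wedge=wedge,
        n_angles=n,
    )


def angle_histogram(angles, bin_width: float = 5.0) -> pd.DataFrame:
    """Histogram of folded angles (default 5° bins), per region."""
    df = angles if isinstance(angles, pd.DataFrame) else pd.DataFrame(
        {"theta": np.asarray(angles), "region": "all"}
    )
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    rows = []
    for region, grp in df.groupby("region"):
        counts, _ = np.histogram(grp["theta"], bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            rows.append({"region": region, "theta_lo": lo, "theta_hi": hi, "count": int(c)})
    return pd.DataFrame(rows)
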