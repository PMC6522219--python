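"""Synthetic-data generators for every analysis stage.

These generators produce data with the statistical structure the analyses
assume: two-state (immobile/free) Brownian motion observed through a finite
axial detection slab with localization noise; homogeneous-Poisson and
Thomas-cluster point patterns inside polygons; particle-based FRAP/FLIP
recovery traces with multiplicative per-frame photobleaching; lognormal FISH
intensities proportional to genome copy number; and piecewise-constant
disorder-score profiles.

All generators are pure functions of (config, seed): the same seed yields
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely

from .geometry import PolygonRegion
from .io import DisorderProfile, IntensityTrace, Trajectory


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# spaSPT simulator
# ---------------------------------------------------------------------------


@dataclass
class SpaSptSimConfig:
    """Two-state Brownian-motion simulation inside a nuclear polygon.

    Defaults correspond to stroboscopic photo-activatable SPT of a protein
    with RNA Pol II-like kinetics: 50% bound, D_free = 3.5 µm²/s, small
    residual chromatin motion for the bound state, 45 nm localization error,
    7.447 ms frame interval, and a 0.7 µm axial detection slab.
    """

    n_trajectories: int = 1000
    F_bound: float = 0.5
    D_free: float = 3.5  # µm²/s
    D_bound: float = 0.005  # µm²/s, residual chromatin motion
    sigma_loc: float = 0.045  # µm
    frame_interval: float = 0.007447  # s
    dZ: float = 0.700  # µm, axial detection slab depth
    n_frames: int = 12  # maximum observed frames per molecule
    nucleus: PolygonRegion | None = None
    compartments: list = field(default_factory=list)
    trap_density: float = 0.0  # traps per µm² (0 disables the trap model)
    trap_capture_radius: float = 0.15  # µm, comparable to one free jump
    trap_escape_prob: float = 0.8  # per-frame escape probability (transient traps)
    traps_in_compartments_only: bool = True
    p_switch: float = 0.0  # per-frame bound<->free switching (off by default)
    start_frame_max: int = 0  # trajectories start uniformly in [0, this]
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.F_bound <= 1.0:
            raise ConfigError("F_bound must lie in [0, 1]")
        if not (self.D_free > self.D_bound >= 0):
            raise ConfigError("need D_free > D_bound >= 0")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive")
        if self.nucleus is not None and self.nucleus.area <= 0:
            raise ConfigError("nucleus polygon has zero area")


@dataclass
class SimulationTruth:
    """Ground truth for a spaSPT simulation: per-trajectory state labels."""

    labels: pd.DataFrame  # traj_id, bound (initial state), n_points
    config: SpaSptSimConfig
    seed: int


def _reflect_into(region: PolygonRegion, pos: np.ndarray) -> np.ndarray:
    """Push points outside the region back inside.

    Outside points are mirrored across their nearest boundary point; points
    that remain outside after mirroring are clamped to that boundary point
    (boundary points count as inside).
    """
    inside = region.contains(pos[:, 0], pos[:, 1])
    if inside.all():
        return pos
    out_idx = np.flatnonzero(~inside)
    pts = shapely.points(pos[out_idx, 0], pos[out_idx, 1])
    lines = shapely.shortest_line(pts, region.shapely.exterior)
    q = shapely.get_coordinates(shapely.get_point(lines, 1))
    mirrored = 2.0 * q - pos[out_idx]
    still_out = ~region.contains(mirrored[:, 0], mirrored[:, 1])
    mirrored[still_out] = q[still_out]
    pos = pos.copy()
    pos[out_idx] = mirrored
    return pos


def simulate_spaspt(config: SpaSptSimConfig) -> tuple[list[Trajectory], SimulationTruth]:
    """Simulate two-state spaSPT trajectories.

    Each molecule is assigned the bound state with probability ``F_bound`` and
    keeps it for its whole trajectory (unless ``p_switch`` > 0).  Lateral
    positions evolve by isotropic Gaussian steps of variance ``2·D·Δt`` per
    axis and are reflected at the nucleus boundary; a hidden z-coordinate
    diffuses in a slab of depth ``dZ`` and the trajectory is truncated once
    ``|z| > dZ/2`` (defocalization).  Independent Gaussian localization noise
    ``sigma_loc`` is added to every observed coordinate.

    Returns the observed trajectories together with the generating truth.
    """
    cfg = config
    rng = _rng(cfg.seed)
    nucleus = cfg.nucleus
    if nucleus is None:
        # default 20x20 µm square nucleus centred at origin
        nucleus = PolygonRegion([(-10, -10), (10, -10), (10, 10), (-10, 10)])
        cfg = replace(cfg, nucleus=nucleus)
    n = cfg.n_trajectories
    dt = cfg.frame_interval

    # trap points (optional)
    traps = np.empty((0, 2))
    if cfg.trap_density > 0:
        regions = cfg.compartments if (cfg.traps_in_compartments_only and
                                       cfg.compartments) else [nucleus]
        parts = []
        for reg in regions:
            k = rng.poisson(cfg.trap_density * reg.area)
            if k:
                parts.append(reg.sample_uniform(k, rng))
        if parts:
            traps = np.vstack(parts)

    bound = rng.random(n) < cfg.F_bound
    pos = nucleus.sample_uniform(n, rng)
    z = rng.uniform(-cfg.dZ / 2, cfg.dZ / 2, n)
    alive = np.ones(n, dtype=bool)
    trapped_left = np.zeros(n, dtype=int)  # remaining trapped frames

    start = (rng.integers(0, cfg.start_frame_max + 1, n)
             if cfg.start_frame_max > 0 else np.zeros(n, dtype=int))

    true_pos = np.full((cfg.n_frames, n, 2), np.nan)
    true_pos[0] = pos
    observed_alive = np.zeros((cfg.n_frames, n), dtype=bool)
    observed_alive[0] = True

    for f in range(1, cfg.n_frames):
        if not alive.any():
            break
        currently_bound = bound | (trapped_left > 0)
        D = np.where(currently_bound, cfg.D_bound, cfg.D_free)
        step_sd = np.sqrt(2.0 * D * dt)
        step = rng.normal(0.0, 1.0, (n, 2)) * step_sd[:, None]
        new_pos = pos + step
        new_pos[alive] = _reflect_into(nucleus, new_pos[alive])

        # axial diffusion and defocalization: absorbing slab with
        # Brownian-bridge crossing probabilities between frames, so absorption
        # is continuous in time rather than checked only at frame boundaries
        b = cfg.dZ / 2
        z_new = z + rng.normal(0.0, 1.0, n) * step_sd
        inside_slab = np.abs(z_new) <= b
        Ddt = D * dt
        with np.errstate(divide="ignore", invalid="ignore"):
            p_up = np.exp(-np.maximum(b - z, 0) * np.maximum(b - z_new, 0) / Ddt)
            p_dn = np.exp(-np.maximum(b + z, 0) * np.maximum(b + z_new, 0) / Ddt)
        p_cross = np.where(Ddt > 0, np.clip(p_up + p_dn, 0.0, 1.0), 0.0)
        alive = alive & inside_slab & (rng.random(n) >= p_cross)
        z = z_new

        # trap dynamics: a free molecule landing within the capture radius of
        # a trap snaps to the trap point and stays for a geometric dwell
        if traps.shape[0]:
            trapped_left = np.maximum(trapped_left - 1, 0)
            free_now = alive & ~bound & (trapped_left == 0)
            if free_now.any():
                idx = np.flatnonzero(free_now)
                d2 = ((new_pos[idx, None, :] - traps[None, :, :]) ** 2).sum(-1)
                nearest = d2.argmin(axis=1)
                caught = d2[np.arange(len(idx)), nearest] <= cfg.trap_capture_radius ** 2
                cidx = idx[caught]
                new_pos[cidx] = traps[nearest[caught]]
                trapped_left[cidx] = rng.geometric(cfg.trap_escape_prob, len(cidx))

        if cfg.p_switch > 0:
            flip = rng.random(n) < cfg.p_switch
            bound = np.where(flip, ~bound, bound)

        pos = new_pos
        true_pos[f, alive] = pos[alive]
        observed_alive[f, alive] = True

    noise = rng.normal(0.0, cfg.sigma_loc, true_pos.shape) if cfg.sigma_loc > 0 else 0.0
    obs = true_pos + noise

    trajs: list[Trajectory] = []
    rows = {"traj_id": [], "bound": [], "n_points": []}
    for i in range(n):
        frames_i = np.flatnonzero(observed_alive[:, i])
        tid = f"sim{i:06d}"
        trajs.append(
            Trajectory(
                traj_id=tid,
                cell_id="simcell",
                frames=frames_i + start[i],
                xy=obs[frames_i, i, :],
                max_gap=1,
            )
        )
        rows["traj_id"].append(tid)
        rows["bound"].append(bool(bound[i]))
        rows["n_points"].append(len(frames_i))
    truth = SimulationTruth(labels=pd.DataFrame(rows), config=cfg, seed=cfg.seed)
    return trajs, truth


# ---------------------------------------------------------------------------
# point patterns
# ---------------------------------------------------------------------------


def simulate_point_pattern(
    region: PolygonRegion,
    mode: str = "csr",
    intensity: float | None = None,
    n_points: int | None = None,
    cluster: dict | None = None,
    seed=0,
) -> np.ndarray:
    """Simulate a 2-D point pattern inside a polygonal region.

    Parameters
    ----------
    mode : {"csr", "cluster"}
        "csr" draws Poisson(λ·Area) points uniformly (or exactly ``n_points``
        if given — conditional CSR, used for envelopes).  "cluster" is a
        Thomas process: Poisson parents with Gaussian-displaced offspring.
    intensity : float
        Points per µm² (CSR) — ignored when ``n_points`` is given.
    cluster : dict
        For cluster mode: ``n_parents`` (or ``parent_intensity``),
        ``offspring_per_parent`` (exact count) or ``mean_offspring``
        (Poisson), and ``sigma`` (µm).

    Returns an (N, 2) array of (x, y) in µm.
    """
    rng = _rng(seed)
    if mode == "csr":
        if n_points is None:
            if intensity is None or intensity <= 0:
                raise ConfigError("CSR mode needs intensity > 0 or n_points")
            n_points = int(rng.poisson(intensity * region.area))
        if n_points == 0:
            return np.empty((0, 2))
        return region.sample_uniform(n_points, rng)
    if mode == "cluster":
        c = dict(cluster or {})
        if "n_parents" in c:
            n_par = int(c["n_parents"])
        elif "parent_intensity" in c:
            n_par = int(rng.poisson(c["parent_intensity"] * region.area))
        else:
            raise ConfigError("cluster mode needs n_parents or parent_intensity")
        sigma = float(c.get("sigma", 0.05))
        parents = region.sample_uniform(max(n_par, 1), rng)[:n_par]
        pts = []
        for p in parents:
            if "offspring_per_parent" in c:
                k = int(c["offspring_per_parent"])
            else:
                k = int(rng.poisson(c.get("mean_offspring", 20)))
            if k == 0:
                continue
            off = p + rng.normal(0.0, sigma, (k, 2))
            keep = region.contains(off[:, 0], off[:, 1])
            pts.append(off[keep])
        if not pts:
            return np.empty((0, 2))
        return np.vstack(pts)
    raise ConfigError(f"unknown point-pattern mode {mode!r}")


# ---------------------------------------------------------------------------
# FRAP / FLIP recovery traces
# ---------------------------------------------------------------------------


@dataclass
class RecoverySimConfig:
    """Particle-based photobleaching simulation in an idealized 2-D nucleus.

    Defaults follow confocal FRAP of Pol II: a 0.956 µm (11 px) bleach circle,
    measurement in a circle of the same size, 250 ms frames, bleach applied
    after 15 pre-bleach frames.
    """

    n_molecules: int = 5000
    F_bound: float = 0.0
    D_free: float = 3.5  # µm²/s
    D_bound: float = 0.0
    nucleus: PolygonRegion | None = None
    bleach_center: tuple[float, float] = (0.0, 0.0)
    bleach_diameter: float = 0.956  # µm
    measure_center: tuple[float, float] | None = None  # default: bleach spot
    measure_diameter: float = 0.956
    bleach_frame: int = 15
    n_frames: int = 100
    frame_interval: float = 0.25  # s
    bleach_rate_per_frame: float = 0.0  # global photobleaching rate
    seed: int = 0


def simulate_recovery(kind: str, config: RecoverySimConfig) -> IntensityTrace:
    """Simulate a FRAP or FLIP intensity trace.

    FRAP darkens all molecules inside the bleach circle once, at the bleach
    frame; FLIP darkens them every frame from the bleach frame on.  The spot
    trace is the count of fluorescent molecules inside the measurement circle
    and the reference trace the count in the whole nucleus, both multiplied by
    a global photobleaching factor ``exp(−bleach_rate·frame)``.
    """
    cfg = config
    kind = kind.upper()
    if kind not in ("FRAP", "FLIP"):
        raise ConfigError(f"kind must be FRAP or FLIP, got {kind!r}")
    if cfg.n_frames <= cfg.bleach_frame:
        raise ConfigError("n_frames must exceed bleach_frame")
    rng = _rng(cfg.seed)
    nucleus = cfg.nucleus
    if nucleus is None:
        from .geometry import regular_polygon

        nucleus = regular_polygon(64, 5.0)
    mx, my = cfg.measure_center if cfg.measure_center is not None else cfg.bleach_center
    if not nucleus.contains_point(mx, my):
        raise ConfigError("measurement circle centre lies outside the nucleus")

    n = cfg.n_molecules
    bound = rng.random(n) < cfg.F_bound
    D = np.where(bound, cfg.D_bound, cfg.D_free)
    step_sd = np.sqrt(2.0 * D * cfg.frame_interval)
    pos = nucleus.sample_uniform(n, rng)
    lit = np.ones(n, dtype=bool)

    bx, by = cfg.bleach_center
    r_bleach2 = (cfg.bleach_diameter / 2) ** 2
    r_meas2 = (cfg.measure_diameter / 2) ** 2

    spot = np.empty(cfg.n_frames)
    ref = np.empty(cfg.n_frames)
    for f in range(cfg.n_frames):
        if f > 0:
            pos = pos + rng.normal(0.0, 1.0, (n, 2)) * step_sd[:, None]
            pos = _reflect_into(nucleus, pos)
        bleach_now = (f == cfg.bleach_frame) if kind == "FRAP" else (f >= cfg.bleach_frame)
        if bleach_now:
            in_bleach = ((pos[:, 0] - bx) ** 2 + (pos[:, 1] - by) ** 2) <= r_bleach2
            lit &= ~in_bleach
        in_meas = ((pos[:, 0] - mx) ** 2 + (pos[:, 1] - my) ** 2) <= r_meas2
        fade = np.exp(-cfg.bleach_rate_per_frame * f)
        spot[f] = float((lit & in_meas).sum()) * fade
        ref[f] = float(lit.sum()) * fade

    return IntensityTrace(
        frames=np.arange(cfg.n_frames),
        spot_raw=spot,
        reference_raw=ref,
        bleach_frame=cfg.bleach_frame,
        frame_interval=cfg.frame_interval,
        kind=kind,
    )


# ---------------------------------------------------------------------------
# FISH intensities
# ---------------------------------------------------------------------------


def simulate_fish_intensities(
    copy_numbers: dict[str, "list[int] | np.ndarray"],
    intensity_per_copy: float = 1000.0,
    cv: float = 0.3,
    n_paa: int = 50,
    volume_per_copy: float = 0.25,
    seed=0,
) -> pd.DataFrame:
    """Simulate per-compartment DNA FISH intensities.

    Each compartment's integrated intensity is ``copy_number ×
    Lognormal(mean=intensity_per_copy, CV=cv)``.  A PAA (replication-blocked)
    condition with copy number exactly 1 is always included, providing the
    single-genome calibration standard.

    Returns a table with columns ``rc_id, condition, integrated_intensity,
    volume, copy_number_true``.
    """
    if cv < 0:
        raise ConfigError("CV must be >= 0")
    if any(np.any(np.asarray(v) < 1) for v in copy_numbers.values()):
        raise ConfigError("copy numbers must be >= 1")
    rng = _rng(seed)

    def lognormal(mean, size):
        if cv == 0:
            return np.full(size, mean)
        s2 = np.log1p(cv**2)
        mu = np.log(mean) - s2 / 2
        return rng.lognormal(mu, np.sqrt(s2), size)

    conditions = {"PAA": np.ones(n_paa, dtype=int)}
    for cond, copies in copy_numbers.items():
        conditions[cond] = np.asarray(copies, dtype=int)

    rows = []
    for cond, copies in conditions.items():
        per_copy = lognormal(intensity_per_copy, len(copies))
        vol = copies * volume_per_copy * lognormal(1.0, len(copies))
        for i, (c, ipc, v) in enumerate(zip(copies, per_copy, vol)):
            rows.append(
                {
                    "rc_id": f"{cond}_rc{i:04d}",
                    "condition": cond,
                    "integrated_intensity": c * ipc,
                    "volume": v,
                    "copy_number_true": int(c),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disorder-score profiles
# ---------------------------------------------------------------------------


def simulate_disorder_scores(
    segments: list[tuple[int, float]],
    noise_sd: float = 0.0,
    seed=0,
    sequence_id: str = "synthetic",
) -> DisorderProfile:
    """Piecewise-constant disorder profile with truncated Gaussian noise.

    ``segments`` is a list of (length, mean score); the profile is their
    concatenation, plus N(0, noise_sd) noise clipped to [0, 1].
    """
    if any(length <= 0 for length, _ in segments):
        raise ConfigError("segment lengths must be positive")
    rng = _rng(seed)
    parts = [np.full(int(length), float(score)) for length, score in segments]
    scores = np.concatenate(parts)
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, len(scores))
    return DisorderProfile(sequence_id=sequence_id, scores=np.clip(scores, 0.0, 1.0))
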