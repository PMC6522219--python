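"""Two-state jump-length kinetic modelling.

The model assumes each molecule is either immobile ("bound", diffusion
coefficient D_bound absorbing residual chromatin motion) or freely diffusing
(D_free).  For a time lag t = n·Δt the squared jump length of a population
with diffusion coefficient D, observed with localization error σ, follows an
exponential with scale 4(D·t + σ²), giving the jump-length CDF

    P(r' <= r) = 1 − exp(−r² / (4(D·t + σ²))).

Fast molecules are progressively lost from the axial detection slab of depth
dZ (defocalization), so the free component's mixture weight at lag n is
down-weighted by the survival fraction Z_n of a molecule diffusing axially in
an absorbing slab, starting from a uniform axial position:

    Z_n(D, dZ, t) = Σ_{k odd} 8/(k²π²) · exp(−k²π²·D·t / dZ²).

The model is fitted to empirical jump-length CDFs jointly over lags 1..7 by
bounded least squares, each lag weighted by its jump count, with multiple
stratified restarts.  Per-condition uncertainty follows the subsampling
scheme used for sparse per-cell data: 15 cells are drawn without replacement,
pooled and fitted; the median and SD over 100 such resamples are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import Trajectory
from .tracking import LabeledTrajectory

DEFAULT_LAGS = tuple(range(1, 8))
DEFAULT_JUMPS_PER_TRAJ = 4

# fit bounds (µm²/s); localization error is fixed, not fitted
D_FREE_BOUNDS = (0.5, 25.0)
D_BOUND_BOUNDS = (1e-4, 0.08)
F_BOUND_BOUNDS = (0.0, 1.0)


class FitError(RuntimeError):
    """The optimizer failed to converge on every restart."""


@dataclass(frozen=True)
class TwoStateModelParams:
    """Parameter set of the two-state jump-length model."""

    F_bound: float
    D_free: float  # µm²/s
    D_bound: float  # µm²/s
    sigma_loc: float = 0.045  # µm, fixed
    dZ: float = 0.700  # µm
    frame_interval: float = 0.007447  # s

    def validate(self):
        if not F_BOUND_BOUNDS[0] <= self.F_bound <= F_BOUND_BOUNDS[1]:
            raise ValueError("F_bound out of [0, 1]")
        if not D_FREE_BOUNDS[0] <= self.D_free <= D_FREE_BOUNDS[1]:
            raise ValueError(f"D_free out of {D_FREE_BOUNDS}")
        if not D_BOUND_BOUNDS[0] <= self.D_bound <= D_BOUND_BOUNDS[1]:
            raise ValueError(f"D_bound out of {D_BOUND_BOUNDS}")
        return self


# ---------------------------------------------------------------------------
# jump statistics
# ---------------------------------------------------------------------------


@dataclass
class JumpLengthData:
    """Empirical jump lengths per time lag (1..7 frames).

    ``jumps[n]`` holds the retained jump lengths at lag n, after applying the
    per-trajectory cap (at most the first ``cap`` jumps of each trajectory at
    each lag).
    """

    jumps: dict[int, np.ndarray]
    n_trajectories: int
    cap: int = DEFAULT_JUMPS_PER_TRAJ
    frame_interval: float = 0.007447

    @property
    def counts(self) -> dict[int, int]:
        return {n: len(v) for n, v in self.jumps.items()}

    def ecdf(self, lag: int, grid: np.ndarray) -> np.ndarray:
        v = np.sort(self.jumps[lag])
        return np.searchsorted(v, grid, side="right") / len(v)


def trajectory_jumps(traj: Trajectory, lag: int, cap: int | None = None) -> np.ndarray:
    """Jump lengths at a given frame lag for one trajectory.

    A jump pairs localizations whose frame difference equals the lag exactly,
    so frame gaps are never silently spanned.  With a cap, only the first
    ``cap`` jumps (by start frame) are retained.
    """
    frames = traj.frames
    idx = np.searchsorted(frames, frames + lag)
    ok = idx < len(frames)
    ok[ok] = frames[idx[ok]] == frames[ok] + lag
    starts = np.flatnonzero(ok)
    if cap is not None:
        starts = starts[:cap]
    if starts.size == 0:
        return np.empty(0)
    return np.linalg.norm(traj.xy[idx[starts]] - traj.xy[starts], axis=1)


def compile_jump_statistics(
    trajs,
    lags=DEFAULT_LAGS,
    cap: int | None = DEFAULT_JUMPS_PER_TRAJ,
    frame_interval: float = 0.007447,
) -> "JumpLengthData | dict[str, JumpLengthData]":
    """Compile jump-length statistics, optionally split by compartment label.

    Accepts plain trajectories (returns one JumpLengthData) or labeled
    trajectories (returns a dict keyed by "inside"/"outside").
    """
    if trajs and isinstance(trajs[0], LabeledTrajectory):
        out = {}
        for label in ("inside", "outside"):
            subset = [lt.trajectory for lt in trajs if lt.label == label]
            if subset:
                out[label] = compile_jump_statistics(
                    subset, lags=lags, cap=cap, frame_interval=frame_interval
                )
        return out

    jumps: dict[int, list] = {n: [] for n in lags}
    for t in trajs:
        if len(t) < 2:
            continue
        for n in lags:
            v = trajectory_jumps(t, n, cap)
            if v.size:
                jumps[n].append(v)
    compiled = {}
    for n in lags:
        if jumps[n]:
            compiled[n] = np.concatenate(jumps[n])
        else:
            warnings.warn(f"no jumps at lag {n}; lag omitted")
    return JumpLengthData(
        jumps=compiled,
        n_trajectories=len(trajs),
        cap=cap if cap is not None else -1,
        frame_interval=frame_interval,
    )


# ---------------------------------------------------------------------------
# model CDF and defocalization
# ---------------------------------------------------------------------------


def defocalization_fraction(D: float, dZ: float, t: float, tol: float = 1e-10) -> float:
    """Survival probability of an axially diffusing molecule in an absorbing
    slab of depth dZ after time t, starting uniform in [−dZ/2, dZ/2].

    Computed from the eigenfunction series Σ_{k odd} 8/(k²π²)·exp(−k²π²Dt/dZ²),
    truncated once terms fall below ``tol``.
    """
    if D < 0 or dZ <= 0 or t <= 0:
        raise ValueError("need D >= 0, dZ > 0, t > 0")
    if D == 0:
        return 1.0
    a = np.pi**2 * D * t / dZ**2
    total = 0.0
    k = 1
    while True:
        term = 8.0 / (k**2 * np.pi**2) * np.exp(-(k**2) * a)
        total += term
        if term < tol:
            break
        k += 2
    return float(min(total, 1.0))


def lag_detection_weight(
    D: float, dZ: float, frame_interval: float, lag: int, cap: int = DEFAULT_JUMPS_PER_TRAJ
) -> float:
    """Expected number of observed lag-n jumps per molecule of diffusivity D.

    Jump statistics retain up to ``cap`` jumps per trajectory at each lag,
    anchored at the first ``cap`` start frames; the jump starting at frame s
    is observed iff the molecule is still within the detection slab at frame
    s + lag, which happens with probability Z_{s+lag}.  The per-lag mixture
    weight of a population is therefore Σ_{s<cap} Z_{s+lag}(D) rather than
    the single-window survival Z_lag; for cap = 1 the two coincide.
    """
    return sum(
        defocalization_fraction(D, dZ, (lag + s) * frame_interval)
        for s in range(max(cap, 1))
    )


def two_state_cdf(
    params: TwoStateModelParams, lag: int, r: np.ndarray,
    cap: int = DEFAULT_JUMPS_PER_TRAJ,
) -> np.ndarray:
    """Model jump-length CDF at a given frame lag.

    Mixture of the bound and free components, each weighted by its expected
    per-molecule jump count at this lag (defocalization-corrected via the
    absorbing-slab survival series) and renormalized to sum to one — each
    lag's empirical CDF is itself normalized.
    """
    params.validate()
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("r grid must be non-negative")
    t = lag * params.frame_interval
    s2 = params.sigma_loc**2
    w_b = params.F_bound * lag_detection_weight(
        params.D_bound, params.dZ, params.frame_interval, lag, cap
    )
    w_f = (1.0 - params.F_bound) * lag_detection_weight(
        params.D_free, params.dZ, params.frame_interval, lag, cap
    )
    norm = w_b + w_f
    if norm == 0:
        return np.zeros_like(r)
    cdf_b = 1.0 - np.exp(-(r**2) / (4.0 * (params.D_bound * t + s2)))
    cdf_f = 1.0 - np.exp(-(r**2) / (4.0 * (params.D_free * t + s2)))
    return (w_b * cdf_b + w_f * cdf_f) / norm


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


@dataclass
class TwoStateJumpResults:
    """Results of a two-state jump-length model fit."""

    params: TwoStateModelParams
    sse: float
    n_jumps: dict[int, int]
    n_trajectories: int
    n_restarts: int
    success: bool
    model: "TwoStateJumpModel" = field(repr=False, default=None)
    resampling: pd.DataFrame | None = field(repr=False, default=None)

    @property
    def F_bound(self) -> float:
        return self.params.F_bound

    @property
    def D_free(self) -> float:
        return self.params.D_free

    @property
    def D_bound(self) -> float:
        return self.params.D_bound

    def predict(self, lag: int, r: np.ndarray) -> np.ndarray:
        cap = self.model.cap if self.model is not None else DEFAULT_JUMPS_PER_TRAJ
        return two_state_cdf(self.params, lag, r, cap=cap)

    def summary(self) -> str:
        lines = [
            "Two-state jump-length model fit",
            "===============================",
            f"trajectories: {self.n_trajectories}",
            f"jumps per lag: {self.n_jumps}",
            f"restarts: {self.n_restarts}   converged: {self.success}",
            f"SSE: {self.sse:.6g}",
            "",
            f"  F_bound  = {self.params.F_bound:8.4f}",
            f"  D_free   = {self.params.D_free:8.4f} um^2/s",
            f"  D_bound  = {self.params.D_bound:8.4f} um^2/s",
            f"  sigma    = {self.params.sigma_loc:8.4f} um (fixed)",
            f"  dZ       = {self.params.dZ:8.4f} um (fixed)",
            f"  dt       = {self.params.frame_interval * 1e3:8.4f} ms (fixed)",
        ]
        if self.resampling is not None:
            lines.append("")
            lines.append("subsampling (median ± SD over resamples):")
            for p in ("F_bound", "D_free", "D_bound"):
                med = self.resampling[p].median()
                sd = self.resampling[p].std(ddof=1)
                lines.append(f"  {p:8s} = {med:8.4f} ± {sd:.4f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Empirical vs fitted CDFs per lag (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.data
        for lag in sorted(data.jumps):
            grid = np.linspace(0, data.jumps[lag].max(), 200)
            ax.step(grid, data.ecdf(lag, grid), where="post", alpha=0.5, lw=0.8)
            ax.plot(grid, self.predict(lag, grid), "k-", lw=0.8)
        ax.set_xlabel("jump length (µm)")
        ax.set_ylabel("CDF")
        return ax


class TwoStateJumpModel:
    """Two-state (bound/free) jump-length model for SPT data.

    Build from compiled jump statistics or directly from trajectories, then
    call :meth:`fit`.

    Parameters
    ----------
    data : JumpLengthData
        Empirical jump lengths per lag.
    sigma_loc, dZ : float
        Fixed localization error (µm) and detection-slab depth (µm).
    grid_max_points : int
        Each lag's empirical support is subsampled to at most this many grid
        points for the least-squares objective.
    """

    def __init__(
        self,
        data: JumpLengthData,
        sigma_loc: float = 0.045,
        dZ: float = 0.700,
        grid_max_points: int = 500,
        min_trajectories: int = 100,
        warn_trajectories: int = 1000,
    ):
        if data.n_trajectories < min_trajectories:
            raise ValueError(
                f"refusing to fit {data.n_trajectories} trajectories "
                f"(< {min_trajectories}); pool more cells"
            )
        if data.n_trajectories < warn_trajectories:
            warnings.warn(
                f"only {data.n_trajectories} trajectories; two-state fits are "
                f"reliable from ~{warn_trajectories} up"
            )
        self.data = data
        self.sigma_loc = sigma_loc
        self.dZ = dZ
        self.frame_interval = data.frame_interval
        self.cap = data.cap if data.cap > 0 else 1
        self._grids = {}
        self._targets = {}
        self._weights = {}
        total = sum(len(v) for v in data.jumps.values())
        for lag, v in data.jumps.items():
            grid = np.sort(np.unique(v))
            if len(grid) > grid_max_points:
                grid = grid[np.linspace(0, len(grid) - 1, grid_max_points).astype(int)]
            self._grids[lag] = grid
            self._targets[lag] = data.ecdf(lag, grid)
            self._weights[lag] = np.sqrt(len(v) / total / len(grid))

    @classmethod
    def from_trajectories(
        cls,
        trajs: list[Trajectory],
        lags=DEFAULT_LAGS,
        cap: int | None = DEFAULT_JUMPS_PER_TRAJ,
        frame_interval: float = 0.007447,
        **kwargs,
    ) -> "TwoStateJumpModel":
        data = compile_jump_statistics(
            trajs, lags=lags, cap=cap, frame_interval=frame_interval
        )
        return cls(data, **kwargs)

    def _params(self, x) -> TwoStateModelParams:
        return TwoStateModelParams(
            F_bound=float(x[0]),
            D_free=float(x[1]),
            D_bound=float(x[2]),
            sigma_loc=self.sigma_loc,
            dZ=self.dZ,
            frame_interval=self.frame_interval,
        )

    def _residuals(self, x) -> np.ndarray:
        p = self._params(x)
        parts = []
        for lag, grid in self._grids.items():
            model = two_state_cdf(p, lag, grid, cap=self.cap)
            parts.append((model - self._targets[lag]) * self._weights[lag])
        return np.concatenate(parts)

    def sse(self, params: TwoStateModelParams) -> float:
        """Weighted sum of squared CDF residuals for a given parameter set."""
        x = (params.F_bound, params.D_free, params.D_bound)
        r = self._residuals(x)
        return float(r @ r)

    def _effective_share(self, x, component: str) -> float:
        """Smallest per-lag mixture share of one component."""
        p = self._params(x)
        shares = []
        for lag in self._grids:
            w_b = p.F_bound * lag_detection_weight(
                p.D_bound, p.dZ, p.frame_interval, lag, self.cap
            )
            w_f = (1 - p.F_bound) * lag_detection_weight(
                p.D_free, p.dZ, p.frame_interval, lag, self.cap
            )
            total = w_b + w_f
            shares.append((w_f if component == "free" else w_b) / total
                          if total > 0 else 0.0)
        return max(shares) if shares else 0.0

    def _collapse_negligible_component(self, x, sse):
        """Parsimony rule at the mixture boundary.

        When defocalization weighting leaves one component with < 1% effective
        share at every lag, F_bound and the vanished component's D trade off
        along a ridge and are not identified; the fit then collapses to the
        single-state boundary (re-optimizing the surviving component's D).
        """
        for component, f_fixed in (("free", 1.0), ("bound", 0.0)):
            if self._effective_share(x, component) >= 0.01:
                continue
            if component == "free":
                def resid(d):
                    return self._residuals([1.0, x[1], d[0]])
                bounds = (D_BOUND_BOUNDS[0], D_BOUND_BOUNDS[1])
                res = least_squares(resid, [x[2]], bounds=bounds, xtol=1e-10,
                                    ftol=1e-10, gtol=1e-10)
                x_new = np.array([1.0, x[1], res.x[0]])
            else:
                def resid(d):
                    return self._residuals([0.0, d[0], x[2]])
                bounds = (D_FREE_BOUNDS[0], D_FREE_BOUNDS[1])
                res = least_squares(resid, [x[1]], bounds=bounds, xtol=1e-10,
                                    ftol=1e-10, gtol=1e-10)
                x_new = np.array([0.0, res.x[0], x[2]])
            return x_new, float(res.fun @ res.fun)
        return x, sse

    def fit(self, n_restarts: int = 4, seed: int = 0) -> TwoStateJumpResults:
        """Bounded least-squares fit with stratified random restarts.

        The first start is a stratified grid point; further starts are drawn
        uniformly within the bounds from the seeded generator.  The restart
        with the lowest SSE wins; deterministic given the seed.
        """
        rng = np.random.default_rng(seed)
        lo = np.array([F_BOUND_BOUNDS[0], D_FREE_BOUNDS[0], D_BOUND_BOUNDS[0]])
        hi = np.array([F_BOUND_BOUNDS[1], D_FREE_BOUNDS[1], D_BOUND_BOUNDS[1]])
        starts = [
            np.array([0.5, 3.0, 0.01]),
            np.array([0.2, 10.0, 0.001]),
            np.array([0.8, 1.0, 0.05]),
        ]
        while len(starts) < max(n_restarts, 3):
            starts.append(lo + rng.random(3) * (hi - lo))

        best = None
        n_ok = 0
        for x0 in starts[: max(n_restarts, 3)]:
            try:
                res = least_squares(
                    self._residuals, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10,
                    gtol=1e-10,
                )
            except Exception:
                continue
            if not res.success:
                continue
            n_ok += 1
            sse = float(res.fun @ res.fun)
            if best is None or sse < best[0]:
                best = (sse, res.x)
        if best is None:
            raise FitError(
                "optimizer failed on all restarts; "
                f"jump counts per lag: {self.data.counts}"
            )
        sse, x = best
        x, sse = self._collapse_negligible_component(x, sse)
        return TwoStateJumpResults(
            params=self._params(x).validate(),
            sse=sse,
            n_jumps=self.data.counts,
            n_trajectories=self.data.n_trajectories,
            n_restarts=len(starts[: max(n_restarts, 3)]),
            success=n_ok > 0,
            model=self,
        )


def fit_two_state(
    data: JumpLengthData,
    sigma_loc: float = 0.045,
    dZ: float = 0.700,
    n_restarts: int = 4,
    seed: int = 0,
) -> TwoStateJumpResults:
    """Convenience wrapper: fit the two-state model to compiled jump data."""
    return TwoStateJumpModel(data, sigma_loc=sigma_loc, dZ=dZ).fit(
        n_restarts=n_restarts, seed=seed
    )


# ---------------------------------------------------------------------------
# subsampled uncertainty
# ---------------------------------------------------------------------------


@dataclass
class SubsampleEstimate:
    """Median and SD of a fitted parameter over cell-level resamples."""

    median: float
    sd: float
    n_resamples: int
    cells_per_resample: int


def subsample_fit(
    per_cell_trajs: dict[str, list[Trajectory]],
    cells_per_resample: int = 15,
    n_resamples: int = 100,
    seed: int = 0,
    frame_interval: float = 0.007447,
    cap: int | None = DEFAULT_JUMPS_PER_TRAJ,
    sigma_loc: float = 0.045,
    dZ: float = 0.700,
    min_trajectories: int = 100,
) -> tuple[dict[str, SubsampleEstimate], pd.DataFrame]:
    """Random-subsampling uncertainty for the two-state fit.

    Per resample, ``cells_per_resample`` cells are drawn without replacement,
    their trajectories pooled and fitted; the median and SD of each parameter
    over ``n_resamples`` draws are reported.  Deterministic given the seed.
    """
    cells = sorted(per_cell_trajs)
    if len(cells) < cells_per_resample:
        raise ValueError(
            f"{len(cells)} cells available but cells_per_resample="
            f"{cells_per_resample}; lower cells_per_resample"
        )
    rng = np.random.default_rng(seed)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_resamples):
            chosen = rng.choice(cells, size=cells_per_resample, replace=False)
            pooled = [t for c in chosen for t in per_cell_trajs[c]]
            data = compile_jump_statistics(pooled, cap=cap, frame_interval=frame_interval)
            model = TwoStateJumpModel(
                data, sigma_loc=sigma_loc, dZ=dZ, min_trajectories=min_trajectories
            )
            res = model.fit(seed=int(rng.integers(2**31 - 1)))
            rows.append(
                {
                    "resample": i,
                    "F_bound": res.F_bound,
                    "D_free": res.D_free,
                    "D_bound": res.D_bound,
                    "sse": res.sse,
                    "n_trajectories": len(pooled),
                }
            )
    df = pd.DataFrame(rows)
    est = {
        p: SubsampleEstimate(
            median=float(df[p].median()),
            sd=float(df[p].std(ddof=1)) if len(df) > 1 else 0.0,
            n_resamples=n_resamples,
            cells_per_resample=cells_per_resample,
        )
        for p in ("F_bound", "D_free", "D_bound")
    }
    return est, df
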