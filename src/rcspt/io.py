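"""Domain types and file I/O.

Units and conventions
---------------------
Internal coordinates are always micrometres (µm), 2-D, origin at the image
top-left, y increasing downward.  Frames are 0-based integer indices; frame
intervals are half-open in time.  Localization tables arrive in pixels and are
converted on read via a mandatory ``pixel_size`` (µm/px).

File formats
------------
* localizations / trajectories: CSV (one row per localization; trajectory
  files carry ``traj_id, cell_id, frame, x_um, y_um``)
* annotations: polygon JSON, or a labeled 16-bit TIFF mask
  (0 = background, 1 = nucleus, >= 2 = compartments)
* intensity traces: CSV with ``frame, spot, reference``
* disorder scores: two-column TSV (residue index, score), IUPred-compatible
* protein sequences: FASTA
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GeometryError, PolygonRegion


class FormatError(ValueError):
    """File does not have the expected columns/structure."""


class ParseError(ValueError):
    """A row or value could not be parsed; message names the offending row."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Localization:
    """A single detection: position (µm), frame index and owning cell."""

    x: float
    y: float
    frame: int
    cell_id: str
    channel: str | None = None

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError("localization coordinates must be finite")
        if self.frame < 0:
            raise ValidationError("frame index must be >= 0")


@dataclass
class Trajectory:
    """An ordered sequence of localizations of one molecule.

    ``frames`` are strictly increasing; consecutive frame increments never
    exceed ``1 + max_gap`` (the linker may bridge up to ``max_gap`` missing
    frames).
    """

    traj_id: str
    cell_id: str
    frames: np.ndarray
    xy: np.ndarray
    max_gap: int = 1

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1 or len(self.frames) < 1:
            raise ValidationError(f"trajectory {self.traj_id}: needs >= 1 point")
        if self.xy.shape != (len(self.frames), 2):
            raise ValidationError(f"trajectory {self.traj_id}: frames/xy shape mismatch")
        d = np.diff(self.frames)
        if len(d) and (d < 1).any():
            raise ValidationError(
                f"trajectory {self.traj_id}: frames must be strictly increasing"
            )
        if len(d) and (d > 1 + self.max_gap).any():
            raise ValidationError(
                f"trajectory {self.traj_id}: frame gap exceeds max_gap={self.max_gap}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def points(self) -> list[Localization]:
        return [
            Localization(x=px, y=py, frame=int(f), cell_id=self.cell_id)
            for (px, py), f in zip(self.xy, self.frames)
        ]


@dataclass
class CellAnnotation:
    """Nucleus/compartment/nucleolus polygons with before/after drift anchors.

    ``*_before`` polygons are drawn on the first frames of the movie,
    ``*_after`` on the last; each compartment pair must have equal vertex
    counts so per-frame positions can be linearly interpolated.
    """

    cell_id: str
    nucleus_before: PolygonRegion
    nucleus_after: PolygonRegion
    compartments_before: list[PolygonRegion]
    compartments_after: list[PolygonRegion]
    nucleoli: list[PolygonRegion] = field(default_factory=list)
    n_frames: int = 1

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValidationError(f"cell {self.cell_id}: n_frames must be >= 1")
        if len(self.compartments_before) != len(self.compartments_after):
            raise ValidationError(
                f"cell {self.cell_id}: before/after compartment counts differ"
            )
        if len(self.nucleus_before.vertices) != len(self.nucleus_after.vertices):
            raise ValidationError(
                f"cell {self.cell_id}: nucleus before/after vertex counts differ"
            )
        for k, (b, a) in enumerate(
            zip(self.compartments_before, self.compartments_after)
        ):
            if len(b.vertices) != len(a.vertices):
                raise ValidationError(
                    f"cell {self.cell_id}: compartment {k} before/after "
                    f"vertex counts differ ({len(b.vertices)} vs {len(a.vertices)})"
                )

    @classmethod
    def static(cls, cell_id, nucleus, compartments=(), nucleoli=(), n_frames=1):
        """Annotation with no drift (before == after)."""
        return cls(
            cell_id=cell_id,
            nucleus_before=nucleus,
            nucleus_after=nucleus,
            compartments_before=list(compartments),
            compartments_after=list(compartments),
            nucleoli=list(nucleoli),
            n_frames=n_frames,
        )


@dataclass
class IntensityTrace:
    """Per-frame spot and reference intensities for FRAP/FLIP analysis."""

    frames: np.ndarray
    spot_raw: np.ndarray
    reference_raw: np.ndarray
    bleach_frame: int
    frame_interval: float  # seconds
    kind: str = "FRAP"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.spot_raw = np.asarray(self.spot_raw, dtype=float)
        self.reference_raw = np.asarray(self.reference_raw, dtype=float)
        n = len(self.frames)
        if not np.array_equal(self.frames, np.arange(n)):
            raise ValidationError("trace frames must be contiguous from 0")
        if (self.spot_raw < 0).any():
            raise ValidationError("spot intensities must be >= 0")
        if self.spot_raw.shape != (n,) or self.reference_raw.shape != (n,):
            raise ValidationError("trace arrays must have equal length")


@dataclass
class DisorderProfile:
    """Per-residue disorder likelihoods in [0, 1] for one protein."""

    sequence_id: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or len(self.scores) == 0:
            raise ValidationError("scores must be a non-empty 1-D array")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValidationError("disorder scores must lie in [0, 1]")

    @property
    def length(self) -> int:
        return len(self.scores)


# ---------------------------------------------------------------------------
# localization tables
# ---------------------------------------------------------------------------

DEFAULT_DIALECT = {
    "x": "x",
    "y": "y",
    "frame": "frame",
    "cell_id": "cell_id",
    "pixel_size": 1.0,  # µm per pixel; 1.0 means coordinates already in µm
}


def read_localizations(path, dialect: dict) -> dict[str, pd.DataFrame]:
    """Read a localization table, converting pixel coordinates to µm.

    Parameters
    ----------
    path : str or file-like
        CSV file with one row per detection.
    dialect : dict
        Column mapping with keys ``x``, ``y``, ``frame``, ``cell_id`` and the
        mandatory ``pixel_size`` (µm/px).

    Returns
    -------
    dict mapping cell_id -> DataFrame with columns ``x, y, frame`` (µm).
    """
    d = {**DEFAULT_DIALECT, **dialect}
    df = pd.read_csv(path)
    for key in ("x", "y", "frame"):
        if d[key] not in df.columns:
            raise FormatError(f"missing column {d[key]!r} in localization table")
    if d["cell_id"] not in df.columns:
        df[d["cell_id"]] = "cell0"
    px = float(d["pixel_size"])

    out: dict[str, pd.DataFrame] = {}
    if df.empty:
        return out
    for col in ("x", "y", "frame"):
        vals = pd.to_numeric(df[d[col]], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise ParseError(
                f"non-numeric value in column {d[col]!r} at row {bad[0]}"
            )
        df[d[col]] = vals
    neg = np.flatnonzero((df[d["frame"]] < 0).to_numpy())
    if neg.size:
        raise ParseError(f"negative frame index at row {neg[0]}")
    for cell, grp in df.groupby(d["cell_id"], sort=True):
        out[str(cell)] = pd.DataFrame(
            {
                "x": grp[d["x"]].to_numpy(float) * px,
                "y": grp[d["y"]].to_numpy(float) * px,
                "frame": grp[d["frame"]].to_numpy(int),
            }
        ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def _poly(obj) -> PolygonRegion:
    try:
        return PolygonRegion(np.asarray(obj, dtype=float))
    except GeometryError as e:
        raise ValidationError(str(e)) from e


def read_annotations(path) -> list[CellAnnotation]:
    """Read cell annotations from polygon JSON.

    The JSON layout is ``{"cells": [{"cell_id", "n_frames", "nucleus_before",
    "nucleus_after", "compartments_before", "compartments_after",
    "nucleoli"}]}`` with each polygon an array of [x, y] pairs in µm.
    A missing ``*_after`` entry defaults to its ``*_before`` partner
    (static annotation).
    """
    if hasattr(path, "read"):
        doc = json.load(path)
    else:
        with open(path) as fh:
            doc = json.load(fh)
    cells = []
    for rec in doc["cells"]:
        nb = _poly(rec["nucleus_before"])
        na = _poly(rec.get("nucleus_after", rec["nucleus_before"]))
        cb = [_poly(p) for p in rec.get("compartments_before", [])]
        ca_src = rec.get("compartments_after", rec.get("compartments_before", []))
        ca = [_poly(p) for p in ca_src]
        nucleoli = [_poly(p) for p in rec.get("nucleoli", [])]
        cells.append(
            CellAnnotation(
                cell_id=str(rec["cell_id"]),
                nucleus_before=nb,
                nucleus_after=na,
                compartments_before=cb,
                compartments_after=ca,
                nucleoli=nucleoli,
                n_frames=int(rec.get("n_frames", 1)),
            )
        )
    return cells


def write_annotations(cells: list[CellAnnotation], path) -> None:
    doc = {
        "cells": [
            {
                "cell_id": c.cell_id,
                "n_frames": c.n_frames,
                "nucleus_before": c.nucleus_before.vertices.tolist(),
                "nucleus_after": c.nucleus_after.vertices.tolist(),
                "compartments_before": [p.vertices.tolist() for p in c.compartments_before],
                "compartments_after": [p.vertices.tolist() for p in c.compartments_after],
                "nucleoli": [p.vertices.tolist() for p in c.nucleoli],
            }
            for c in cells
        ]
    }
    if hasattr(path, "write"):
        json.dump(doc, path)
    else:
        with open(path, "w") as fh:
            json.dump(doc, fh)


def read_annotation_mask(path, pixel_size: float, cell_id: str = "cell0",
                         n_frames: int = 1) -> CellAnnotation:
    """Build a static CellAnnotation from a labeled TIFF mask.

    Label 0 is background, 1 the nucleus, labels >= 2 compartments.  Each
    label's largest contour is traced and converted to a polygon in µm.
    """
    import tifffile
    from skimage import measure

    img = tifffile.imread(path)
    if img.ndim != 2:
        raise FormatError("mask must be a single-plane labeled image")

    def label_polygon(label):
        binary = (img == label).astype(float)
        contours = measure.find_contours(binary, 0.5)
        if not contours:
            return None
        contour = max(contours, key=len)
        # find_contours returns (row, col); convert to (x, y) µm
        xy = np.column_stack([contour[:, 1], contour[:, 0]]) * pixel_size
        # decimate closed contour to its vertices (drop the repeated endpoint)
        if np.allclose(xy[0], xy[-1]):
            xy = xy[:-1]
        return PolygonRegion(xy)

    nucleus = label_polygon(1)
    if nucleus is None:
        raise ValidationError("mask has no nucleus label (1)")
    comps = []
    for label in range(2, int(img.max()) + 1):
        p = label_polygon(label)
        if p is not None:
            comps.append(p)
    return CellAnnotation.static(
        cell_id, nucleus, compartments=comps, n_frames=n_frames
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = ["traj_id", "cell_id", "frame", "x_um", "y_um"]


def write_trajectories(trajs: list[Trajectory], path) -> None:
    """Write trajectories as CSV, one row per localization.

    Coordinates are written with full float precision so that a read/write
    round trip is the identity (<= 1e-9 µm).
    """
    rows = {c: [] for c in _TRAJ_COLUMNS}
    for t in trajs:
        for (x, y), f in zip(t.xy, t.frames):
            rows["traj_id"].append(t.traj_id)
            rows["cell_id"].append(t.cell_id)
            rows["frame"].append(int(f))
            rows["x_um"].append(x)
            rows["y_um"].append(y)
    pd.DataFrame(rows, columns=_TRAJ_COLUMNS).to_csv(path, index=False)


def read_trajectories(path, max_gap: int = 1) -> list[Trajectory]:
    """Read trajectories written by :func:`write_trajectories`."""
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trajectory file missing columns {missing}")
    out = []
    if df.empty:
        return out
    for (tid, cid), grp in df.groupby(["traj_id", "cell_id"], sort=False):
        grp = grp.sort_values("frame")
        out.append(
            Trajectory(
                traj_id=str(tid),
                cell_id=str(cid),
                frames=grp["frame"].to_numpy(int),
                xy=grp[["x_um", "y_um"]].to_numpy(float),
                max_gap=max_gap,
            )
        )
    return out


def trajectories_to_frame(trajs: list[Trajectory]) -> pd.DataFrame:
    """Flatten trajectories into a long DataFrame (one row per localization)."""
    if not trajs:
        return pd.DataFrame(columns=_TRAJ_COLUMNS)
    parts = []
    for t in trajs:
        parts.append(
            pd.DataFrame(
                {
                    "traj_id": t.traj_id,
                    "cell_id": t.cell_id,
                    "frame": t.frames,
                    "x_um": t.xy[:, 0],
                    "y_um": t.xy[:, 1],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# traces, scores, sequences
# ---------------------------------------------------------------------------


def write_trace(trace: IntensityTrace, path) -> None:
    pd.DataFrame(
        {"frame": trace.frames, "spot": trace.spot_raw, "reference": trace.reference_raw}
    ).to_csv(path, index=False)


def read_trace(path, bleach_frame: int, frame_interval: float,
               kind: str = "FRAP") -> IntensityTrace:
    df = pd.read_csv(path)
    for col in ("frame", "spot", "reference"):
        if col not in df.columns:
            raise FormatError(f"trace file missing column {col!r}")
    return IntensityTrace(
        frames=df["frame"].to_numpy(int),
        spot_raw=df["spot"].to_numpy(float),
        reference_raw=df["reference"].to_numpy(float),
        bleach_frame=bleach_frame,
        frame_interval=frame_interval,
        kind=kind,
    )


def read_disorder_scores(path, sequence_id: str | None = None) -> DisorderProfile:
    """Read a two-column TSV (residue index, score), IUPred output compatible.

    Lines starting with '#' are ignored; residue indices must be 1..L in order.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 2:
        raise FormatError("disorder score file needs two columns (index, score)")
    idx = df.iloc[:, 0].to_numpy(int)
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValidationError("residue indices must run 1..L consecutively")
    name = sequence_id or (str(path) if not hasattr(path, "read") else "seq")
    return DisorderProfile(sequence_id=name, scores=df.iloc[:, 1].to_numpy(float))


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
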