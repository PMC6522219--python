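"""FRAP and FLIP trace normalization, photobleaching correction and
aggregation.

FRAP traces are first internally normalized to a whole-nucleus reference
(cancelling acquisition photobleaching), then scaled so the pre-bleach mean
over the first ``pre_frames`` frames is 1.  FLIP traces have no internal
reference; instead the global photobleaching is divided out with an
empirically determined exponential (default rate 0.09 per frame), then the
trace is normalized to its initial value.  Spot extraction from raw movies is
an upstream contract: this module consumes per-frame spot/reference
intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import IntensityTrace

FLIP_BLEACH_RATE = 0.09  # per frame
FRAP_PRE_FRAMES = 15


@dataclass
class RecoveryCurve:
    """Aggregated recovery/loss curve: pointwise mean flanked by SEM."""

    time: np.ndarray  # seconds
    mean: np.ndarray
    sem: np.ndarray
    n_cells: int
    kind: str


def normalize_frap(trace: IntensityTrace, pre_frames: int = FRAP_PRE_FRAMES) -> np.ndarray:
    """Doubly normalized FRAP trace.

    corrected = spot/reference (removes photobleaching), then divided by the
    mean corrected value over frames 0..pre_frames−1, so the pre-bleach level
    is 1 by construction.
    """
    if (trace.reference_raw == 0).any():
        raise ZeroDivisionError("reference trace contains zeros")
    if trace.bleach_frame != pre_frames:
        warnings.warn(
            f"bleach_frame={trace.bleach_frame} differs from pre_frames={pre_frames}"
        )
    corrected = trace.spot_raw / trace.reference_raw
    baseline = corrected[:pre_frames].mean()
    if baseline == 0:
        raise ZeroDivisionError("pre-bleach baseline is zero")
    return corrected / baseline


def normalize_flip(trace: IntensityTrace, bleach_rate: float = FLIP_BLEACH_RATE) -> np.ndarray:
    """Photobleach-corrected, initial-value-normalized FLIP trace.

    corrected = spot / exp(−bleach_rate·frame); the measurement spot must be
    well away from the bleach spot so the exponential captures only global
    acquisition photobleaching.
    """
    corrected = trace.spot_raw / np.exp(-bleach_rate * trace.frames)
    if corrected[0] == 0:
        raise ZeroDivisionError("initial FLIP intensity is zero")
    return corrected / corrected[0]


def aggregate_curves(
    normalized: list[np.ndarray],
    frame_interval: float,
    kind: str = "FRAP",
) -> RecoveryCurve:
    """Pointwise mean and SEM (= SD/sqrt(n)) over equal-length traces."""
    lengths = {len(v) for v in normalized}
    if len(lengths) != 1:
        raise ValueError(f"traces have unequal lengths: {sorted(lengths)}")
    arr = np.asarray(normalized, dtype=float)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sem = (arr.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else np.zeros(arr.shape[1])
    time = np.arange(arr.shape[1]) * frame_interval
    return RecoveryCurve(time=time, mean=mean, sem=sem, n_cells=n, kind=kind)
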