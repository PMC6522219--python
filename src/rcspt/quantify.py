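"""Genome-budget bookkeeping: FISH copy numbers, DNA concentrations,
accessibility enrichment, MOI estimation and compartment shape metrics.

Viral genome copy numbers are calibrated against a replication-blocked (PAA)
condition in which each fluorescent punctum contains exactly one genome: the
copy number of a compartment is its integrated FISH intensity divided by the
PAA median.  The budget arithmetic compares total viral base pairs against a
diploid host genome (2 × 3.2e9 bp), derives concentrations from measured
volumes, and expresses chromatin accessibility as the ratio of the viral
ATAC-seq read percentage to the viral share of total DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import PolygonRegion

HOST_GENOME_BP = 3.2e9  # haploid human genome
HOST_PLOIDY = 2  # calculations assume a diploid cell
VIRAL_GENOME_BP = 1.5e5  # HSV1


class BudgetError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FISH copy numbers
# ---------------------------------------------------------------------------


def estimate_copy_number(measurements: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-compartment genome copy numbers from FISH intensities.

    ``measurements`` needs columns ``condition`` and ``integrated_intensity``
    and must include a "PAA" condition (single-genome calibration).  Returns
    the table with an added ``copy_number`` column and the per-condition
    medians.  Copy numbers are invariant to global intensity rescaling.
    """
    if "PAA" not in set(measurements["condition"]):
        raise BudgetError("PAA calibration condition missing")
    paa_median = measurements.loc[
        measurements["condition"] == "PAA", "integrated_intensity"
    ].median()
    if paa_median <= 0:
        raise BudgetError("PAA median intensity must be positive")
    out = measurements.copy()
    out["copy_number"] = out["integrated_intensity"] / paa_median
    medians = out.groupby("condition")["copy_number"].median()
    return out, medians


# ---------------------------------------------------------------------------
# genome budget (Table-style arithmetic)
# ---------------------------------------------------------------------------


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (presentation only)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1))


@dataclass
class GenomeBudget:
    """Host/viral DNA bookkeeping for one condition (full precision)."""

    copy_number: float
    host_genome_bp: float = HOST_GENOME_BP
    host_ploidy: int = HOST_PLOIDY
    viral_genome_bp: float = VIRAL_GENOME_BP
    nucleus_volume: float | None = None  # µm³
    rc_volume: float | None = None  # µm³, total compartment volume per cell
    atac_viral_read_pct: float | None = None

    @property
    def total_host_bp(self) -> float:
        return self.host_genome_bp * self.host_ploidy

    @property
    def total_viral_bp(self) -> float:
        return self.copy_number * self.viral_genome_bp

    @property
    def percent_viral(self) -> float:
        return 100.0 * self.total_viral_bp / (self.total_host_bp + self.total_viral_bp)

    @property
    def genome_size_ratio(self) -> float:
        """Host / viral genome length."""
        return self.host_genome_bp / self.viral_genome_bp

    @property
    def host_concentration(self) -> float | None:
        if self.nucleus_volume is None:
            return None
        return self.total_host_bp / self.nucleus_volume

    @property
    def viral_concentration(self) -> float | None:
        if self.rc_volume is None:
            return None
        return self.total_viral_bp / self.rc_volume

    @property
    def concentration_ratio(self) -> float | None:
        """Host over viral DNA concentration."""
        hc, vc = self.host_concentration, self.viral_concentration
        if hc is None or vc is None:
            return None
        return hc / vc

    @property
    def fold_enrichment(self) -> float | None:
        """ATAC read percentage over the viral share of total DNA."""
        if self.atac_viral_read_pct is None:
            return None
        if self.percent_viral == 0:
            return None  # undefined for zero viral DNA; flagged by caller
        return atac_enrichment(self.atac_viral_read_pct, self.percent_viral)

    def summary(self, sig: int = 2) -> dict:
        """Presentation-rounded budget (2 significant figures, like a table)."""
        vals = {
            "host_genome_bp": self.total_host_bp,
            "viral_genome_bp": self.viral_genome_bp,
            "copy_number": self.copy_number,
            "total_viral_bp": self.total_viral_bp,
            "percent_viral": self.percent_viral,
            "genome_size_ratio": self.genome_size_ratio,
            "host_concentration": self.host_concentration,
            "viral_concentration": self.viral_concentration,
            "concentration_ratio": self.concentration_ratio,
            "atac_viral_read_pct": self.atac_viral_read_pct,
            "fold_enrichment": self.fold_enrichment,
        }
        return {k: (round_sig(v, sig) if v is not None else None) for k, v in vals.items()}


def genome_budget(
    copy_number: float,
    nucleus_volume: float | None = None,
    rc_volume: float | None = None,
    atac_viral_read_pct: float | None = None,
    **kwargs,
) -> GenomeBudget:
    """Build a :class:`GenomeBudget`; volumes in µm³, percentages in 0–100."""
    if copy_number < 0:
        raise BudgetError("copy number must be >= 0")
    for name, v in (("nucleus_volume", nucleus_volume), ("rc_volume", rc_volume)):
        if v is not None and v <= 0:
            raise BudgetError(f"{name} must be positive")
    return GenomeBudget(
        copy_number=copy_number,
        nucleus_volume=nucleus_volume,
        rc_volume=rc_volume,
        atac_viral_read_pct=atac_viral_read_pct,
        **kwargs,
    )


def atac_enrichment(viral_read_pct: float, percent_viral: float) -> float:
    """Fold accessibility enrichment: ATAC read % over DNA %."""
    if percent_viral <= 0:
        raise BudgetError("percent_viral must be positive")
    return viral_read_pct / percent_viral


# ---------------------------------------------------------------------------
# MOI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MoiEstimate:
    f_uninfected: float
    moi: float

    def pmf(self, k: int) -> float:
        """Poisson probability of k infection events per cell."""
        from scipy.stats import poisson

        return float(poisson.pmf(k, self.moi))


def estimate_moi(n_uninfected: int, n_total: int) -> MoiEstimate:
    """Poisson MOI from the uninfected fraction: MOI = −ln(f_uninfected)."""
    if not 0 < n_uninfected <= n_total:
        raise ValueError(
            "need 0 < n_uninfected <= n_total (all cells infected gives an "
            "infinite MOI estimate; count more cells or dilute)"
        )
    f = n_uninfected / n_total
    return MoiEstimate(f_uninfected=f, moi=float(-np.log(f)))


# ---------------------------------------------------------------------------
# shape metrics
# ---------------------------------------------------------------------------


def feret_diameters(region: PolygonRegion) -> tuple[float, float]:
    """(max, min) Feret diameters of a polygon via rotating calipers.

    The max Feret diameter is the largest pairwise distance between convex
    hull vertices; the min is the smallest width over all hull-edge
    directions.
    """
    from scipy.spatial import ConvexHull

    pts = region.vertices
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    # max: largest pairwise distance
    d2 = ((hp[:, None, :] - hp[None, :, :]) ** 2).sum(-1)
    dmax = float(np.sqrt(d2.max()))
    # min: smallest projected width across hull edge normals
    edges = np.roll(hp, -1, axis=0) - hp
    norms = np.linalg.norm(edges, axis=1)
    ok = norms > 0
    normals = np.column_stack([-edges[ok, 1], edges[ok, 0]]) / norms[ok, None]
    proj = hp @ normals.T  # (n_vertices, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return dmax, float(widths.min())


def shape_metrics(region: PolygonRegion) -> dict:
    """Aspect ratio (max/min Feret diameter, >= 1) and the diameters."""
    dmax, dmin = feret_diameters(region)
    if dmin <= 0:
        raise ValueError("degenerate polygon: zero minimal width")
    return {"aspect_ratio": dmax / dmin, "feret_max": dmax, "feret_min": dmin}
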