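"""Configuration-driven orchestration of the analysis stages.

A single global seed deterministically spawns per-stage substreams, so a run
with the same config and seed reproduces its text outputs bit for bit.  Every
parameter consumed is echoed to the run log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import anisotropy as aniso
from . import disorder as dis
from . import io, kinetics, photokinetics, quantify, simulate, spatial, tracking
from .geometry import PolygonRegion, regular_polygon

logger = logging.getLogger("rcspt")

# stage order also fixes the seed-substream assignment
STAGES = (
    "simulate",
    "assign",
    "kinetics",
    "mocknull",
    "anisotropy",
    "ripley",
    "frap",
    "flip",
    "disorder",
    "quantify",
)


def demo_config(outdir: str = "rcspt_demo") -> dict:
    """A small end-to-end demo configuration (runs in well under 5 minutes)."""
    return {
        "seed": 7,
        "outdir": outdir,
        "geometry": {
            "nucleus_radius": 5.0,
            "compartments": [
                {"cx": -2.0, "cy": 0.0, "r": 1.2},
                {"cx": 2.5, "cy": 1.0, "r": 0.9},
            ],
        },
        "simulate": {
            "n_trajectories": 3000,
            "F_bound": 0.5,
            "D_free": 3.5,
            "D_bound": 0.005,
            "sigma_loc": 0.045,
            "frame_interval": 0.007447,
            "dZ": 0.700,
            "n_frames": 8,
        },
        "kinetics": {"cap": 4, "lags": 7, "resamples": 0, "cells": 15},
        "mocknull": {"enabled": False, "n_mocks": 2},
        "anisotropy": {"min_jump": 0.150, "wedge": 30.0},
        # radii stay well below the compartment size: edge weights blow up
        # once circles routinely exceed the region
        "ripley": {
            "n_points": 800,
            "radii": [0.02, 0.3, 15],
            "envelope_sims": 20,
            "subsample": {"n_points": 25000, "n_draws": 10},
        },
        "frap": {"enabled": True, "n_molecules": 3000, "F_bound": 0.5,
                  "n_frames": 80},
        "flip": {"enabled": True, "bleach_rate": 0.09, "n_frames": 80},
        "disorder": {
            "enabled": True,
            "segments": [[60, 0.8], [100, 0.3], [40, 0.9]],
            "noise_sd": 0.05,
        },
        "quantify": {
            "enabled": True,
            "copy_numbers": {"6hpi": [30, 47, 60, 82, 100]},
            "cv": 0.3,
            "nucleus_volume": 680.0,
            "rc_volume": 315.0,
            "atac_viral_read_pct": 24.2,
        },
    }


def _geometry(cfg: dict) -> tuple[PolygonRegion, list[PolygonRegion]]:
    g = cfg.get("geometry", {})
    nucleus = regular_polygon(48, g.get("nucleus_radius", 5.0))
    comps = [
        regular_polygon(32, c["r"], c["cx"], c["cy"])
        for c in g.get("compartments", [])
    ]
    return nucleus, comps


def _dump(obj, path: Path):
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


def run_pipeline(config: dict) -> Path:
    """Run the configured stages; returns the results directory.

    Writes versioned JSON/CSV outputs plus ``run.log`` (seed and full
    parameter echo).  A stage failure aborts with the stage name; outputs of
    completed stages are preserved.
    """
    outdir = Path(config.get("outdir", "rcspt_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    substreams = {
        name: int(ss.generate_state(1)[0] % (2**31 - 1))
        for name, ss in zip(STAGES, np.random.SeedSequence(seed).spawn(len(STAGES)))
    }

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("global seed: %d", seed)
    logger.info("config echo: %s", json.dumps(config, sort_keys=True))
    logger.info("stage substreams: %s", substreams)

    stage = "setup"
    try:
        nucleus, comps = _geometry(config)
        ann = io.CellAnnotation.static("cell0", nucleus, compartments=comps)

        # --- simulate -----------------------------------------------------
        stage = "simulate"
        sim_cfg = simulate.SpaSptSimConfig(
            nucleus=nucleus,
            compartments=comps,
            seed=substreams["simulate"],
            **config.get("simulate", {}),
        )
        trajs, truth = simulate.simulate_spaspt(sim_cfg)
        io.write_trajectories(trajs, outdir / "trajectories.csv")
        truth.labels.to_csv(outdir / "truth.csv", index=False)
        io.write_annotations([ann], outdir / "annotations.json")
        logger.info("simulate: %d trajectories", len(trajs))

        # --- assign -------------------------------------------------------
        stage = "assign"
        labeled = tracking.assign_compartments(trajs, ann)
        lab_df = pd.DataFrame(
            {
                "traj_id": [lt.trajectory.traj_id for lt in labeled],
                "label": [lt.label for lt in labeled],
            }
        )
        lab_df.to_csv(outdir / "labels.csv", index=False)
        logger.info(
            "assign: %d inside / %d outside",
            (lab_df["label"] == "inside").sum(),
            (lab_df["label"] == "outside").sum(),
        )

        # --- kinetics -----------------------------------------------------
        stage = "kinetics"
        kcfg = config.get("kinetics", {})
        lags = tuple(range(1, kcfg.get("lags", 7) + 1))
        fits = {}
        for label in ("inside", "outside"):
            subset = [lt.trajectory for lt in labeled if lt.label == label]
            if len(subset) < 100:
                logger.warning("kinetics: too few %s trajectories, skipped", label)
                continue
            data = kinetics.compile_jump_statistics(
                subset, lags=lags, cap=kcfg.get("cap", 4),
                frame_interval=sim_cfg.frame_interval,
            )
            res = kinetics.TwoStateJumpModel(
                data, sigma_loc=sim_cfg.sigma_loc, dZ=sim_cfg.dZ
            ).fit(seed=substreams["kinetics"])
            fits[label] = {
                "F_bound": res.F_bound,
                "D_free": res.D_free,
                "D_bound": res.D_bound,
                "sse": res.sse,
                "n_trajectories": res.n_trajectories,
            }
            logger.info("kinetics %s: %s", label, fits[label])
        _dump(fits, outdir / "kinetics.json")

        # --- mock-compartment null ----------------------------------------
        stage = "mocknull"
        mcfg = config.get("mocknull", {})
        if mcfg.get("enabled", False):
            bare = io.CellAnnotation.static("cell0", nucleus)
            mock_ann = tracking.place_mock_compartments(
                comps, mcfg.get("n_mocks", len(comps)), bare,
                seed=substreams["mocknull"],
            )
            mock_labeled = tracking.assign_compartments(trajs, mock_ann)
            mock_fits = {}
            for label in ("inside", "outside"):
                subset = [lt.trajectory for lt in mock_labeled if lt.label == label]
                if len(subset) < 100:
                    continue
                data = kinetics.compile_jump_statistics(
                    subset, lags=lags, cap=kcfg.get("cap", 4),
                    frame_interval=sim_cfg.frame_interval,
                )
                res = kinetics.TwoStateJumpModel(
                    data, sigma_loc=sim_cfg.sigma_loc, dZ=sim_cfg.dZ
                ).fit(seed=substreams["mocknull"])
                mock_fits[label] = {"F_bound": res.F_bound, "D_free": res.D_free}
            _dump(mock_fits, outdir / "mocknull.json")
            logger.info("mocknull: %s", mock_fits)

        # --- anisotropy ----------------------------------------------------
        stage = "anisotropy"
        acfg = config.get("anisotropy", {})
        triples = aniso.filter_mobile_segments(
            labeled, min_jump=acfg.get("min_jump", 0.150)
        )
        angles = aniso.compute_angles(triples, ann)
        aniso.angle_histogram(angles).to_csv(outdir / "angles.csv", index=False)
        folds = {}
        for region, grp in angles.groupby("region"):
            if (grp["theta"] <= acfg.get("wedge", 30.0)).sum() == 0:
                continue
            f = aniso.fold_anisotropy(
                grp, wedge=acfg.get("wedge", 30.0), seed=substreams["anisotropy"]
            )
            folds[region] = {
                "f_180_0": f.f_180_0,
                "bootstrap_sd": f.bootstrap_sd,
                "n_backward": f.n_backward,
                "n_forward": f.n_forward,
            }
        _dump(folds, outdir / "anisotropy.json")
        logger.info("anisotropy: %s", folds)

        # --- Ripley -------------------------------------------------------
        stage = "ripley"
        rcfg = config.get("ripley", {})
        lo, hi, num = rcfg.get("radii", [0.05, 1.0, 20])
        radii = np.linspace(lo, hi, int(num))
        region = comps[0] if comps else nucleus
        pts = simulate.simulate_point_pattern(
            region, "csr", n_points=rcfg.get("n_points", 2000),
            seed=substreams["ripley"],
        )
        pattern = spatial.PointPattern(pts, region)
        sub = rcfg.get("subsample", {})
        curve = spatial.subsample_detections(
            pattern, radii, n_points=sub.get("n_points", 25000),
            n_draws=sub.get("n_draws", 10), seed=substreams["ripley"],
        )
        env = spatial.csr_envelope(
            region, pattern.n_points, radii,
            n_sims=rcfg.get("envelope_sims", 20), seed=substreams["ripley"] + 1,
        )
        pd.DataFrame(
            {
                "radius_um": radii,
                "l_minus_r": curve.l_minus_r,
                "sd": curve.sd,
                "csr_lo": env["lo"],
                "csr_hi": env["hi"],
            }
        ).to_csv(outdir / "ripley.csv", index=False)
        logger.info("ripley: %d points, %d radii", pattern.n_points, len(radii))

        # --- FRAP / FLIP ----------------------------------------------------
        for stage in ("frap", "flip"):
            pcfg = config.get(stage, {})
            if not pcfg.get("enabled", False):
                continue
            rec_cfg = simulate.RecoverySimConfig(
                n_molecules=pcfg.get("n_molecules", 3000),
                F_bound=pcfg.get("F_bound", 0.0),
                D_free=pcfg.get("D_free", 3.5),
                nucleus=nucleus,
                n_frames=pcfg.get("n_frames", 80),
                bleach_rate_per_frame=pcfg.get("bleach_rate", 0.0)
                if stage == "flip" else 0.0,
                measure_center=(2.0, 2.0) if stage == "flip" else None,
                seed=substreams[stage],
            )
            trace = simulate.simulate_recovery(stage.upper(), rec_cfg)
            if stage == "frap":
                norm = photokinetics.normalize_frap(trace)
            else:
                norm = photokinetics.normalize_flip(
                    trace, bleach_rate=pcfg.get("bleach_rate", 0.09)
                )
            curve = photokinetics.aggregate_curves(
                [norm], rec_cfg.frame_interval, kind=stage.upper()
            )
            pd.DataFrame(
                {"time_s": curve.time, "mean": curve.mean, "sem": curve.sem}
            ).to_csv(outdir / f"{stage}.csv", index=False)
            logger.info("%s: %d frames", stage, len(curve.time))

        # --- disorder -------------------------------------------------------
        stage = "disorder"
        dcfg = config.get("disorder", {})
        if dcfg.get("enabled", False):
            profile = simulate.simulate_disorder_scores(
                [tuple(s) for s in dcfg.get("segments", [[100, 0.8]])],
                noise_sd=dcfg.get("noise_sd", 0.0),
                seed=substreams["disorder"],
            )
            summary = dis.disorder_pipeline(profile)
            _dump(
                {
                    "fraction_idr": summary.fraction_idr,
                    "n_segments": summary.n_segments,
                    "segments": [
                        {"start": s.start, "end": s.end, "qualifying": s.qualifying}
                        for s in summary.segments
                    ],
                },
                outdir / "disorder.json",
            )
            logger.info("disorder: fraction_idr=%.3f", summary.fraction_idr)

        # --- quantify -------------------------------------------------------
        stage = "quantify"
        qcfg = config.get("quantify", {})
        if qcfg.get("enabled", False):
            fish = simulate.simulate_fish_intensities(
                {k: v for k, v in qcfg.get("copy_numbers", {}).items()},
                cv=qcfg.get("cv", 0.3),
                seed=substreams["quantify"],
            )
            table, medians = quantify.estimate_copy_number(fish)
            table.to_csv(outdir / "fish.csv", index=False)
            cond = max(medians.index.drop("PAA"), key=str) if len(medians) > 1 else "PAA"
            budget = quantify.genome_budget(
                copy_number=float(medians[cond]),
                nucleus_volume=qcfg.get("nucleus_volume"),
                rc_volume=qcfg.get("rc_volume"),
                atac_viral_read_pct=qcfg.get("atac_viral_read_pct"),
            )
            _dump(budget.summary(), outdir / "budget.json")
            logger.info("quantify: medians=%s", medians.to_dict())
    except Exception:
        logger.exception("stage %r failed; partial outputs kept in %s", stage, outdir)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from None
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
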