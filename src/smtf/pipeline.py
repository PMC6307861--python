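"""Stage runner chaining the analysis modules from a single config.

Each stage reads its inputs from paths declared in the config, writes
its outputs (CSV/TIFF/JSON) under an output directory, and embeds the
config hash and seed in its JSON report so re-runs are attributable and
reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile

from . import frap as frap_mod
from . import hubs as hubs_mod
from . import kinetics, locus, msd, simulate, tracking
from .io import (
    Movie,
    PipelineConfig,
    read_movie,
    read_trajectories,
    write_movie,
    write_report,
    write_trajectories,
)

STAGES = (
    "simulate",
    "track",
    "kinetics",
    "residence",
    "msd",
    "hubs",
    "locus",
    "frap",
)


def _require(config: PipelineConfig, key: str) -> Path:
    p = config.paths.get(key)
    if not p or not Path(p).exists():
        raise FileNotFoundError(f"missing input: {key}")
    return Path(p)


def run_pipeline(config: PipelineConfig, stage: str, out_dir="out") -> dict:
    """Run one pipeline stage; returns the report written to disk."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stage": stage}

    if stage == "simulate":
        blk = dict(config.simulate)
        kind = blk.pop("kind", "trajectories")
        if kind == "trajectories":
            preset = blk.pop("preset", None)
            imaging = blk.pop("imaging", "fast")
            if preset:
                params = simulate.preset_params(
                    preset, imaging=imaging, seed=config.rng_seed, **blk
                )
            else:
                params = simulate.TwoStateSimParams(seed=config.rng_seed, **blk)
            trajs, truth = simulate.simulate_trajectories(params)
            write_trajectories(trajs, out / "trajectories.csv")
            truth.to_csv(out / "ground_truth.csv", index=False)
            report.update(
                n_trajectories=len(trajs), params=dataclasses.asdict(params)
            )
        elif kind == "frap":
            params = simulate.FrapSimParams(seed=config.rng_seed, **blk)
            exp = simulate.simulate_frap(params)
            np.savetxt(out / "frap_bleach.csv", exp.bleach, delimiter=",")
            np.savetxt(out / "frap_control.csv", exp.control, delimiter=",")
            np.savetxt(out / "frap_dark.csv", exp.dark, delimiter=",")
            report.update(n_spots=exp.bleach.shape[0],
                          params=dataclasses.asdict(params))
        elif kind == "nuclei":
            params = simulate.NucleusSimParams(seed=config.rng_seed, **blk)
            movie, hub_mask, labels = simulate.simulate_nucleus_movie(params)
            write_movie(movie, out / "nuclei.tif")
            tifffile.imwrite(out / "hub_mask.tif", hub_mask.astype(np.uint8))
            tifffile.imwrite(out / "nucleus_labels.tif", labels.astype(np.int32))
            report.update(n_nuclei=int(labels.max()))
        else:
            raise ValueError(f"unknown simulate kind {kind!r}")

    elif stage == "track":
        movie = read_movie(_require(config, "movie"), config.track.get("metadata"))
        blk = dict(config.track)
        blk.pop("metadata", None)
        per_frame = [
            tracking.detect_spots(
                f,
                sigma_psf=blk.get("sigma_psf", 1.3),
                threshold_mads=blk.get("threshold_mads", 6.0),
                pixel_size=movie.pixel_size_xy,
                frame_index=i,
            )
            for i, f in enumerate(movie.frames)
        ]
        trajs = tracking.link_trajectories(
            per_frame,
            max_disp=blk.get("max_disp", 0.5),
            max_gap=blk.get("max_gap", 1),
            frame_interval=movie.frame_interval,
        )
        write_trajectories(trajs, out / "trajectories.csv")
        report.update(n_trajectories=len(trajs))

    elif stage == "kinetics":
        trajs = read_trajectories(_require(config, "trajectories"))
        blk = config.kinetics
        ds = kinetics.compile_displacements(
            trajs,
            timepoints=blk.get("timepoints", 8),
            jumps_per_traj=blk.get("jumps_per_traj", 4),
            gaps_allowed=blk.get("gaps_allowed", 1),
        )
        fit = kinetics.fit_two_state(
            ds,
            slice_depth=blk.get("slice_depth", 0.8),
            n_init=blk.get("n_init", 5),
            seed=config.rng_seed,
        )
        report.update(dataclasses.asdict(fit))

    elif stage == "residence":
        trajs = read_trajectories(_require(config, "trajectories"))
        control = read_trajectories(_require(config, "control_trajectories"))
        res = kinetics.ResidenceTimeModel(trajs, control).fit()
        report.update(
            tau_res=res.tau_res,
            k_s=res.target_fit.k_s,
            k_bias=res.control_fit.k_s,
            min_duration_frames=res.min_duration_frames,
        )

    elif stage == "msd":
        trajs = read_trajectories(_require(config, "trajectories"))
        trajs = [t for t in trajs if len(t) >= 3]
        curve = msd.compute_tamsd(
            trajs, max_lag_fraction=config.msd.get("max_lag_fraction", 0.25)
        )
        fit = msd.fit_anomalous(curve)
        np.savetxt(
            out / "tamsd.csv",
            np.column_stack([curve.lags, curve.msd, curve.n_pairs]),
            delimiter=",",
            header="lag_s,msd_um2,n_pairs",
        )
        report.update(alpha=fit.alpha, gamma=fit.gamma)

    elif stage == "hubs":
        movie = read_movie(
            _require(config, "hub_image"),
            config.hubs.get("metadata", {"pixel_size_xy": 0.1, "frame_interval": 1.0}),
        )
        trajs = read_trajectories(_require(config, "trajectories"))
        img = movie.frames[0]
        labels = hubs_mod.segment_nuclei(img)
        dmap = hubs_mod.relative_density_map(
            img, labels, pixel_size=movie.pixel_size_xy
        )
        result = hubs_mod.fold_enrichment(
            trajs, dmap, threshold=config.hubs.get("threshold", 85)
        )
        tifffile.imwrite(
            out / "density_map.tif", dmap.percentiles.astype(np.int16)
        )
        report.update(
            fold_enrichment=result.fold_enrichment,
            count_in=result.count_in,
            count_out=result.count_out,
            n_nuclei=labels.n_nuclei,
        )

    elif stage == "locus":
        mcp = read_movie(_require(config, "mcp_movie"), config.locus.get("metadata"))
        tf = read_movie(_require(config, "tf_movie"), config.locus.get("metadata"))
        labels = tifffile.imread(_require(config, "nucleus_labels"))
        blk = config.locus
        dets_per_t = []
        for t in range(mcp.n_frames):
            dets = locus.detect_loci(
                mcp.frames[t],
                threshold_mads=blk.get("threshold_mads", 10.0),
                voxel_size_xy=mcp.pixel_size_xy,
                voxel_size_z=mcp.voxel_size_z,
                timepoint=t,
            )
            kept = []
            for d in dets:
                ok, refined = locus.contrast_filter(
                    d, mcp.frames[t],
                    min_ratio=blk.get("min_contrast", 2.0),
                    voxel_size_xy=mcp.pixel_size_xy,
                    voxel_size_z=mcp.voxel_size_z,
                )
                if ok:
                    kept.append(refined)
            dets_per_t.append(kept)
        tracks = locus.track_loci(dets_per_t, max_disp=blk.get("max_disp", 1.0))
        ts_all, rs_all = [], []
        for tr in tracks:
            ts, rs, _ = locus.crop_windows(tr, tf, labels)
            if len(ts):
                ts_all.append(ts)
                rs_all.append(rs)
        if not ts_all:
            report.update(n_windows=0)
        else:
            ts_stack = np.concatenate(ts_all)
            rs_stack = np.concatenate(rs_all)
            _, prof_ts = locus.average_and_radial_profile(
                ts_stack, tf.pixel_size_xy
            )
            _, prof_rs = locus.average_and_radial_profile(
                rs_stack, tf.pixel_size_xy
            )
            np.savetxt(
                out / "radial_profiles.csv",
                np.column_stack(
                    [prof_ts.radii, prof_ts.mean, prof_ts.sem,
                     prof_rs.mean, prof_rs.sem]
                ),
                delimiter=",",
                header="radius_um,ts_mean,ts_sem,rs_mean,rs_sem",
            )
            report.update(
                n_windows=prof_ts.n_windows,
                ts_central=float(prof_ts.mean[0]),
                rs_central=float(prof_rs.mean[0]),
            )

    elif stage == "frap":
        bleach = np.loadtxt(_require(config, "frap_bleach"), delimiter=",")
        control = np.loadtxt(_require(config, "frap_control"), delimiter=",")
        dark = np.loadtxt(_require(config, "frap_dark"), delimiter=",")
        blk = config.frap
        exp = frap_mod.FrapExperiment(
            bleach, control, dark,
            frame_interval=blk.get("frame_interval", 0.024),
            n_pre=blk.get("n_pre", 10),
        )
        rec = frap_mod.bleach_correct(exp)
        fit = frap_mod.FrapRecoveryModel(rec).fit()
        report.update(
            a_amp=fit.a_amp, k_a=fit.k_a, b_amp=fit.b_amp, k_b=fit.k_b,
            t_half_slow=fit.t_half_slow, n_spots_kept=rec.n_spots_kept,
        )

    write_report(out / f"{stage}_report.json", report, config)
    return report
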