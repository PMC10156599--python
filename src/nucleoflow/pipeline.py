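"""End-to-end orchestration of the synthetic → analysis pipeline.

``run_pipeline`` executes the requested stages in dependency order on a
synthetic monolayer (and optionally an organoid recording), writing a single
JSON report of summary statistics with full provenance (config hash, seed).
Each stage only consumes the products of earlier stages, so reruns with the
same configuration are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import dynamics, mechanics, organoid, piv, segtrack, synthetic

log = logging.getLogger("nucleoflow")

ALL_STAGES = ["simulate", "segment", "track", "piv", "dynamics",
              "mechanics", "organoid"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["simulate", "segment", "track", "dynamics", "mechanics"],
    "simulate": {"regime": "flocking", "n_cells": 200, "n_frames": 30,
                 "box_size": 200.0, "dt": 10.0},
    "optics": {},
    "segment": {},
    "track": {"max_displacement": 8.0, "memory": 0},
    "piv": {"window_um": 14.0, "overlap": 0.5},
    "dynamics": {},
    "mechanics": {"n_bins": 11},
    "organoid": {"n_cells": 60, "omega": [0.0, 0.0, 0.04],
                 "residual_D": 2.0, "n_frames": 30, "dt": 15.0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and \
            isinstance(base.get(k), dict) else v
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None,
                 ) -> dict:
    """Run the requested stages; returns (and optionally writes) the report.

    Stages: simulate → segment → track → piv → dynamics → mechanics →
    organoid.  A stage requiring a missing upstream product raises a
    descriptive error naming the stage.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    stages = cfg["stages"]
    seed = int(cfg["seed"])
    report: dict = {"config_hash": config_hash(cfg), "seed": seed,
                    "stages": stages, "timings_s": {}}
    products: dict = {}

    def stage_needs(stage: str, key: str):
        if key not in products:
            raise RuntimeError(
                f"stage '{stage}' requires missing upstream product '{key}'")
        return products[key]

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            sim = dict(cfg["simulate"])
            regime = sim.pop("regime", "flocking")
            maker = (synthetic.MonolayerConfig.jammed if regime == "jammed"
                     else synthetic.MonolayerConfig.flocking)
            mc = maker(seed=seed, **sim)
            truth = synthetic.simulate_monolayer(mc)
            optics = synthetic.OpticsConfig(**cfg["optics"])
            stack = synthetic.render_frames(truth, optics)
            products["truth"] = truth
            products["stack"] = stack
            report["simulate"] = {"n_cells": mc.n_cells,
                                  "n_frames": mc.n_frames,
                                  "regime": regime,
                                  "planted_R": mc.moduli_ratio,
                                  "planted_beta": mc.beta,
                                  "planted_gamma0_h": truth.planted_gamma0}
            if outdir:
                out = Path(outdir)
                out.mkdir(parents=True, exist_ok=True)
                stack.save_tiff(out / "stack.tif")
                truth.to_csv(out / "ground_truth.csv")
        elif stage == "segment":
            stack = stage_needs("segment", "stack")
            seg_cfg = segtrack.SegmentationConfig(**cfg["segment"])
            obs = segtrack.segment_stack(stack, seg_cfg)
            products["observations"] = obs
            report["segment"] = {"nuclei_per_frame":
                                 float(np.mean([len(o) for o in obs]))}
        elif stage == "track":
            obs = stage_needs("track", "observations")
            stack = stage_needs("track", "stack")
            tracks = segtrack.link_tracks(
                obs, pixel_size=stack.pixel_size, dt=stack.dt,
                **cfg["track"])
            tracks = segtrack.apply_quality_filter(tracks)
            products["tracks"] = tracks
            report["track"] = {"n_tracks": int(len(tracks.track_ids)),
                               "n_excluded": len(tracks.excluded)}
            if outdir:
                tracks.to_csv(Path(outdir) / "tracks.csv")
        elif stage == "piv":
            stack = stage_needs("piv", "stack")
            sig = []
            for t in range(stack.n_frames - 1):
                vf = piv.compute_velocity_field(
                    stack.data[t], stack.data[t + 1], stack.pixel_size,
                    stack.dt, **cfg["piv"])
                vf = piv.clean_outliers(vf)
                sig.append(piv.divergence_field(vf).sigma_div)
            products["sigma_div_series"] = sig
            report["piv"] = {"sigma_div_per_min": float(np.mean(sig))}
        elif stage == "dynamics":
            tracks = stage_needs("dynamics", "tracks")
            mot = dynamics.motility_stats(tracks)
            curve = dynamics.fit_mss(dynamics.mss_curve(tracks))
            cvv = dynamics.velocity_correlation(tracks)
            report["dynamics"] = {
                "v_rms_um_min": float(np.mean(mot.v_rms)),
                "v_cm_um_min": float(np.mean(np.hypot(*mot.v_cm.T))),
                "gamma0_h": curve.gamma0,
                "tau_c_h": curve.tau_c,
                "sigma_w": curve.sigma_w,
            }
            try:
                lc, alpha, _ = dynamics.fit_correlation_length(cvv)
                report["dynamics"]["L_c_um"] = lc
                report["dynamics"]["alpha"] = alpha
            except (ValueError, RuntimeError) as e:
                report["dynamics"]["L_c_um"] = None
                log.warning("correlation-length fit failed: %s", e)
            products["motility"] = mot
        elif stage == "mechanics":
            truth = stage_needs("mechanics", "truth")
            gn, gc, ids = strain_coupling_from_truth(truth)
            beta = truth.config.beta
            fit = mechanics.coupling_fit(gn, gc, beta, nucleus_ids=ids,
                                         n_bins=cfg["mechanics"]["n_bins"],
                                         seed=seed)
            report["mechanics"] = {"slope_s": fit.slope,
                                   "slope_sd": fit.slope_sd,
                                   "E_N_over_E_CY": fit.ratio,
                                   "ratio_sd": fit.ratio_sd,
                                   "beta": beta}
        elif stage == "organoid":
            ocfg = dict(cfg["organoid"])
            table, omega_true = synthetic.simulate_organoid(seed=seed, **ocfg)
            clouds = organoid.clouds_from_table(table)
            rm = organoid.rigid_motion_3d(clouds, dt=ocfg.get("dt", 15.0))
            d0 = organoid.default_overlap_cutoff(clouds[0])
            qtab, tau_star = organoid.overlap_parameter(rm.residuals, d0,
                                                        rm.dt)
            report["organoid"] = {
                "mean_angular_speed_cyc_h": rm.mean_speed,
                "classification": organoid.classify_rotation(rm.angular_speed),
                "tau_star_h": tau_star if np.isfinite(tau_star) else None,
                "d0_um": d0,
            }
        else:
            raise ValueError(f"unknown stage '{stage}'")
        report["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", stage, report["timings_s"][stage])

    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def strain_coupling_from_truth(truth: synthetic.GroundTruth,
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired (γ̇_N, γ̇_C) samples from a ground-truth monolayer.

    γ̇_N by central differences of nuclear areas; γ̇_C as the mean of the
    two coarse-grained divergence fields bracketing each frame (velocity
    fields live on half-integer times, so the central-difference γ̇_N(t)
    spans exactly those two intervals).
    """
    cfg = truth.config
    t_n, n = truth.areas.shape
    frames = np.arange(t_n)
    gn = np.full((t_n, n), np.nan)
    for i in range(n):
        gn[:, i] = dynamics.nuclear_strain_rate(frames, truth.areas[:, i],
                                                cfg.dt)
    gc = np.full((t_n, n), np.nan)
    for t in range(1, t_n - 1):
        gc[t] = 0.5 * (truth.cell_strain_rate[t - 1] +
                       truth.cell_strain_rate[t])
    ok_rows = slice(1, t_n - 1)
    ids = np.tile(np.arange(n), t_n - 2)
    return (gn[ok_rows].ravel(), gc[ok_rows].ravel(), ids)
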