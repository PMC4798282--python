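"""End-to-end pipeline orchestration with a config file and seeded RNG.

The pipeline runs stages in dependency order — I/O (or synthesis) ->
kinematics/fits/MSD/correlation -> search-efficiency simulation -> hotspot
detection -> heterogeneity — writing tidy CSV tables and one JSON summary
per run, every output stamped with the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import heterogeneity, hotspots, simulator, synthetic_data, trackio
from .model import MotilityModel

logger = logging.getLogger(__name__)

CONFIG_VERSION = 1

DEFAULT_CONFIG = {
    "version": CONFIG_VERSION,
    "seed": 0,
    "input": None,                # path to a track CSV, or null to synthesize
    "generator": {},              # GeneratorSpec overrides when synthesizing
    "stages": {                   # stage toggles
        "fit": True,
        "simulate": False,
        "hotspots": False,
        "heterogeneity": True,
    },
    "filter": {"min_path": 17.0, "min_sq_disp": 300.0, "min_steps": 3},
    "theta_max": 15.0,
    "r2_min": 0.8,
    "simulate_opts": {"models": list(simulator.WALKER_MODELS),
                      "cluster_radii": [10.0], "replicates": 20, "reps": 4},
    "hotspot_opts": {"reps": 10, "cube_edge": hotspots.CUBE_EDGE},
}


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(base.get(k), dict) else v
    return out


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured stages and write results under ``outdir``.

    Returns the JSON summary (also written to ``summary.json``).
    Raises :class:`StageError` naming the failing stage.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if cfg["seed"] is None:
        raise StageError("config", "a seed is mandatory")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": _config_hash(cfg), "seed": cfg["seed"]}
    rng = np.random.default_rng(cfg["seed"])
    summary: dict = {"stamp": stamp}

    # --- io / synthesis ---------------------------------------------------
    try:
        if cfg["input"]:
            field = trackio.read_tracks(cfg["input"])
        else:
            spec = synthetic_data.GeneratorSpec(
                **cfg["generator"], seed=int(rng.integers(2**31)))
            field, _ = synthetic_data.gen_field(spec)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("io", exc) from exc
    f = cfg["filter"]
    field = trackio.filter_motile(field, f["min_path"], f["min_sq_disp"],
                                  f["min_steps"])
    summary["io"] = {"n_tracks": field.n_tracks, "frame_dt": field.frame_dt}

    # --- fits / msd / correlation -----------------------------------------
    results = None
    if cfg["stages"]["fit"]:
        try:
            results = MotilityModel(field, filter_tracks=False).fit(
                theta_max=cfg["theta_max"], r2_min=cfg["r2_min"])
        except Exception as exc:
            raise StageError("fit", exc) from exc
        summary["fit"] = results.to_dict()
        pd.DataFrame({
            "lag_s": results.msd_curve.lags,
            "msd_um2": results.msd_curve.msd,
            "n": results.msd_curve.counts,
        }).assign(**stamp).to_csv(outdir / "msd.csv", index=False)
        pd.DataFrame({
            "delay_s": results.autocorrelation.delays,
            "corr": results.autocorrelation.corr,
            "n_pairs": results.autocorrelation.n_pairs,
        }).assign(**stamp).to_csv(outdir / "autocorrelation.csv", index=False)

    # --- simulation ---------------------------------------------------------
    if cfg["stages"]["simulate"]:
        try:
            so = cfg["simulate_opts"]
            table = simulator.efficiency_experiment(
                field, models=so["models"], cluster_radii=so["cluster_radii"],
                replicates=so["replicates"], reps=so["reps"],
                rng=int(rng.integers(2**31)))
        except Exception as exc:
            raise StageError("simulate", exc) from exc
        table.assign(**stamp).to_csv(outdir / "efficiency.csv", index=False)
        comp = {}
        obs = table[table.model == "observed"]
        for model in so["models"]:
            sub = table[table.model == model]
            comp[model] = simulator.compare_models(
                [g.efficiency_unique.to_numpy() for _, g in sub.groupby("rep")],
                [g.efficiency_unique.to_numpy() for _, g in obs.groupby("rep")],
            )
        summary["simulate"] = comp

    # --- hotspots -----------------------------------------------------------
    if cfg["stages"]["hotspots"]:
        try:
            params = simulator.fit_walker_params(field, cfg["theta_max"])
            grid = hotspots.detect(field, params,
                                   reps=cfg["hotspot_opts"]["reps"],
                                   cube_edge=cfg["hotspot_opts"]["cube_edge"],
                                   rng=int(rng.integers(2**31)))
            labels, hs_summary = hotspots.classify_hot_cold(field, grid)
        except Exception as exc:
            raise StageError("hotspots", exc) from exc
        summary["hotspots"] = {
            "threshold": grid.threshold,
            "hotspot_fraction": grid.hotspot_fraction,
            **hs_summary,
        }
        pd.DataFrame([vars(l) for l in labels]).assign(**stamp).to_csv(
            outdir / "track_heat_labels.csv", index=False)

    # --- heterogeneity ------------------------------------------------------
    if cfg["stages"]["heterogeneity"]:
        try:
            windows = heterogeneity.sliding_skew(field.tracks)
            subpops = heterogeneity.subpopulation_fits(field.tracks)
        except Exception as exc:
            raise StageError("heterogeneity", exc) from exc
        pd.DataFrame([vars(w) for w in windows]).assign(**stamp).to_csv(
            outdir / "sliding_skew.csv", index=False)
        summary["heterogeneity"] = {
            cls: {"winner": info["winner"], "skew": info["skew"],
                  "kurtosis": info["kurtosis"], "n": info["n"]}
            for cls, info in subpops.items()
        }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    logger.info("pipeline complete; summary at %s", outdir / "summary.json")
    return summary
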