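"""Pipeline orchestration: layered configs, run manifests, seeded stages.

A pipeline is a list of declared stages (synthesize → quantify, or
simulate/solve → summarize) executed in order with all randomness flowing
through explicitly recorded seeds. Every run writes a :class:`RunManifest`
sufficient to reproduce it byte-identically for deterministic commands.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__, actin, io as vio, quantify, synthdata, twophase

log = logging.getLogger("viscocell")

__all__ = [
    "RunManifest",
    "load_config",
    "actin_params_from_config",
    "twophase_params_from_config",
    "regime_from_config",
    "estimator_recovery_table",
    "viscosity_demo",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    """Load a flat key/value config file with optional includes.

    A config may name other files under the key ``include`` (a list of paths
    resolved relative to the including file); later files override earlier
    ones, the including file overrides its includes, and explicit
    ``overrides`` (e.g. from the command line) override everything.
    """
    merged: dict = {}
    if path is not None:
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a flat key/value mapping")
        for inc in raw.pop("include", []) or []:
            merged.update(load_config((path.parent / inc).resolve()))
        merged.update(raw)
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})
    return merged


def _filtered_kwargs(cls, cfg: dict, prefix: str = "") -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    out = {}
    for key, value in cfg.items():
        if prefix and not key.startswith(prefix):
            continue
        name = key[len(prefix):]
        if name in names:
            out[name] = value
    return out


def actin_params_from_config(cfg: dict) -> actin.ActinSimParams:
    """Build simulator params from a flat config; ``viscosity_cp`` wins over
    ``eta_visc`` when both are present."""
    kwargs = _filtered_kwargs(actin.ActinSimParams, cfg)
    if "viscosity_cp" in cfg:
        kwargs["eta_visc"] = actin.cp_to_pa_s(float(cfg["viscosity_cp"]))
    return actin.ActinSimParams(**kwargs)


def twophase_params_from_config(cfg: dict) -> twophase.TwoPhaseParams:
    return twophase.TwoPhaseParams(**_filtered_kwargs(twophase.TwoPhaseParams, cfg))


def regime_from_config(cfg: dict) -> twophase.RegimeConfig:
    """Resolve a regime: named preset (LV/HV) plus ``regime_*`` overrides."""
    name = str(cfg.get("regime", "LV")).upper()
    if name == "LV":
        base = twophase.LV_REGIME
    elif name == "HV":
        base = twophase.HV_REGIME
    else:
        base = twophase.RegimeConfig()
    over = _filtered_kwargs(twophase.RegimeConfig, cfg, prefix="regime_")
    over.pop("name", None)
    return replace(base, **over) if over else base


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Everything needed to reproduce a run of the pipeline."""

    command: str
    config: dict
    seed: int
    outputs: list[str] = field(default_factory=list)
    inputs: list[str] = field(default_factory=list)
    stages: list[dict] = field(default_factory=list)
    package_version: str = __version__
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = datetime.datetime.now(datetime.UTC).isoformat()
        return self

    def finish(self) -> "RunManifest":
        self.finished = datetime.datetime.now(datetime.UTC).isoformat()
        return self

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        return path


# ---------------------------------------------------------------------------
# composite computations shared by the analysis drivers and the CLI
# ---------------------------------------------------------------------------

_RECOVERY_SPECS = (
    "track_speed",
    "track_persistence_straight",
    "sphere_volume",
    "spike_count",
    "contour_growth",
    "front_rear_ratio",
    "edge_occupancy",
    "ph_rate",
    "flow_speed",
)


def estimator_recovery_table(seed: int = 0, n_tracks: int = 100) -> pd.DataFrame:
    """Run every generator/estimator pair and tabulate truth vs estimate.

    Returns one row per statistic with columns (statistic, truth, estimate,
    rel_err). Track speed is averaged over ``n_tracks`` persistent random
    walks; the other statistics use a single seeded dataset each.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(16)]
    rows = []

    def add(stat: str, truth: float, est: float) -> None:
        denom = abs(truth) if truth != 0 else 1.0
        rows.append(
            {
                "statistic": stat,
                "truth": truth,
                "estimate": est,
                "rel_err": abs(est - truth) / denom,
            }
        )

    speeds = []
    for i in range(n_tracks):
        track, truth = synthdata.make_prw_track(seed=seeds[0] + i)
        s, _ = quantify.speed_and_persistence(track)
        speeds.append(s)
    add("track_speed_um_s", truth.parameters["true_speed"], float(np.mean(speeds)))

    straight, _ = synthdata.make_prw_track(persistence_time=1e12, seed=seeds[1])
    _, pers = quantify.speed_and_persistence(straight)
    add("track_persistence_straight", 1.0, pers)

    stack, truth = synthdata.make_sphere_stack(seed=seeds[2])
    add("sphere_volume_um3", truth.parameters["true_volume"], quantify.cell_volume(stack))

    trace, truth = synthdata.make_spike_trace(seed=seeds[3])
    add(
        "spike_count",
        truth.parameters["true_spike_count"],
        quantify.calcium_spike_count(trace),
    )

    series, truth = synthdata.make_growing_contour()
    add(
        "contour_growth_um",
        truth.parameters["true_step_growth"],
        float(np.mean(quantify.lamella_growth(series))),
    )

    cell, truth = synthdata.make_polarized_cell(seed=seeds[4])
    add("front_rear_ratio", truth.parameters["true_ratio"], quantify.front_rear_ratio(cell))

    img, poly, truth = synthdata.make_edge_pattern(seed=seeds[5])
    add(
        "edge_occupancy_pct",
        100.0 * truth.parameters["true_occupancy"],
        quantify.storm_edge_density(
            img, poly, band=truth.parameters["band"],
            pixel_size=truth.parameters["pixel_size"],
        ),
    )

    ph, truth = synthdata.make_ph_trace(seed=seeds[6])
    add("ph_recovery_rate", truth.parameters["true_rate"], quantify.ph_recovery_rate(ph))

    t, s_pos, truth = synthdata.make_kymograph_track(seed=seeds[7])
    add(
        "flow_speed_um_s",
        truth.parameters["true_flow_speed"],
        quantify.retrograde_flow(t, s_pos),
    )
    return pd.DataFrame(rows)


def viscosity_demo(seed: int, out_dir: str | Path, n_rep: int = 20) -> dict[str, Path]:
    """The bundled end-to-end pipeline: three summary tables.

    1. actin ensemble mean densities at 0.8 vs 8 cP (load at t_load);
    2. two-phase migration speeds for LV/HV with and without NHE1 flux;
    3. the estimator-recovery table on synthetic data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    frames = []
    for cp in (0.8, 8.0):
        params = actin.ActinSimParams.from_cp(cp)
        ens = actin.ensemble_density(params, n_rep=n_rep, base_seed=seed)
        frames.append(
            pd.DataFrame(
                {
                    "time_s": ens.times,
                    "viscosity_cp": cp,
                    "mean_density": ens.mean_density,
                    "sd_density": ens.sd_density,
                    "mean_edge_vel_um_s": ens.mean_edge_vel,
                }
            )
        )
        log.info("actin ensemble at %.1f cP: post-load density %.1f /um", cp,
                 ens.mean_density[ens.times >= params.t_load].mean())
    path = out_dir / "actin_ensemble.csv"
    pd.concat(frames).to_csv(path, index=False)
    written["actin_ensemble"] = path

    rows = []
    params = twophase.TwoPhaseParams()
    for regime in (twophase.LV_REGIME, twophase.HV_REGIME):
        sol = twophase.solve_steady_state(params, regime)
        kd = twophase.solve_steady_state(twophase.knockdown_nhe1(params), regime)
        rows.append(
            {
                "regime": regime.name,
                "v0_um_s": sol.v0,
                "v0_nhe1_kd_um_s": kd.v0,
                "relative_reduction": 1.0 - kd.v0 / sol.v0,
                "front_rear_theta_n_ratio": sol.front_rear_theta_n_ratio,
            }
        )
        log.info("two-phase %s: v0=%.4f um/s, knockdown v0=%.4f um/s",
                 regime.name, sol.v0, kd.v0)
    path = out_dir / "twophase_speeds.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    written["twophase_speeds"] = path

    path = out_dir / "estimator_recovery.csv"
    estimator_recovery_table(seed=seed).to_csv(path, index=False)
    written["estimator_recovery"] = path
    return written


# ---------------------------------------------------------------------------
# pipeline runner
# ---------------------------------------------------------------------------


def _stage_synth(stage: dict, out_dir: Path, seed: int) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    name = stage["generator"]
    kwargs = dict(stage.get("params", {}))
    kwargs.setdefault("seed", seed)
    out: list[Path] = []
    if name == "prw_track":
        track, truth = synthdata.make_prw_track(**kwargs)
        vio.write_track_csv(track, out_dir / "track.csv")
        out.append(out_dir / "track.csv")
    elif name == "sphere_stack":
        stack, truth = synthdata.make_sphere_stack(**kwargs)
        vio.write_stack(stack, out_dir / "stack.tif")
        out.append(out_dir / "stack.tif")
    elif name == "spike_trace":
        trace, truth = synthdata.make_spike_trace(**kwargs)
        vio.write_trace_csv(trace, out_dir / "trace.csv")
        out.append(out_dir / "trace.csv")
    elif name == "growing_contour":
        kwargs.pop("seed", None)
        series, truth = synthdata.make_growing_contour(**kwargs)
        vio.write_contours_csv(series, out_dir / "contours.csv")
        out.append(out_dir / "contours.csv")
    elif name == "ph_trace":
        trace, truth = synthdata.make_ph_trace(**kwargs)
        vio.write_trace_csv(trace, out_dir / "ph_trace.csv")
        out.append(out_dir / "ph_trace.csv")
    else:
        raise ValueError(f"unknown generator {name!r}")
    truth.to_json(out_dir / "truth.json")
    out.append(out_dir / "truth.json")
    return out


def _stage_quantify(stage: dict, out_dir: Path, seed: int) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    kind = stage["statistic"]
    src = Path(stage["input"])
    if kind == "tracks":
        speed, pers = quantify.speed_and_persistence(vio.read_track_csv(src))
        result = {"mean_speed_um_s": speed, "persistence": pers}
    elif kind == "volume":
        result = {"volume_um3": quantify.cell_volume(vio.read_stack(src))}
    elif kind == "lamella":
        growth = quantify.lamella_growth(vio.read_contours_csv(src))
        result = {"mean_growth_um": float(np.mean(growth))}
    elif kind == "spikes":
        result = {"spike_count": quantify.calcium_spike_count(vio.read_trace_csv(src))}
    elif kind == "ph":
        result = {"ph_recovery_rate": quantify.ph_recovery_rate(vio.read_trace_csv(src))}
    else:
        raise ValueError(f"unknown statistic {kind!r}")
    path = out_dir / f"{kind}_result.json"
    path.write_text(json.dumps(result, indent=2))
    return [path]


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> RunManifest:
    """Execute the declared stages in order and write a manifest.

    Each stage is a mapping with a ``kind`` ∈ {synth, quantify,
    simulate-actin, actin-ensemble, solve-twophase, sweep-viscosity, demo}
    plus kind-specific keys; stage outputs land in ``out_dir/<stage-name>``.
    A stage failure aborts the pipeline with the failing stage's diagnostics
    recorded in the manifest.
    """
    out_dir = Path(out_dir)
    manifest = RunManifest(command="run-pipeline", config=config, seed=seed).start()
    stages = config.get("stages", [])
    try:
        for i, stage in enumerate(stages):
            kind = stage.get("kind")
            stage_dir = out_dir / stage.get("name", f"stage{i:02d}")
            stage_dir.mkdir(parents=True, exist_ok=True)
            stage_seed = int(stage.get("seed", seed))
            log.info("stage %d (%s) seed=%d -> %s", i, kind, stage_seed, stage_dir)
            if kind == "synth":
                outputs = _stage_synth(stage, stage_dir, stage_seed)
            elif kind == "quantify":
                outputs = _stage_quantify(stage, stage_dir, stage_seed)
            elif kind == "simulate-actin":
                params = actin_params_from_config({**config, **stage, "seed": stage_seed})
                trace = actin.simulate(params)
                vio.write_edge_trace_csv(trace, stage_dir / "edge_trace.csv")
                outputs = [stage_dir / "edge_trace.csv"]
            elif kind == "actin-ensemble":
                params = actin_params_from_config({**config, **stage})
                ens = actin.ensemble_density(
                    params, n_rep=int(stage.get("n_rep", 20)), base_seed=stage_seed
                )
                vio.write_ensemble_csv(ens, stage_dir / "ensemble.csv")
                outputs = [stage_dir / "ensemble.csv"]
            elif kind == "solve-twophase":
                params = twophase_params_from_config({**config, **stage})
                if stage.get("knockdown") == "nhe1":
                    params = twophase.knockdown_nhe1(params)
                sol = twophase.solve_steady_state(
                    params, regime_from_config({**config, **stage})
                )
                vio.write_solution(sol, stage_dir)
                outputs = [stage_dir / "twophase.json", stage_dir / "twophase_fields.csv"]
            elif kind == "sweep-viscosity":
                rows = twophase.speed_vs_viscosity(
                    twophase_params_from_config({**config, **stage}),
                    regime_from_config({**config, **stage}),
                    stage["viscosities_cp"],
                )
                vio.write_sweep_csv(rows, stage_dir / "sweep.csv")
                outputs = [stage_dir / "sweep.csv"]
            elif kind == "demo":
                outputs = list(viscosity_demo(stage_seed, stage_dir).values())
            else:
                raise ValueError(f"unknown stage kind {kind!r}")
            manifest.stages.append(
                {"kind": kind, "seed": stage_seed, "outputs": [str(p) for p in outputs]}
            )
            manifest.outputs.extend(str(p) for p in outputs)
    except Exception as err:
        manifest.stages.append({"kind": "error", "error": repr(err)})
        manifest.finish().write(out_dir)
        raise
    manifest.finish().write(out_dir)
    return manifest
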