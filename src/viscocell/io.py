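"""Readers and writers for the package's on-disk dialects.

Tracks, contours and traces travel as CSV; label stacks as multi-page TIFF
with a JSON sidecar carrying the physical calibration; model outputs as CSV
tables plus JSON scalar/diagnostic blocks.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .actin import EdgeTrace, EnsembleDensity
from .quantify import ContourSeries, IntensityTrace, LabeledStack, Track
from .twophase import TwoPhaseSolution

__all__ = [
    "read_track_csv",
    "write_track_csv",
    "read_stack",
    "write_stack",
    "read_contours_csv",
    "write_contours_csv",
    "read_trace_csv",
    "write_trace_csv",
    "write_edge_trace_csv",
    "read_edge_trace_csv",
    "write_ensemble_csv",
    "write_solution",
    "write_sweep_csv",
]


def read_track_csv(path: str | Path) -> Track:
    """Read a track CSV with columns t_s, x_um, y_um and optional z_um."""
    df = pd.read_csv(path)
    for col in ("t_s", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"track file {path} lacks required column {col}")
    z = df["z_um"].to_numpy() if "z_um" in df.columns else None
    return Track(df["t_s"].to_numpy(), df["x_um"].to_numpy(), df["y_um"].to_numpy(), z)


def write_track_csv(track: Track, path: str | Path) -> None:
    data = {"t_s": track.t, "x_um": track.x, "y_um": track.y}
    if track.z is not None:
        data["z_um"] = track.z
    pd.DataFrame(data).to_csv(path, index=False)


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> LabeledStack:
    """Read a binary z-stack from multi-page TIFF plus its JSON sidecar.

    The sidecar (default ``<stem>.json`` next to the TIFF) holds
    ``{"dz_um": ..., "pixel_size_um": ...}``.
    """
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(".json")
    meta = json.loads(Path(sidecar).read_text())
    masks = tifffile.imread(path)
    if masks.ndim == 2:
        masks = masks[None]
    return LabeledStack(masks > 0, dz=meta["dz_um"], pixel_size=meta["pixel_size_um"])


def write_stack(stack: LabeledStack, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.masks.astype(np.uint8) * 255)
    path.with_suffix(".json").write_text(
        json.dumps({"dz_um": stack.dz, "pixel_size_um": stack.pixel_size})
    )


def read_contours_csv(path: str | Path) -> ContourSeries:
    df = pd.read_csv(path)
    return ContourSeries(
        df["t_s"].to_numpy(), df["area_um2"].to_numpy(), df["perimeter_um"].to_numpy()
    )


def write_contours_csv(series: ContourSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"t_s": series.t, "area_um2": series.area, "perimeter_um": series.perimeter}
    ).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> IntensityTrace:
    df = pd.read_csv(path)
    return IntensityTrace(df["t_s"].to_numpy(), df["value"].to_numpy())


def write_trace_csv(trace: IntensityTrace, path: str | Path) -> None:
    pd.DataFrame({"t_s": trace.t, "value": trace.value}).to_csv(path, index=False)


_EDGE_COLS = {
    "time_s": "times",
    "edge_pos_um": "edge_pos",
    "edge_vel_um_s": "edge_vel",
    "density_per_um": "density",
    "n_growing": "n_growing",
    "n_capped": "n_capped_barbed",
    "n_pointed": "n_pointed",
}


def write_edge_trace_csv(trace: EdgeTrace, path: str | Path) -> None:
    pd.DataFrame(
        {col: getattr(trace, attr) for col, attr in _EDGE_COLS.items()}
    ).to_csv(path, index=False)


def read_edge_trace_csv(path: str | Path) -> EdgeTrace:
    df = pd.read_csv(path)
    return EdgeTrace(**{attr: df[col].to_numpy() for col, attr in _EDGE_COLS.items()})


def write_ensemble_csv(ens: EnsembleDensity, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": ens.times,
            "mean_density": ens.mean_density,
            "sd_density": ens.sd_density,
            "n_rep": ens.n_rep,
            "mean_edge_vel_um_s": ens.mean_edge_vel,
            "mean_pointed_minus_capped": ens.mean_pointed_minus_capped,
        }
    ).to_csv(path, index=False)


def write_solution(sol: TwoPhaseSolution, out_dir: str | Path, stem: str = "twophase") -> None:
    """Serialize a converged solution: JSON scalars + CSV field table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scalars = {
        "v0_um_s": sol.v0,
        "v_c_um_s": sol.v_c,
        "J_water_f_um_s": sol.J_water_f,
        "J_water_b_um_s": sol.J_water_b,
        "p_star_f_Pa": sol.p_star_f,
        "p_star_b_Pa": sol.p_star_b,
        "front_rear_theta_n_ratio": sol.front_rear_theta_n_ratio,
        "regime": sol.regime.name,
        "residuals": sol.residuals,
        "params": asdict(sol.params),
        "regime_config": {
            **asdict(sol.regime),
            "profile_shape": sol.regime.profile_shape.value,
        },
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(scalars, indent=2))
    pd.DataFrame(
        {
            "x_um": sol.grid,
            "theta_n_mM": sol.theta_n,
            "theta_c_mM": sol.theta_c,
            "c_mM": sol.c,
            "p_Pa": sol.p,
            "v_n_um_s": sol.v_n,
        }
    ).to_csv(out_dir / f"{stem}_fields.csv", index=False)


def write_sweep_csv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows)[["viscosity_cp", "v0_um_s", "converged"]].to_csv(
        path, index=False
    )
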