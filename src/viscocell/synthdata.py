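"""Synthetic inputs with known ground truth for every quantification estimator.

Each generator emulates one microscopy-derived record — persistent-random-walk
tracks, ellipsoid label stacks, spiking calcium traces, growing contours,
polarized cells, edge-band point patterns, pH-recovery ramps and kymograph
feature tracks — and returns the record together with a :class:`SynthTruth`
carrying the parameters it was built from, so estimator-recovery tests need no
external data. All generators are deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .quantify import ContourSeries, IntensityTrace, LabeledStack, PolarizedCell, Track

__all__ = [
    "SynthTruth",
    "make_prw_track",
    "make_sphere_stack",
    "make_spike_trace",
    "make_growing_contour",
    "make_polarized_cell",
    "make_edge_pattern",
    "make_ph_trace",
    "make_kymograph_track",
]


@dataclass(frozen=True)
class SynthTruth:
    """Ground-truth parameters attached to a generated dataset."""

    generator_name: str
    parameters: dict[str, Any]
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "generator_name": self.generator_name,
            "parameters": self.parameters,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthTruth":
        d = json.loads(Path(path).read_text())
        return cls(d["generator_name"], d["parameters"], d["seed"])


def make_prw_track(
    speed: float = 0.01,
    persistence_time: float = 30.0,
    dt: float = 10.0,
    n: int = 60,
    seed: int = 0,
) -> tuple[Track, SynthTruth]:
    """Persistent random walk: constant step speed, mean-reverting heading.

    The heading follows an angular Ornstein–Uhlenbeck process with relaxation
    time ``persistence_time`` (s) and stationary angular variance set by the
    diffusive limit, so large ``persistence_time`` gives near-straight tracks
    and small values give diffusive ones. Step length is ``speed*dt`` exactly,
    so the frame-to-frame speed statistic recovers ``speed``.
    """
    if n < 4:
        raise ValueError("need n >= 4 frames")
    if speed <= 0 or dt <= 0 or persistence_time < 0:
        raise ValueError("speed and dt must be positive, persistence_time >= 0")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi)
    # rotational diffusion with D_r = 1/persistence_time gives directional
    # autocorrelation exp(-t/persistence_time)
    d_theta_sd = (
        np.sqrt(2.0 * dt / persistence_time) if persistence_time > 0 else np.pi
    )
    xs = np.zeros(n)
    ys = np.zeros(n)
    for i in range(1, n):
        xs[i] = xs[i - 1] + speed * dt * np.cos(theta)
        ys[i] = ys[i - 1] + speed * dt * np.sin(theta)
        theta += rng.normal(0.0, d_theta_sd)
    t = np.arange(n) * dt
    truth = SynthTruth(
        "prw_track",
        {
            "true_speed": speed,
            "persistence_time": persistence_time,
            "dt": dt,
            "n": n,
        },
        seed,
    )
    return Track(t, xs, ys), truth


def make_sphere_stack(
    radius: float = 8.0,
    dz: float = 0.5,
    pixel_size: float = 0.1,
    seed: int = 0,
) -> tuple[LabeledStack, SynthTruth]:
    """Rasterized sphere resting on the substrate; truth volume = 4/3·π·r³.

    Slice k is the disc of the sphere at height k·dz; pixels whose centre lies
    inside the disc are ON (pixel-centre-inside rule).
    """
    if radius <= dz:
        raise ValueError("radius must exceed the slice spacing dz")
    n_slices = int(np.floor(2 * radius / dz)) + 1
    npx = int(np.ceil(2 * radius / pixel_size)) + 4
    centre = npx / 2 * pixel_size
    yy, xx = np.meshgrid(
        (np.arange(npx) + 0.5) * pixel_size,
        (np.arange(npx) + 0.5) * pixel_size,
        indexing="ij",
    )
    r2 = (yy - centre) ** 2 + (xx - centre) ** 2
    masks = np.zeros((n_slices, npx, npx), dtype=bool)
    for k in range(n_slices):
        h = k * dz
        disc_r2 = radius**2 - (h - radius) ** 2
        if disc_r2 > 0:
            masks[k] = r2 <= disc_r2
    truth = SynthTruth(
        "sphere_stack",
        {
            "true_volume": 4.0 / 3.0 * np.pi * radius**3,
            "radius": radius,
            "dz": dz,
            "pixel_size": pixel_size,
        },
        seed,
    )
    return LabeledStack(masks, dz=dz, pixel_size=pixel_size), truth


def make_spike_trace(
    baseline: float = 100.0,
    n_spikes: int = 5,
    amplitude_factor: float = 2.5,
    noise_sd: float = 2.0,
    n: int = 120,
    seed: int = 0,
    dt: float = 60.0,
) -> tuple[IntensityTrace, SynthTruth]:
    """Baseline + ``n_spikes`` disjoint rectangular excursions + Gaussian noise.

    Spikes are 3 samples wide, peak at ``amplitude_factor × baseline`` and are
    separated by at least 3 baseline samples, so each counts as one event
    under the >2× rule (for ``amplitude_factor`` > 2).
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    width, gap = 3, 3
    need = n_spikes * (width + gap) + gap
    if need > n:
        raise ValueError(f"{n_spikes} spikes do not fit in {n} samples")
    rng = np.random.default_rng(seed)
    value = np.full(n, baseline, dtype=float)
    if n_spikes > 0:
        # evenly spread spike starts, keeping the mandatory gaps
        starts = np.linspace(gap, n - width - gap, n_spikes).astype(int)
        for s in starts:
            value[s : s + width] = amplitude_factor * baseline
    value += rng.normal(0.0, noise_sd, size=n)
    value = np.clip(value, 0.0, None)
    truth = SynthTruth(
        "spike_trace",
        {
            "true_spike_count": n_spikes if amplitude_factor > 2 else 0,
            "baseline": baseline,
            "amplitude_factor": amplitude_factor,
            "noise_sd": noise_sd,
            "n": n,
        },
        seed,
    )
    return IntensityTrace(np.arange(n) * dt, value, baseline=baseline), truth


def make_growing_contour(
    r0: float = 10.0,
    step_growth: float = 0.1,
    n: int = 20,
    dt: float = 5.0,
) -> tuple[ContourSeries, SynthTruth]:
    """Circle growing by ``step_growth`` µm of radius per frame (noise-free)."""
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    radii = r0 + step_growth * np.arange(n)
    if np.any(radii <= 0):
        raise ValueError("contour radius must stay positive")
    series = ContourSeries(
        np.arange(n) * dt, np.pi * radii**2, 2 * np.pi * radii
    )
    truth = SynthTruth(
        "growing_contour",
        {"true_step_growth": step_growth, "r0": r0, "n": n},
        None,
    )
    return series, truth


def make_polarized_cell(
    ratio: float = 1.67,
    noise_sd: float = 0.0,
    seed: int = 0,
    rear_mean: float = 100.0,
) -> tuple[PolarizedCell, SynthTruth]:
    """Front/rear intensity pair with true front:rear ratio ``ratio``."""
    if ratio <= 0 or rear_mean <= 0:
        raise ValueError("ratio and rear_mean must be positive")
    rng = np.random.default_rng(seed)
    front = ratio * rear_mean + rng.normal(0.0, noise_sd)
    rear = rear_mean + rng.normal(0.0, noise_sd)
    if front <= 0 or rear <= 0:
        raise ValueError("noise drove an intensity non-positive; lower noise_sd")
    truth = SynthTruth(
        "polarized_cell", {"true_ratio": ratio, "noise_sd": noise_sd}, seed
    )
    return PolarizedCell(front, rear), truth


def make_edge_pattern(
    occupancy_in_band: float = 0.4,
    occupancy_out: float = 0.9,
    band: float = 1.5,
    pixel_size: float = 0.02,
    cell_size: float = 6.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SynthTruth]:
    """Binary pixel pattern inside a square cell with distinct band occupancy.

    Returns (image, edge_polygon, truth). Pixels within ``band`` µm of the
    square cell outline are ON with probability ``occupancy_in_band``; deeper
    interior pixels with probability ``occupancy_out``; exterior pixels are
    ON with probability 0.5 so that any band leakage is detectable.
    """
    for p in (occupancy_in_band, occupancy_out):
        if not 0 <= p <= 1:
            raise ValueError("occupancies must lie in [0, 1]")
    from scipy import ndimage
    from skimage.draw import polygon2mask

    margin = 1.0  # µm of exterior around the cell
    npx = int(round((cell_size + 2 * margin) / pixel_size))
    m = margin / pixel_size
    c = cell_size / pixel_size
    poly = np.array(
        [[m, m], [m, m + c], [m + c, m + c], [m + c, m]], dtype=float
    )
    interior = polygon2mask((npx, npx), poly)
    dist = ndimage.distance_transform_edt(interior) * pixel_size
    band_mask = interior & (dist <= band)
    rng = np.random.default_rng(seed)
    u = rng.random((npx, npx))
    img = np.where(
        band_mask,
        u < occupancy_in_band,
        np.where(interior, u < occupancy_out, u < 0.5),
    )
    truth = SynthTruth(
        "edge_pattern",
        {
            "true_occupancy": occupancy_in_band,
            "occupancy_out": occupancy_out,
            "band": band,
            "pixel_size": pixel_size,
        },
        seed,
    )
    return img, poly, truth


def make_ph_trace(
    slope: float = -0.015,
    noise_sd: float = 0.001,
    n: int = 20,
    dt: float = 30.0,
    r0: float = 1.2,
    seed: int = 0,
) -> tuple[IntensityTrace, SynthTruth]:
    """Linear ratiometric recovery R(t) = r0 + slope·t with Gaussian noise.

    The pH-recovery rate statistic −dR/dt recovers ``-slope``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    value = r0 + slope * t + rng.normal(0.0, noise_sd, size=n)
    truth = SynthTruth(
        "ph_trace",
        {"true_slope": slope, "true_rate": -slope, "noise_sd": noise_sd, "n": n},
        seed,
    )
    return IntensityTrace(t, value), truth


def make_kymograph_track(
    flow_speed: float = 0.05,
    dt: float = 0.4,
    n: int = 30,
    s0: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SynthTruth]:
    """Feature positions along a kymograph line moving inward at ``flow_speed``.

    Returns (t, s, truth); the retrograde-flow estimator recovers
    ``flow_speed`` as the magnitude of the fitted slope.
    """
    if n < 2 or dt <= 0:
        raise ValueError("need n >= 2 and dt > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n) * dt
    s = s0 - flow_speed * t + rng.normal(0.0, noise_sd, size=n)
    truth = SynthTruth(
        "kymograph_track",
        {"true_flow_speed": flow_speed, "dt": dt, "n": n, "noise_sd": noise_sd},
        seed,
    )
    return t, s, truth
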