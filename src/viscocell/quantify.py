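"""Quantification statistics for microscopy-derived records.

Implements the per-cell measurements used in viscosity-driven migration
studies, decoupled from image acquisition: leading-edge lamella growth,
confocal z-stack cell volume, projected lamella-area fraction, cell-track
speed and persistence, calcium-spike counting, front-to-rear polarization
ratios, edge-band actin occupancy from binarized super-resolution images,
pH-recovery (NHE1 activity) slopes, kymograph retrograde-flow slopes, and
the %w/v -> molarity/osmolarity accounting for viscous media additives.

All inputs are in µm / s / Pa unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "Track",
    "LabeledStack",
    "ContourSeries",
    "IntensityTrace",
    "PolarizedCell",
    "TrackRejected",
    "lamella_growth",
    "cell_volume",
    "lamella_area_fraction",
    "speed_and_persistence",
    "estimate_baseline",
    "calcium_spike_count",
    "front_rear_ratio",
    "storm_edge_density",
    "ph_recovery_rate",
    "retrograde_flow",
    "mass_to_molar",
    "osmolarity_contribution",
]


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Track:
    """An ordered cell trajectory: times (s) and positions (µm), optional z."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.z is not None:
            object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        if t.size < 2:
            raise ValueError("a track needs at least 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("track times must be strictly increasing")
        for name in ("x", "y"):
            if getattr(self, name).shape != t.shape:
                raise ValueError(f"{name} must match t in length")
        if self.z is not None and self.z.shape != t.shape:
            raise ValueError("z must match t in length")

    def __len__(self) -> int:
        return self.t.size

    @property
    def positions(self) -> np.ndarray:
        """(n, d) position array, d = 2 or 3."""
        cols = [self.x, self.y] + ([self.z] if self.z is not None else [])
        return np.column_stack(cols)


@dataclass(frozen=True)
class LabeledStack:
    """Binary segmentation z-stack, slices ordered from the substrate upward.

    ``masks`` has shape (n_slices, ny, nx); ``dz`` is the slice spacing in µm
    (0.5 µm for the confocal protocol this mirrors) and ``pixel_size`` the
    lateral pixel pitch in µm/px.
    """

    masks: np.ndarray
    dz: float = 0.5
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        masks = np.asarray(self.masks).astype(bool)
        object.__setattr__(self, "masks", masks)
        if masks.ndim != 3:
            raise ValueError("masks must be a (n_slices, ny, nx) array")
        if self.dz <= 0 or self.pixel_size <= 0:
            raise ValueError("dz and pixel_size must be positive")

    @property
    def slice_areas(self) -> np.ndarray:
        """Per-slice segmented area in µm²."""
        return self.masks.sum(axis=(1, 2)) * self.pixel_size**2


@dataclass(frozen=True)
class ContourSeries:
    """Per-frame cell outline measurements: times, areas (µm²), perimeters (µm)."""

    t: np.ndarray
    area: np.ndarray
    perimeter: np.ndarray

    def __post_init__(self) -> None:
        for name in ("t", "area", "perimeter"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.t.shape == self.area.shape == self.perimeter.shape):
            raise ValueError("t, area, perimeter must have equal length")
        if np.any(self.area < 0):
            raise ValueError("areas must be non-negative")
        if np.any(self.perimeter <= 0):
            raise ValueError("perimeters must be positive")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class IntensityTrace:
    """A fluorescence (or ratiometric) time series from a fixed ROI."""

    t: np.ndarray
    value: np.ndarray
    baseline: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "value", np.asarray(self.value, dtype=float))
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have equal length")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class PolarizedCell:
    """Mean intensities in manually drawn front- and rear-edge regions."""

    front_mean: float
    rear_mean: float

    def __post_init__(self) -> None:
        if self.front_mean <= 0 or self.rear_mean <= 0:
            raise ValueError("front and rear mean intensities must be positive")


class TrackRejected(ValueError):
    """Raised when a track fails the frame-count inclusion rule."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def lamella_growth(series: ContourSeries) -> np.ndarray:
    """Per-step leading-edge growth: (Area_i − Area_{i−1}) / Perimeter_{i−1} (µm).

    Normalizing each frame's area change by the previous frame's edge length
    turns areal spreading into an average edge-advance distance, so a circle
    growing by dr per frame reports ≈ dr independent of its size.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 frames")
    return np.diff(series.area) / series.perimeter[:-1]


def cell_volume(stack: LabeledStack) -> float:
    """Cell volume (µm³) by trapezoidal integration of slice areas over z.

    Each adjacent slice pair contributes dz·(A_k + A_{k+1})/2; this is exactly
    the trapezoidal rule on the area-vs-height profile.
    """
    if stack.masks.shape[0] < 2:
        raise ValueError("need at least 2 slices")
    areas = stack.slice_areas
    if not areas.any():
        import warnings

        warnings.warn("empty stack: volume is 0", stacklevel=2)
        return 0.0
    return float(np.trapezoid(areas, dx=stack.dz))


def lamella_area_fraction(stack: LabeledStack, h_crit: float = 2.0) -> float:
    """Fraction of the projected cell footprint that is thin lamella.

    The lamella is the part of the cell below a critical height ``h_crit``
    (default 2 µm, chosen above the ~1 µm typical lamella thickness to absorb
    axial aberrations). Computed as (P_all − P_above)/P_all where P_all is the
    projected area of the whole stack and P_above that of slices whose height
    k·dz exceeds h_crit.
    """
    proj_all = stack.masks.any(axis=0)
    if not proj_all.any():
        raise ValueError("empty projection: no segmented pixels in stack")
    heights = np.arange(stack.masks.shape[0]) * stack.dz
    above = stack.masks[heights > h_crit]
    proj_above = above.any(axis=0) if above.size else np.zeros_like(proj_all)
    p_all = proj_all.sum()
    return float((p_all - proj_above.sum()) / p_all)


def speed_and_persistence(
    track: Track, min_frames: int = 4, max_frames: int = 71
) -> tuple[float, float]:
    """Mean frame-to-frame speed (µm/s) and directional persistence of a track.

    Speed is the mean of displacement/Δt over consecutive frames. Persistence
    is net displacement divided by total point-to-point path length (1 for a
    straight path, → 0 for diffusive motion). Tracks shorter than
    ``min_frames`` are rejected; longer tracks are truncated to their first
    ``max_frames`` samples, mirroring the 4-frame minimum / 71-frame cap
    inclusion rule for in vivo track analysis.
    """
    if len(track) < min_frames:
        raise TrackRejected(
            f"track has {len(track)} frames; at least {min_frames} required"
        )
    pos = track.positions[:max_frames]
    t = track.t[:max_frames]
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    dts = np.diff(t)
    speed = float(np.mean(steps / dts))
    total = steps.sum()
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    persistence = net / total if total > 0 else 0.0
    return speed, float(persistence)


def estimate_baseline(
    trace: IntensityTrace,
    method: Literal["lower-quartile", "window"] = "lower-quartile",
    window: tuple[float, float] | None = None,
) -> float:
    """Baseline level of an intensity trace.

    ``lower-quartile`` (default): median of the lowest quartile of values —
    robust to the spikes themselves. ``window``: mean over a caller-supplied
    pre-stimulus time window (t_start, t_end).
    """
    if trace.baseline is not None:
        return float(trace.baseline)
    v = trace.value
    if method == "window":
        if window is None:
            raise ValueError("window method requires a (t_start, t_end) window")
        sel = (trace.t >= window[0]) & (trace.t <= window[1])
        if not sel.any():
            raise ValueError("baseline window contains no samples")
        return float(v[sel].mean())
    q1 = np.quantile(v, 0.25)
    return float(np.median(v[v <= q1]))


def calcium_spike_count(
    trace: IntensityTrace,
    baseline_method: Literal["lower-quartile", "window"] = "lower-quartile",
    window: tuple[float, float] | None = None,
    refractory_gap: int = 2,
) -> int:
    """Number of calcium spikes: excursions strictly exceeding 2× baseline.

    A spike is a contiguous supra-threshold run; runs separated by fewer than
    ``refractory_gap`` sub-threshold samples are merged into one event.
    """
    if len(trace) < 10:
        raise ValueError("need at least 10 samples to estimate a baseline")
    baseline = estimate_baseline(trace, baseline_method, window)
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    above = trace.value > 2.0 * baseline
    if not above.any():
        return 0
    # merge events separated by short sub-threshold gaps
    filled = ndimage.binary_closing(above, structure=np.ones(refractory_gap + 1))
    labels, n = ndimage.label(filled)
    return int(n)


def front_rear_ratio(cell: PolarizedCell) -> float:
    """Front-to-rear mean-intensity ratio (the polarization statistic γ)."""
    return cell.front_mean / cell.rear_mean


def storm_edge_density(
    binary_image: np.ndarray,
    edge_polygon: Sequence[tuple[float, float]] | np.ndarray,
    band: float = 1.5,
    pixel_size: float = 0.02,
) -> float:
    """Percent ON pixels within ``band`` µm of the cell edge, interior side.

    ``edge_polygon`` is the traced cell outline as (row, col) pixel vertices of
    a closed polygon; the band is the set of interior pixels whose Euclidean
    distance to the outline is at most ``band`` µm. Returns 100·ON/total over
    that band.
    """
    from skimage.draw import polygon2mask

    img = np.asarray(binary_image).astype(bool)
    verts = np.asarray(edge_polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ValueError("edge_polygon must be an (n, 2) vertex array")
    if (
        verts.min() < -0.5
        or verts[:, 0].max() > img.shape[0] - 0.5
        or verts[:, 1].max() > img.shape[1] - 0.5
    ):
        raise ValueError("edge polygon lies outside the image bounds")
    interior = polygon2mask(img.shape, verts)
    # distance (px) from each interior pixel to the nearest exterior pixel,
    # i.e. to the traced edge
    dist = ndimage.distance_transform_edt(interior) * pixel_size
    band_mask = interior & (dist <= band)
    total = band_mask.sum()
    if total == 0:
        raise ValueError("empty edge band: polygon too small for the given band")
    return float(100.0 * img[band_mask].sum() / total)


def ph_recovery_rate(trace: IntensityTrace) -> float:
    """NHE1 activity as the pH-recovery rate −dR/dt.

    Fits a least-squares line to the ratiometric signal R(t) over the supplied
    recovery window and returns the negated slope, so that recovery of a
    falling ratio (rising pH) reports a positive rate.
    """
    if len(trace) < 3:
        raise ValueError("need at least 3 samples in the recovery window")
    if np.ptp(trace.t) == 0:
        raise ValueError("degenerate window: all samples at the same time")
    res = stats.linregress(trace.t, trace.value)
    return float(-res.slope)


def retrograde_flow(t: np.ndarray, s: np.ndarray) -> float:
    """Retrograde-flow speed (µm/s) from kymograph feature positions.

    ``s`` are positions (µm) of a photo-converted feature along the kymograph
    line at times ``t``; the flow speed is the magnitude of the least-squares
    slope (the tangent of the kymograph angle after pixel/time calibration).
    """
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(t) == 0:
        raise ValueError("all samples at the same time")
    slope = np.polyfit(t, s, 1)[0]
    return float(abs(slope))


def mass_to_molar(percent_w_v: float, molecular_mass: float) -> float:
    """Convert a %w/v dose (g per 100 mL) of a polymer to µM.

    0.6% w/v of a 65 kDa polymer is 92.3 µM (92 µM at usual rounding).
    """
    if molecular_mass <= 0:
        raise ValueError("molecular mass must be positive")
    if percent_w_v < 0:
        raise ValueError("percent w/v must be non-negative")
    grams_per_litre = percent_w_v * 10.0
    return grams_per_litre / molecular_mass * 1e6


def osmolarity_contribution(concentration_uM: float) -> float:
    """Ideal-solution osmolarity contribution (µOsm) of a dissolved species.

    A non-dissociating solute contributes 1 µOsm per µM.
    """
    if concentration_uM < 0:
        raise ValueError("concentration must be non-negative")
    return float(concentration_uM)
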