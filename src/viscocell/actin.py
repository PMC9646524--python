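"""Filament-resolved stochastic simulation of lamellipodial network growth.

A 2D leading-edge segment of fixed lateral width advances against a membrane
tension ``F0`` plus, after ``t_load``, a linear-viscous dashpot load

    F_eta(i) = k_scale * eta_visc * v_{i-1}

that scales with the extracellular viscosity and the edge velocity of the
previous iteration. Barbed ends elongate, branch and cap as independent
Poisson processes (Bernoulli-thinned per time step); the edge velocity obeys
an exponential Brownian-ratchet force–velocity law with the total load shared
equally among the force-bearing ("working") filaments near the membrane.

Geometric conventions (documented simplifications):

* The edge is a straight segment of width ``edge_width`` with lateral
  periodicity; filament state reduces to a lateral coordinate and a normal
  offset ("lag") behind the edge.
* Growing barbed ends elongate toward the membrane at the free speed
  ``kon_rate`` but can never pass the edge; under load the edge is slower
  than free elongation, so lagging filaments catch up and join the working
  band. Capped filaments are left behind at the edge speed.
* New branches appear a small normal offset behind their mother's tip
  (side-branching), with orientation mother ± ``branch_angle`` and their
  pointed end anchored to the mother filament.

Units: µm, s, pN; viscosity in Pa·s (1 cP = 1e−3 Pa·s); forces are per unit
edge width (pN/µm).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "FilamentStatus",
    "Filament",
    "ActinSimParams",
    "LamellipodiumState",
    "EdgeTrace",
    "EnsembleDensity",
    "viscous_load",
    "total_load",
    "force_velocity",
    "brownian_ratchet_velocity",
    "initial_state",
    "step",
    "simulate",
    "ensemble_density",
    "cp_to_pa_s",
]

CP_TO_PA_S = 1e-3


def cp_to_pa_s(viscosity_cp: float) -> float:
    """Convert a viscosity in centipoise to Pa·s."""
    return viscosity_cp * CP_TO_PA_S


class FilamentStatus(Enum):
    GROWING = "growing"
    CAPPED = "capped"


@dataclass(frozen=True)
class Filament:
    """A single actin filament record (materialized view of the state arrays)."""

    barbed_pos: tuple[float, float]  # (lateral, normal) position, µm
    orientation: float  # rad, relative to the edge normal
    status: FilamentStatus
    pointed_anchor: int | None  # index of the mother filament, None for seeds
    birth_time: float  # s


@dataclass(frozen=True)
class ActinSimParams:
    """Parameters of the stochastic leading-edge simulation.

    ``k_scale`` is the dimensionless viscous scaling constant (default
    100,000) of the dashpot law; ``eta_visc`` the extracellular viscosity in
    Pa·s; ``F0`` the membrane-tension load per unit edge width. Kinetic rates
    are documented literature-magnitude defaults; none of the qualitative
    model behaviour is tied to their exact values.
    """

    eta_visc: float = 0.8e-3  # Pa·s (0.8 cP baseline)
    k_scale: float = 100_000.0  # dimensionless dashpot constant
    F0: float = 50.0  # pN/µm membrane tension
    kon_rate: float = 0.3  # µm/s free-load elongation speed
    branch_rate: float = 0.4  # 1/s per working filament
    cap_rate: float = 0.3  # 1/s per growing filament
    branch_angle: float = math.radians(70.0)  # rad
    edge_width: float = 1.0  # µm
    delta: float = 0.0027  # µm monomer half-size (ratchet step)
    kBT: float = 4.1e-3  # pN·µm
    dt: float = 0.05  # s
    t_load: float = 6.0  # s: viscous force switch-on
    t_end: float = 20.0  # s
    seed: int = 0
    n_seed_filaments: int = 100
    work_band: float = 0.05  # µm: force-bearing / branch-competent band
    density_band: float = 1.0  # µm: band for the density readout
    branch_offset: float = 0.075  # µm behind the mother tip for new branches

    def __post_init__(self) -> None:
        if self.eta_visc < 0:
            raise ValueError("viscosity must be non-negative")
        if self.k_scale <= 0:
            raise ValueError("k_scale must be positive")
        for name in ("kon_rate", "branch_rate", "cap_rate", "F0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.t_load > self.t_end:
            # allowed: a load that never switches on
            pass
        if max(self.branch_rate, self.cap_rate) * self.dt >= 1.0:
            raise ValueError("per-step event probability reaches 1; reduce dt")
        pmax = 1.0 - math.exp(-max(self.branch_rate, self.cap_rate) * self.dt)
        if pmax > 0.1:
            warnings.warn(
                f"per-step event probability {pmax:.3f} > 0.1; consider a "
                "smaller dt for faithful Poisson thinning",
                stacklevel=2,
            )

    @classmethod
    def from_cp(cls, viscosity_cp: float, **kwargs) -> "ActinSimParams":
        """Build params with the viscosity given in centipoise."""
        return cls(eta_visc=cp_to_pa_s(viscosity_cp), **kwargs)


# ---------------------------------------------------------------------------
# force laws
# ---------------------------------------------------------------------------


def viscous_load(k_scale: float, eta_visc: float, v_prev: float) -> float:
    """Linear-viscous dashpot load per unit edge width (pN/µm).

    F_eta = k_scale · eta_visc · v_prev, with a retracting or stalled edge
    (v_prev ≤ 0) clamped to zero load: drag opposes protrusion and cannot
    push the edge forward.
    """
    if k_scale <= 0:
        raise ValueError("k_scale must be positive")
    if eta_visc < 0:
        raise ValueError("viscosity must be non-negative")
    if v_prev <= 0:
        return 0.0
    return k_scale * eta_visc * v_prev


def total_load(F0: float, F_eta: float) -> float:
    """Total load per unit edge width: membrane tension plus viscous drag."""
    if F0 < 0:
        raise ValueError("F0 must be non-negative")
    return F0 + F_eta


def brownian_ratchet_velocity(
    F_total: float, n_working: int, params: ActinSimParams
) -> float:
    """Exponential Brownian-ratchet law with equal load sharing.

    v = kon · exp(−F_total · edge_width · delta / (n_working · kBT)); zero
    when no filament bears the load. Monotone non-increasing in F_total and
    non-decreasing in n_working.
    """
    if n_working < 0:
        raise ValueError("n_working must be non-negative")
    if n_working == 0:
        return 0.0
    exponent = F_total * params.edge_width * params.delta / (n_working * params.kBT)
    return params.kon_rate * math.exp(-exponent)


ForceVelocityLaw = Callable[[float, int, ActinSimParams], float]

#: pluggable force–velocity strategy used by :func:`step`
force_velocity: ForceVelocityLaw = brownian_ratchet_velocity


# ---------------------------------------------------------------------------
# state and stepping
# ---------------------------------------------------------------------------


@dataclass
class LamellipodiumState:
    """The evolving filament set plus leading-edge position/velocity.

    Filament attributes live in parallel arrays; ``lag`` is the normal
    distance of each barbed end behind the edge (0 = touching the membrane).
    Cumulative event counters support the pointed-vs-capped-end readout.
    """

    t: float
    edge_pos: float
    edge_vel: float
    lat: np.ndarray  # lateral positions, µm
    lag: np.ndarray  # normal offset behind the edge, µm (>= 0)
    orient: np.ndarray  # rad
    growing: np.ndarray  # bool
    anchor: np.ndarray  # int, -1 for seed filaments
    birth: np.ndarray  # s
    n_pointed_created: int
    n_capped_created: int

    @property
    def n_filaments(self) -> int:
        return self.lag.size

    @property
    def n_growing(self) -> int:
        return int(self.growing.sum())

    @property
    def n_capped(self) -> int:
        return int((~self.growing).sum())

    def working_mask(self, params: ActinSimParams) -> np.ndarray:
        return self.growing & (self.lag <= params.work_band)

    def density(self, params: ActinSimParams) -> float:
        """Filaments per µm of edge within the density band."""
        return float((self.lag <= params.density_band).sum() / params.edge_width)

    def filaments(self) -> list[Filament]:
        """Materialize the filament records (for inspection/serialization)."""
        out = []
        for i in range(self.n_filaments):
            out.append(
                Filament(
                    barbed_pos=(float(self.lat[i]), self.edge_pos - float(self.lag[i])),
                    orientation=float(self.orient[i]),
                    status=(
                        FilamentStatus.GROWING
                        if self.growing[i]
                        else FilamentStatus.CAPPED
                    ),
                    pointed_anchor=None if self.anchor[i] < 0 else int(self.anchor[i]),
                    birth_time=float(self.birth[i]),
                )
            )
        return out

    def copy(self) -> "LamellipodiumState":
        return LamellipodiumState(
            self.t,
            self.edge_pos,
            self.edge_vel,
            self.lat.copy(),
            self.lag.copy(),
            self.orient.copy(),
            self.growing.copy(),
            self.anchor.copy(),
            self.birth.copy(),
            self.n_pointed_created,
            self.n_capped_created,
        )


def initial_state(params: ActinSimParams, rng: np.random.Generator) -> LamellipodiumState:
    """Seed filaments at the edge with uniform lateral positions/orientations."""
    n = params.n_seed_filaments
    lat = rng.uniform(0.0, params.edge_width, size=n)
    orient = rng.uniform(-params.branch_angle / 2, params.branch_angle / 2, size=n)
    return LamellipodiumState(
        t=0.0,
        edge_pos=0.0,
        edge_vel=0.0,
        lat=lat,
        lag=np.zeros(n),
        orient=orient,
        growing=np.ones(n, dtype=bool),
        anchor=np.full(n, -1, dtype=np.int64),
        birth=np.zeros(n),
        n_pointed_created=n,  # each seed contributes one pointed end
        n_capped_created=0,
    )


def step(
    state: LamellipodiumState, params: ActinSimParams, rng: np.random.Generator
) -> LamellipodiumState:
    """Advance the network by one time step ``dt``.

    Order of operations: the edge advances under the current load (viscous
    term active from ``t_load`` on, driven by the previous edge velocity);
    barbed ends elongate toward/track the edge; then capping and branching
    events are drawn by Bernoulli thinning of their Poisson rates.
    """
    if max(params.cap_rate, params.branch_rate) * params.dt >= 1.0:
        raise ValueError("per-step event probability reaches 1; reduce dt")
    p_cap = 1.0 - math.exp(-params.cap_rate * params.dt)
    p_branch = 1.0 - math.exp(-params.branch_rate * params.dt)

    s = state.copy()
    # force balance and edge advance (viscous dashpot from t_load onward)
    f_eta = (
        viscous_load(params.k_scale, params.eta_visc, s.edge_vel)
        if s.t >= params.t_load
        else 0.0
    )
    n_work = int(s.working_mask(params).sum())
    v = force_velocity(total_load(params.F0, f_eta), n_work, params)
    dx = v * params.dt

    # growing tips elongate at kon toward the edge but never pass it;
    # capped tips are static and fall behind as the edge advances
    s.lag[s.growing] = np.maximum(
        s.lag[s.growing] + dx - params.kon_rate * params.dt, 0.0
    )
    s.lag[~s.growing] += dx
    s.edge_pos += dx
    s.edge_vel = v
    s.t += params.dt

    # capping: any growing barbed end
    grow_idx = np.flatnonzero(s.growing)
    if grow_idx.size:
        capped = grow_idx[rng.random(grow_idx.size) < p_cap]
        s.growing[capped] = False
        s.n_capped_created += capped.size
    # branching: growing filaments in the membrane-proximal working band
    # (ARP2/3 activation is membrane-bound); daughters appear a small offset
    # behind the mother tip with orientation mother ± branch_angle
    work_idx = np.flatnonzero(s.working_mask(params))
    if work_idx.size:
        mothers = work_idx[rng.random(work_idx.size) < p_branch]
        if mothers.size:
            signs = rng.choice([-1.0, 1.0], size=mothers.size)
            new_orient = s.orient[mothers] + signs * params.branch_angle
            new_lat = np.mod(s.lat[mothers], params.edge_width)
            new_lag = s.lag[mothers] + params.branch_offset
            s.lat = np.concatenate([s.lat, new_lat])
            s.lag = np.concatenate([s.lag, new_lag])
            s.orient = np.concatenate([s.orient, new_orient])
            s.growing = np.concatenate([s.growing, np.ones(mothers.size, dtype=bool)])
            s.anchor = np.concatenate([s.anchor, mothers.astype(np.int64)])
            s.birth = np.concatenate([s.birth, np.full(mothers.size, s.t)])
            s.n_pointed_created += mothers.size
    return s


@dataclass(frozen=True)
class EdgeTrace:
    """Time series of the leading edge and filament bookkeeping counts."""

    times: np.ndarray
    edge_pos: np.ndarray
    edge_vel: np.ndarray
    density: np.ndarray  # filaments per µm within the density band
    n_pointed: np.ndarray  # cumulative pointed ends created
    n_capped_barbed: np.ndarray  # cumulative capped barbed ends
    n_growing: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def mean_velocity(self, t_from: float | None = None) -> float:
        """Mean edge velocity, optionally restricted to t >= t_from."""
        sel = slice(None) if t_from is None else self.times >= t_from
        return float(np.mean(self.edge_vel[sel]))

    def mean_density(self, t_from: float | None = None) -> float:
        sel = slice(None) if t_from is None else self.times >= t_from
        return float(np.mean(self.density[sel]))

    def pointed_minus_capped_rate(self) -> np.ndarray:
        """Per-step excess of pointed-end over capped-barbed-end creation."""
        return np.diff(self.n_pointed) - np.diff(self.n_capped_barbed)


def simulate(params: ActinSimParams) -> EdgeTrace:
    """Run the full stochastic simulation; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    state = initial_state(params, rng)
    n_steps = int(round(params.t_end / params.dt))
    times = np.empty(n_steps)
    edge_pos = np.empty(n_steps)
    edge_vel = np.empty(n_steps)
    density = np.empty(n_steps)
    n_pointed = np.empty(n_steps, dtype=np.int64)
    n_capped = np.empty(n_steps, dtype=np.int64)
    n_growing = np.empty(n_steps, dtype=np.int64)
    for i in range(n_steps):
        state = step(state, params, rng)
        times[i] = state.t
        edge_pos[i] = state.edge_pos
        edge_vel[i] = state.edge_vel
        density[i] = state.density(params)
        n_pointed[i] = state.n_pointed_created
        n_capped[i] = state.n_capped_created
        n_growing[i] = state.n_growing
    return EdgeTrace(times, edge_pos, edge_vel, density, n_pointed, n_capped, n_growing)


@dataclass(frozen=True)
class EnsembleDensity:
    """Per-timepoint mean ± sd of the density across an ensemble of runs."""

    times: np.ndarray
    mean_density: np.ndarray
    sd_density: np.ndarray
    n_rep: int
    mean_edge_vel: np.ndarray
    mean_pointed_minus_capped: np.ndarray  # per-step creation excess


def ensemble_density(
    params: ActinSimParams,
    n_rep: int = 20,
    base_seed: int = 0,
    seeds: Sequence[int] | None = None,
) -> EnsembleDensity:
    """Ensemble statistics over ``n_rep`` independently seeded simulations.

    Replicate seeds are spawned deterministically from ``base_seed`` unless an
    explicit ``seeds`` sequence is supplied (duplicate seeds are allowed but
    warned about, and collapse the spread).
    """
    if n_rep < 2:
        raise ValueError("need at least 2 replicates")
    if seeds is None:
        ss = np.random.SeedSequence(base_seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_rep)]
    else:
        seeds = [int(s) for s in seeds]
        if len(seeds) != n_rep:
            raise ValueError("seeds must have length n_rep")
        if len(set(seeds)) < len(seeds):
            warnings.warn("duplicate replicate seeds: ensemble sd will be 0")
    traces = [simulate(replace(params, seed=s)) for s in seeds]
    dens = np.stack([tr.density for tr in traces])
    vels = np.stack([tr.edge_vel for tr in traces])
    pmc = np.stack(
        [
            np.concatenate([[0.0], tr.pointed_minus_capped_rate()])
            for tr in traces
        ]
    )
    return EnsembleDensity(
        times=traces[0].times,
        mean_density=dens.mean(axis=0),
        sd_density=dens.std(axis=0, ddof=0),
        n_rep=n_rep,
        mean_edge_vel=vels.mean(axis=0),
        mean_pointed_minus_capped=pmc.mean(axis=0),
    )
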