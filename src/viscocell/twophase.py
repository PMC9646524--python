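"""Steady-state two-phase (actin network + cytosol) model of confined migration.

A cell of length L fills a microchannel of length L0 and smallest dimension w.
On the co-moving domain x ∈ [0, L] (x = L is the leading edge) the model
couples:

* cytosol flow: incompressible, velocity ``v_c`` spatially constant, pressure
  gradient balanced by interfacial friction with the network,
  −dp/dx − η θn (v_c − v_n) = 0;
* membrane water fluxes (inward-positive) driven by hydraulic and osmotic
  pressure differences, J_water = −α[(p − p*) − RT(c − c0)], with the
  channel pressure p* felt by each face offset from the reservoir pressure by
  the hydraulic resistance d_g = 12 µ l0 / w² of the fluid column it pushes;
* network mechanics: swelling stress σn = k_σn θn, interfacial drag, and a
  focal-adhesion body force −η_st(x) θn v_n with a viscosity-regime-specific
  normalized profile (quadratic, end-loaded at baseline viscosity; quartic,
  front-loaded at elevated viscosity);
* F-/G-actin turnover: polymerization flux J_actin = J_actin_f0 θc/(θ_cc+θc)
  at the leading edge, bulk depolymerization at rate γ, G-actin diffusion,
  and a fixed total actin content ∫(θn+θc)dx = L θ*;
* ion transport: convection–diffusion with passive leak fluxes
  −k_sol (c − c0) and prescribed active fluxes at the poles; polarized cells
  carry J_active_f = −γ_polar · J_active_b (the front/rear flux-magnitude
  ratio equals the measured NHE1 polarization ratio);
* a whole-cell force balance: reservoir pressure difference, hydraulic drag
  on the displaced fluid column, adhesion traction ∫η_st θn v_n dx, and wall
  friction ξ v0 sum to zero, which selects the migration speed v0.

Conservation convention: on the steady co-moving domain all convective
fluxes are taken relative to the cell (θ(v − v0), c(v_c − v0)); this makes
the total-actin constraint and the boundary fluxes mutually exact.

Units: µm, s, Pa; concentrations in mM; RT in Pa/mM (so RT·c is an osmotic
pressure in Pa); fluxes in mM·µm/s; water fluxes and velocities in µm/s.
The built-in numeric defaults for the core parameters are documented
literature-magnitude stand-ins; regime constants (adhesion minima, friction
coefficients, polarization ratios, cell lengths) are measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_bvp

__all__ = [
    "TwoPhaseParams",
    "RegimeConfig",
    "TwoPhaseSolution",
    "SolverError",
    "LV_REGIME",
    "HV_REGIME",
    "adhesion_profile",
    "hydraulic_resistance",
    "channel_cross_section_area",
    "effective_channel_length",
    "water_flux",
    "face_pressures",
    "network_velocity",
    "polarized_ion_fluxes",
    "knockdown_nhe1",
    "solve_steady_state",
    "speed_vs_viscosity",
    "cp_to_pa_s",
]

CP_TO_PA_S = 1e-3


def cp_to_pa_s(viscosity_cp: float) -> float:
    return viscosity_cp * CP_TO_PA_S


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoPhaseParams:
    """Core (regime-independent) parameters of the two-phase model.

    Symbol collisions in the field's notation are resolved by distinct
    names: ``eta_drag`` is the interfacial (network–cytosol) friction, while
    the extracellular medium viscosity lives in :class:`RegimeConfig` as
    ``mu_medium_cp``; ``gamma_depoly`` is the F-actin depolymerization rate,
    while the NHE1 polarization ratio is ``gamma_polar`` of the regime.
    """

    eta_drag: float = 300.0  # Pa·s/(µm²·mM) interfacial friction
    k_sigma_n: float = 200.0  # Pa/mM network swelling coefficient
    gamma_depoly: float = 0.001  # 1/s F-actin depolymerization
    D_theta_c: float = 10.0  # µm²/s G-actin diffusion
    D_c: float = 100.0  # µm²/s ion diffusion
    alpha_f: float = 1e-4  # µm/(Pa·s) membrane water permeability, front
    alpha_b: float = 1e-4  # µm/(Pa·s) back
    RT: float = 2577.0  # Pa/mM (R·310 K)
    k_sol_f: float = 1.0  # µm/s passive ion permeability, front
    k_sol_b: float = 1.0  # µm/s back
    J_active_b: float = -8.0  # mM·µm/s active flux at the rear (inward +)
    J_active_f: float | None = None  # None -> −gamma_polar · J_active_b
    J_actin_f0: float = 0.04  # mM·µm/s maximal polymerization flux (front)
    J_actin_b0: float = 0.0  # mM·µm/s rear-face polymerization (0 = off)
    theta_cc: float = 0.3  # mM polymerization saturation constant
    theta_star: float = 0.6  # mM mean total actin concentration
    c0_f: float = 340.0  # mM external osmolarity, front
    c0_b: float = 340.0  # mM back
    p0_f: float = 0.0  # Pa channel-end pressure, front
    p0_b: float = 0.0  # Pa back
    L0: float = 200.0  # µm channel length
    w: float = 3.5  # µm smallest channel dimension
    front_l0_fraction: float = 0.5  # share of the open channel ahead of the cell

    def __post_init__(self) -> None:
        for name in ("D_theta_c", "D_c", "RT", "L0", "w", "theta_star"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha_f", "alpha_b", "k_sol_f", "k_sol_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.front_l0_fraction <= 1.0:
            raise ValueError("front_l0_fraction must lie in [0, 1]")


class AdhesionShape(str, Enum):
    QUADRATIC = "quadratic"
    QUARTIC = "quartic"


@dataclass(frozen=True)
class RegimeConfig:
    """Viscosity-regime constants (measured, not fitted here).

    LV is the 0.77 cP baseline; HV the 8 cP elevated-viscosity condition.
    ``eta_st0`` scales the normalized adhesion profile into a focal-adhesion
    friction coefficient; the elevated regime uses an 8× larger scale,
    mirroring the measured 8× larger maximal local focal-adhesion area.
    """

    name: str = "custom"
    b_adh: float = 0.3  # adhesion-profile minimum
    profile_shape: AdhesionShape = AdhesionShape.QUADRATIC
    eta_st0: float = 50.0  # Pa·s/(µm²·mM) focal-adhesion coefficient scale
    xi: float = 180.0  # Pa·s/µm cell–wall friction
    gamma_polar: float = 1.67  # NHE1 front/back active-flux ratio
    L_cell: float = 85.0  # µm
    mu_medium_cp: float = 0.77  # cP extracellular medium viscosity

    def __post_init__(self) -> None:
        if not 0.0 <= self.b_adh <= 1.0:
            raise ValueError("b_adh must lie in [0, 1]")
        if self.xi <= 0 or self.gamma_polar <= 0:
            raise ValueError("xi and gamma_polar must be positive")

    def validate_against(self, params: TwoPhaseParams) -> None:
        if self.L_cell >= params.L0:
            raise ValueError("cell length must be smaller than the channel length")


ETA_ST0_LV = 50.0  # Pa·s/(µm²·mM); elevated-viscosity scale is 8× this

LV_REGIME = RegimeConfig(
    name="LV",
    b_adh=0.3,
    profile_shape=AdhesionShape.QUADRATIC,
    eta_st0=ETA_ST0_LV,
    xi=180.0,
    gamma_polar=1.67,
    L_cell=85.0,
    mu_medium_cp=0.77,
)

HV_REGIME = RegimeConfig(
    name="HV",
    b_adh=0.25,
    profile_shape=AdhesionShape.QUARTIC,
    eta_st0=8.0 * ETA_ST0_LV,
    xi=900.0,
    gamma_polar=2.84,
    L_cell=125.0,
    mu_medium_cp=8.0,
)


# ---------------------------------------------------------------------------
# elementary relations
# ---------------------------------------------------------------------------


def adhesion_profile(
    x_norm: np.ndarray | float,
    b_adh: float,
    profile_shape: AdhesionShape | str = AdhesionShape.QUADRATIC,
) -> np.ndarray | float:
    """Normalized focal-adhesion strength profile on x̄ ∈ [0, 1].

    ``quadratic``: 4(1−b)(x̄ − 1/2)² + b — high at both ends, minimum b at
    mid-cell (baseline-viscosity pattern). ``quartic``: (1−b)x̄⁴ + b — high
    at the leading edge, minimum b at the rear (elevated-viscosity pattern).
    """
    x = np.asarray(x_norm, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("x_norm must lie in [0, 1]")
    shape = AdhesionShape(profile_shape)
    if shape is AdhesionShape.QUADRATIC:
        out = 4.0 * (1.0 - b_adh) * (x - 0.5) ** 2 + b_adh
    else:
        out = (1.0 - b_adh) * x**4 + b_adh
    return out if isinstance(x_norm, np.ndarray) else float(out)


def hydraulic_resistance(mu: float, l0: float, w: float) -> float:
    """Channel hydraulic-resistance coefficient d_g = 12 µ l0 / w² (Pa·s/µm).

    ``mu`` is the medium viscosity in Pa·s, ``l0`` the effective (open)
    channel length and ``w`` the smallest cross-sectional dimension.
    """
    if w <= 0:
        raise ValueError("w must be positive")
    if l0 < 0 or mu < 0:
        raise ValueError("l0 and mu must be non-negative")
    return 12.0 * mu * l0 / w**2


def channel_cross_section_area(w: float, h: float = 10.0) -> float:
    """Cross-sectional area (µm²) of a rectangular confining channel.

    The standard confining geometry is width 3.5 µm × height 10 µm = 35 µm².
    """
    if w <= 0 or h <= 0:
        raise ValueError("channel dimensions must be positive")
    return w * h


def effective_channel_length(L0: float, L_cell: float) -> float:
    """Open channel length l0 = L0 − L around a cell of length L."""
    if L_cell > L0:
        raise ValueError("cell cannot be longer than the channel")
    return L0 - L_cell


def water_flux(
    alpha: float, p_face: float, p_star: float, c_face: float, c0: float, RT: float
) -> float:
    """Inward-positive membrane water flux −α[(p − p*) − RT(c − c0)] (µm/s)."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return -alpha * ((p_face - p_star) - RT * (c_face - c0))


def face_pressures(
    p0_f: float,
    p0_b: float,
    d_g_f: float,
    d_g_b: float,
    v0: float,
    J_water_f: float,
    J_water_b: float,
) -> tuple[float, float]:
    """Hydraulic pressures felt by the cell faces inside the channel.

    The column of fluid ahead of a cell moving at v0 while taking up water at
    J_water^f is pushed at (v0 − J_water^f); the column behind is displaced
    at (v0 + J_water^b); each costs d_g times that rate.
    """
    if d_g_f < 0 or d_g_b < 0:
        raise ValueError("hydraulic resistances must be non-negative")
    p_star_f = p0_f + d_g_f * (v0 - J_water_f)
    p_star_b = p0_b - d_g_b * (v0 + J_water_b)
    return p_star_f, p_star_b


def network_velocity(
    theta_n: np.ndarray | float,
    dtheta_n_dx: np.ndarray | float,
    v_c: float,
    eta_drag: float,
    k_sigma_n: float,
    eta_st_local: np.ndarray | float,
) -> np.ndarray | float:
    """Network velocity from the pointwise force balance on the actin phase.

    Solves −k_σn dθn/dx + η θn (v_c − v_n) − η_st θn v_n = 0 for v_n. At a
    degenerate point θn = 0 the swelling-gradient term is dropped (limit
    value η v_c / (η + η_st)) with a warning.
    """
    theta = np.asarray(theta_n, dtype=float)
    grad = np.asarray(dtheta_n_dx, dtype=float)
    degenerate = theta <= 0
    if np.any(degenerate):
        warnings.warn("theta_n = 0 encountered; swelling term dropped there")
    safe_theta = np.where(degenerate, 1.0, theta)
    term = np.where(degenerate, 0.0, k_sigma_n * grad / safe_theta)
    out = (eta_drag * v_c - term) / (eta_drag + eta_st_local)
    return out if isinstance(theta_n, np.ndarray) else float(out)


def polarized_ion_fluxes(
    J_active_b: float, gamma_polar: float
) -> tuple[float, float]:
    """Front/rear active ion fluxes under the polarization rule.

    The rear flux is prescribed; the front flux is −γ_polar times it, so the
    magnitude ratio |J_f/J_b| equals the NHE1 polarization ratio and the two
    fluxes have opposite transport directions (an efflux at the rear pairs
    with a γ-fold stronger influx at the front).
    """
    if gamma_polar <= 0:
        raise ValueError("gamma_polar must be positive")
    return -gamma_polar * J_active_b, J_active_b


def knockdown_nhe1(params: TwoPhaseParams) -> TwoPhaseParams:
    """NHE1 inhibition: both active ion fluxes zeroed, all else unchanged."""
    return replace(params, J_active_b=0.0, J_active_f=0.0)


# ---------------------------------------------------------------------------
# steady-state solver
# ---------------------------------------------------------------------------


class SolverError(RuntimeError):
    """Raised when the boundary-value solver fails to converge."""

    def __init__(self, message: str, residuals: dict | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


@dataclass(frozen=True)
class TwoPhaseSolution:
    """Converged steady-state fields and diagnostics."""

    v0: float  # µm/s cell speed (positive = toward the leading edge)
    v_c: float  # µm/s cytosol velocity (spatially uniform)
    grid: np.ndarray  # x positions, µm
    theta_n: np.ndarray  # mM
    theta_c: np.ndarray  # mM
    c: np.ndarray  # mM
    p: np.ndarray  # Pa
    v_n: np.ndarray  # µm/s
    J_water_f: float
    J_water_b: float
    p_star_f: float
    p_star_b: float
    residuals: dict[str, float]
    params: TwoPhaseParams
    regime: RegimeConfig

    @property
    def front_rear_theta_n_ratio(self) -> float:
        """F-actin polarization: θn at the leading edge over θn at the rear."""
        return float(self.theta_n[-1] / self.theta_n[0])


def _actin_flux(theta_c_face: float, j0: float, theta_cc: float) -> float:
    """Saturating polymerization flux J = j0 θc/(θ_cc + θc)."""
    return j0 * theta_c_face / (theta_cc + theta_c_face)


def solve_steady_state(
    params: TwoPhaseParams,
    regime: RegimeConfig,
    n_grid: int = 201,
    tol: float = 1e-8,
    max_nodes: int = 60_000,
    guess: tuple[float, float] | None = None,
) -> TwoPhaseSolution:
    """Solve the coupled steady-state system on x ∈ [0, L_cell].

    All equations are solved together as one collocation boundary-value
    problem with the cell speed v0 and cytosol velocity v_c as unknown
    parameters. The state vector is (θn, w, θc, θc', c, c', p, m, T) where
    w = θn(v_n − v0) is the co-moving F-actin flux, m the running total-actin
    integral and T the running adhesion-traction integral; the total-actin
    constraint and the whole-cell force balance enter as boundary conditions
    on m and T, so a converged solution satisfies them to collocation
    accuracy by construction.
    """
    regime.validate_against(params)
    if n_grid < 50:
        raise ValueError("need at least 50 grid nodes")
    L = regime.L_cell
    mu = cp_to_pa_s(regime.mu_medium_cp)
    l0 = effective_channel_length(params.L0, L)
    d_g_f = hydraulic_resistance(mu, params.front_l0_fraction * l0, params.w)
    d_g_b = hydraulic_resistance(mu, (1.0 - params.front_l0_fraction) * l0, params.w)
    if params.J_active_f is None:
        J_act_f, J_act_b = polarized_ion_fluxes(params.J_active_b, regime.gamma_polar)
    else:
        J_act_f, J_act_b = params.J_active_f, params.J_active_b

    eta = params.eta_drag
    ks = params.k_sigma_n
    gam = params.gamma_depoly
    theta_floor = 1e-9 * params.theta_star

    def eta_st(x):
        return regime.eta_st0 * adhesion_profile(
            x / L, regime.b_adh, regime.profile_shape
        )

    def odes(x, y, p):
        v0, v_c = p
        u = v_c - v0
        theta_n, w_flux, theta_c, dtheta_c, c, dc, _p, _m, _T = y
        tn = np.maximum(theta_n, theta_floor)
        est = eta_st(x)
        dtheta_n = (eta * tn * u - (eta + est) * w_flux - est * v0 * tn) / ks
        return np.vstack(
            [
                dtheta_n,
                -gam * tn,
                dtheta_c,
                (u * dtheta_c - gam * tn) / params.D_theta_c,
                dc,
                u * dc / params.D_c,
                -eta * (tn * u - w_flux),
                theta_n + theta_c,
                est * (w_flux + v0 * tn),
            ]
        )

    def bcs(ya, yb, p):
        v0, v_c = p
        u = v_c - v0
        j_f = _actin_flux(yb[2], params.J_actin_f0, params.theta_cc)
        j_b = _actin_flux(ya[2], params.J_actin_b0, params.theta_cc)
        p_star_f = params.p0_f + d_g_f * v_c
        p_star_b = params.p0_b - d_g_b * v_c
        return np.array(
            [
                # rear boundary
                ya[1] - j_b,  # F-actin flux (0 unless rear polymerization)
                ya[2] * u - params.D_theta_c * ya[3] + j_b,  # G-actin flux
                ya[7],  # total-actin integral starts at 0
                ya[8],  # traction integral starts at 0
                # rear ion flux: inward-positive passive + active
                ya[4] * u
                - params.D_c * ya[5]
                - (-params.k_sol_b * (ya[4] - params.c0_b) + J_act_b),
                # rear water flux: J_water^b = u
                u - water_flux(
                    params.alpha_b, ya[6], p_star_b, ya[4], params.c0_b, params.RT
                ),
                # front boundary
                yb[1] + j_f,  # F-actin created at the leading edge
                yb[7] - L * params.theta_star,  # total actin content
                # front ion flux (outward = −inward)
                yb[4] * u
                - params.D_c * yb[5]
                + (-params.k_sol_f * (yb[4] - params.c0_f) + J_act_f),
                # front water flux: J_water^f = −u
                -u - water_flux(
                    params.alpha_f, yb[6], p_star_f, yb[4], params.c0_f, params.RT
                ),
                # whole-cell force balance
                -(params.p0_f - params.p0_b)
                - (d_g_f + d_g_b) * v_c
                - yb[8]
                - regime.xi * v0,
            ]
        )

    x0 = np.linspace(0.0, L, n_grid)
    y0 = np.zeros((9, n_grid))
    frac_n = 0.35
    y0[0] = frac_n * params.theta_star
    y0[2] = (1.0 - frac_n) * params.theta_star
    y0[4] = 0.5 * (params.c0_f + params.c0_b)
    y0[7] = params.theta_star * x0
    p_guess = np.array(guess if guess is not None else (1e-3, 1e-3))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collocation may probe rough iterates
        sol = solve_bvp(odes, bcs, x0, y0, p=p_guess, tol=tol, max_nodes=max_nodes)

    v0, v_c = (float(v) for v in sol.p)
    bc_res = bcs(sol.y[:, 0], sol.y[:, -1], sol.p)
    force_terms = np.array(
        [
            abs(params.p0_f - params.p0_b),
            abs((d_g_f + d_g_b) * v_c),
            abs(sol.y[8, -1]),
            abs(regime.xi * v0),
        ]
    )
    force_scale = max(force_terms.max(), 1e-300)
    mass = L * params.theta_star
    residuals = {
        "bvp_rms_residual": float(np.max(sol.rms_residuals)) if sol.success else np.inf,
        "actin_mass_rel": float(abs(sol.y[7, -1] - mass) / mass),
        "force_balance_rel": float(abs(bc_res[-1]) / force_scale),
        "vc_variation_rel": 0.0,  # v_c is a scalar unknown: exact by construction
        "max_bc_mismatch": float(np.max(np.abs(bc_res))),
    }
    if not sol.success:
        raise SolverError(
            f"two-phase solver did not converge: {sol.message}", residuals
        )
    if np.any(sol.y[0] < -1e-9) or np.any(sol.y[2] < -1e-9) or np.any(sol.y[4] < -1e-9):
        raise SolverError("negative concentrations in converged solution", residuals)

    u = v_c - v0
    tn = np.maximum(sol.y[0], theta_floor)
    v_n = v0 + sol.y[1] / tn
    p_star_f = params.p0_f + d_g_f * v_c
    p_star_b = params.p0_b - d_g_b * v_c
    return TwoPhaseSolution(
        v0=v0,
        v_c=v_c,
        grid=sol.x,
        theta_n=sol.y[0],
        theta_c=sol.y[2],
        c=sol.y[4],
        p=sol.y[6],
        v_n=v_n,
        J_water_f=-u,
        J_water_b=u,
        p_star_f=p_star_f,
        p_star_b=p_star_b,
        residuals=residuals,
        params=params,
        regime=regime,
    )


def speed_vs_viscosity(
    params: TwoPhaseParams,
    regime: RegimeConfig,
    viscosities_cp: Sequence[float],
    **solver_kwargs,
) -> list[dict]:
    """Solve over a sweep of medium viscosities, recomputing d_g per value.

    Regime constants other than the medium viscosity are held fixed. Returns
    one row per viscosity: {viscosity_cp, v0_um_s, converged, message}; solver
    failures are recorded and the sweep continues.
    """
    rows = []
    for mu_cp in viscosities_cp:
        if mu_cp <= 0:
            raise ValueError("viscosities must be positive")
        reg = replace(regime, name="custom", mu_medium_cp=float(mu_cp))
        try:
            sol = solve_steady_state(params, reg, **solver_kwargs)
            rows.append(
                {
                    "viscosity_cp": float(mu_cp),
                    "v0_um_s": sol.v0,
                    "converged": True,
                    "message": "",
                }
            )
        except SolverError as err:
            rows.append(
                {
                    "viscosity_cp": float(mu_cp),
                    "v0_um_s": np.nan,
                    "converged": False,
                    "message": str(err),
                }
            )
    return rows
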