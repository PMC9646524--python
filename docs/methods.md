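# Methods

`viscocell` implements two complementary biophysical models of how elevated
extracellular fluid viscosity enhances cell migration, together with the
quantification statistics used to measure that behaviour in microscopy-derived
records, and synthetic-data generators that make the whole pipeline testable
without external data. This note records the models, their assumptions, the
parameter choices, and the limits of what the tests demonstrate.

## 1. Stochastic leading-edge model (`viscocell.actin`)

### Model

A flat leading-edge segment of width `edge_width` (1 µm, laterally periodic)
advances against a total load per unit width

    F = F0 + F_eta,      F_eta(i) = k_scale · eta_visc · v_{i−1},

i.e. a constant membrane tension plus a linear-viscous dashpot whose force is
proportional to the extracellular viscosity and to the edge velocity of the
previous iteration. The dashpot is switched on at `t_load` (6 s) and
maintained to the end of the run; a retracting or stalled edge (`v ≤ 0`) is
clamped to zero drag, since viscous resistance opposes protrusion but cannot
push the edge outward.

The edge velocity follows an exponential Brownian-ratchet force–velocity law
with the load shared equally among the `n` "working" filaments (growing
barbed ends within `work_band` = 0.05 µm of the membrane):

    v = kon_rate · exp(−F · edge_width · delta / (n · kBT)),

which gives the free-load speed at zero force, approaches it again as the
load is shared among many filaments, and stalls exponentially as the force
per filament grows. The law is exposed as a pluggable strategy
(`actin.force_velocity`) so tethered-ratchet or end-tracking variants can be
substituted without touching the event loop.

Filaments undergo independent capping and branching as Poisson processes,
Bernoulli-thinned per time step (probability `1 − exp(−rate·dt)`); parameters
are validated so `rate·dt < 1` (error) and warn above a per-step probability
of 0.1. Branching is restricted to membrane-proximal (working) filaments —
the biochemical picture is that branch nucleation is activated at the
membrane — and each daughter appears `branch_offset` (0.075 µm) behind its
mother's tip with orientation mother ± 70°, its pointed end anchored to the
mother. Growing barbed ends elongate toward the membrane at the free speed
`kon_rate` but can never pass the edge; capped ends are static and fall
behind at the edge speed.

### Emergent behaviour

These rules produce the three loaded-network phenomena the package tests:

* **Densification under load.** When the dashpot engages, the edge slows
  while filament production continues, so the filament count per µm of grown
  network — the density readout, filaments within a 1 µm band of the edge —
  rises, and rises more at higher viscosity.
* **Velocity–viscosity monotonicity.** The ensemble-mean steady edge
  velocity decreases across 0.8 → 2 → 5 → 8 cP.
* **Pointed-end spike at load onset.** Pre-load, freshly branched filaments
  lag ~0.075 µm behind a nearly free-running edge and take seconds to join
  the branch-competent band, maintaining a standing pool of laggards. When
  the edge slows abruptly at `t_load`, that pool floods into the band within
  a fraction of a second and branch (pointed-end) creation transiently
  outpaces capping. The per-step excess of pointed-end over capped-barbed-end
  creation is reported in the ensemble summary.

### Parameters and numerics

`k_scale` = 100,000 (dimensionless) with η in Pa·s (1 cP = 1e−3 Pa·s), v in
µm/s and force per width in pN/µm is the documented unit convention for the
dashpot. Kinetic defaults are literature magnitudes, not fitted values:
`kon_rate` 0.3 µm/s, `branch_rate` 0.4 s⁻¹, `cap_rate` 0.3 s⁻¹, `F0` 50
pN/µm, `delta` 2.7 nm, `kBT` 4.1e−3 pN·µm, 100 seed filaments. All tested
claims about the simulator are directional or structural (conservation of
event counts, seeded determinism, ensemble orderings), never tied to these
exact numbers. `dt` = 0.05 s keeps per-step event probabilities near 0.02.
The explicit previous-velocity dashpot can ring for a few steps right after
load onset when the network is sparse (the map's local gain exceeds 1); the
default seeding density keeps the iteration damped, and ensemble means are
used for all quantitative readouts.

Geometry is deliberately reduced: orientation and lateral position are
bookkeeping for branch genealogy; forces and the density readout depend only
on the normal offset behind the edge. There is no filament bending or
severing, no monomer depletion, and no membrane shape beyond the straight
edge.

## 2. Two-phase osmotic-engine model (`viscocell.twophase`)

### Model

The confined cell is a 1D two-phase continuum on the co-moving domain
x ∈ [0, L]: an F-actin network (concentration θn, velocity v_n) and a cytosol
(pressure p, spatially uniform velocity v_c) exchanging momentum through
interfacial friction η θn (v_c − v_n). Ions (concentration c) diffuse and
convect in the cytosol; water crosses the membrane at the poles driven by
hydraulic minus osmotic pressure differences, J = −α[(p − p*) − RT(c − c0)],
inward-positive. The channel contributes hydraulic resistance d_g = 12 µ l0 /
w² per face (l0 = L0 − L split evenly front/back by default; the split is a
config knob because the geometry does not dictate it); each face feels the
reservoir pressure offset by d_g times the rate at which its fluid column is
displaced. In steady state both face displacement rates equal v_c, so
p*_f − p*_b = (d_g_f + d_g_b) v_c.

Network mechanics balance a swelling stress σn = k_σn θn, the interfacial
drag, and a focal-adhesion body force −η_st(x) θn v_n. The normalized
adhesion profile is regime-specific: quadratic 4(1−b)(x̄−½)² + b (high at
both poles, minimum b = 0.3 mid-cell) at baseline viscosity, quartic
(1−b)x̄⁴ + b (front-loaded, minimum b = 0.25 at the rear) at 8 cP, with the
elevated-viscosity scale η_st⁰ taken 8× the baseline scale, mirroring the
8× larger maximal local focal-adhesion area measured in that condition.

Actin turns over: a saturating polymerization flux J_actin = J⁰ θc/(θ_cc+θc)
converts G- to F-actin at the leading edge, depolymerization at rate γ
returns it throughout the bulk, G-actin diffuses, and the total content is
fixed, ∫(θn+θc)dx = Lθ*. Active ion fluxes are prescribed at the poles with
the polarization rule J_f = −γ_polar · J_b: the rear flux is an efflux and
the front flux a γ_polar-fold stronger influx, with γ_polar equal to the
measured NHE1 front/rear polarization ratio (1.67 at 0.77 cP, 2.84 at 8 cP).
NHE1 knockdown sets both active fluxes to zero. Finally the whole-cell force
balance — reservoir pressure difference, hydraulic drag on the displaced
columns, adhesion traction ∫η_st θn v_n dx, and wall friction ξ v0 — selects
the migration speed v0.

**Conservation convention.** On the steady co-moving domain, all convective
fluxes are taken relative to the cell: θ(v − v0) for the actin species and
c(v_c − v0) for ions. Writing the bulk conservation laws with lab-frame
fluxes on a co-moving steady domain would contradict the fixed-total-actin
constraint and the boundary fluxes (which are relative-velocity
expressions); the relative-flux form makes constraint and boundary
conditions mutually exact, and is the convention implemented.

### Numerics

The full coupled system is solved as a single collocation boundary-value
problem (`scipy.integrate.solve_bvp`, damped Newton with adaptive mesh
refinement) with the cell speed v0 and cytosol velocity v_c as unknown
parameters. The state vector is (θn, w, θc, θc′, c, c′, p, m, T) where
w = θn(v_n − v0) is the co-moving F-actin flux — this makes the network
force balance a first-order equation in θn with no divisions — m the running
total-actin integral and T the running adhesion-traction integral. The
total-actin constraint and the global force balance enter as boundary
conditions on m and T, so both are satisfied to collocation accuracy in any
converged solution; the incompressibility of v_c is exact because v_c is a
scalar unknown. Eleven boundary conditions close the 9 states + 2
parameters; the front G-actin flux condition is omitted because it is
implied by the rear conditions plus the bulk equations (including it would
make the system singular). Defaults: 201 initial mesh nodes, collocation
tolerance 1e−8, θn floored at 1e−9 θ* in divisions with degenerate points
flagged. Non-convergence raises a `SolverError` carrying the last residual
diagnostics; converged solutions report the actin-mass error, the force-
balance residual relative to the largest force term, and the maximal
boundary mismatch (all ≲ 1e−8 in practice).

### Parameters

The regime constants are measurements: b, ξ (180/900 Pa·s/µm), γ_polar
(1.67/2.84), L (85/125 µm), the 8× adhesion scale, L0 = 200 µm, w = 3.5 µm.
The core coefficients are **stand-ins of literature magnitude** (flagged in
`configs/twophase_core.yaml`), because the study-specific values are not
publicly tabulated: interfacial drag η = 300 Pa·s/(µm²·mM), k_σn = 200
Pa/mM, γ = 1e−3 s⁻¹, D_θc = 10 µm²/s, D_c = 100 µm²/s, α = 1e−4 µm/(Pa·s)
(within the 10–100 µm·atm⁻¹·s⁻¹ range used in osmotic-engine modelling),
k_sol = 1 µm/s, J_active_b = −8 mM·µm/s (osmotic-engine models use active
fluxes of order 1e−5 mol m⁻² s⁻¹ ≈ 10 mM·µm/s; a cell translocating at
~1 µm/min purely by water transit must pump roughly v0·c0 ≈ 6–7 mM·µm/s of
osmolytes), J⁰_actin = 0.04 mM·µm/s, θ_cc = 0.3 mM, θ* = 0.6 mM, c0 = 340
mM, RT = 2577 Pa/mM, open channel ends (p0 = 0). With these defaults the
model lands in a mixed actin/osmotic regime: baseline speed ≈ 1.5 µm/min,
elevated-viscosity speed ≈ 2.3 µm/min, water transit comparable to v0, and
zeroing the active fluxes cuts speed by ~28% (LV) and ~44% (HV).

Every model-level claim the tests assert is directional — faster in the
elevated-viscosity regime, knockdown hurts more there, speed non-decreasing
in medium viscosity and in γ_polar, stillness under symmetry — chosen to be
robust across reasonable stand-in values rather than tied to them.

### Mechanistic reading

Two propulsion channels coexist. The actin channel: leading-edge
polymerization drives retrograde network flow; adhesion converts it into
forward traction. The osmotic channel: polarized ion fluxes sustain a
front-high osmolyte excess, water enters at the front and leaves at the
rear, and the resulting backward cytosol stream both drags the network
(adding traction through the interfacial friction) and lets the cell advance
while displacing less of the channel's fluid column (v_c < v0), which is
exactly why elevated hydraulic resistance — higher medium viscosity —
*increases* speed in this model. The elevated-viscosity regime leans harder
on the osmotic channel (larger γ_polar, larger d_g), which is why removing
the active fluxes costs it proportionally more speed.

## 3. Quantification statistics (`viscocell.quantify`)

Each estimator implements one measurement protocol, decoupled from image
acquisition:

* **Lamella growth** per frame: (A_i − A_{i−1})/P_{i−1}, an average
  edge-advance distance in µm.
* **Cell volume**: trapezoidal integration of per-slice segmented areas over
  z (slice spacing 0.5 µm by default). Removal of out-of-focus slices is the
  caller's responsibility.
* **Lamella area fraction**: 1 − (projected area above a 2 µm critical
  height)/(total projected area); the 2 µm threshold sits above the ~1 µm
  typical lamella thickness to absorb axial aberrations.
* **Speed and persistence** of a track: mean frame-to-frame
  displacement/Δt, and net displacement over path length; tracks shorter
  than 4 frames are rejected, longer ones truncated to their first 71
  samples (the in vivo inclusion rule). Persistence of a single straight
  segment is 1; a closed loop gives 0.
* **Calcium spikes**: excursions whose values strictly exceed 2× baseline;
  contiguous supra-threshold runs count once, and runs separated by fewer
  than 2 sub-threshold samples are merged (refractory rule). The baseline
  is the median of the lowest quartile by default — robust to the spikes
  themselves — with a pre-stimulus-window override. "Greater than 2×" is
  read as a strict inequality, and events (not supra-threshold frames) are
  counted.
* **Front/rear ratio**: mean front intensity over mean rear intensity (the
  polarization statistic feeding γ_polar).
* **Edge-band occupancy**: percent ON pixels within 1.5 µm of the traced
  cell outline, interior side only (the measurement is made inside the
  cell). The band is computed by a Euclidean distance transform of the
  polygon interior.
* **pH recovery rate**: −dR/dt from a least-squares line over the recovery
  window; the window is an explicit caller choice because protocols select
  it manually.
* **Retrograde flow**: magnitude of the least-squares slope of kymograph
  feature position vs time (the tangent of the kymograph angle after
  calibration).
* **Medium chemistry**: %w/v → µM for a polymer of given molecular mass
  (0.6% of a 65 kDa polymer ↦ 92 µM), and the ideal-solution osmolarity
  contribution (1 µOsm per µM for a non-dissociating solute), which keeps
  the maximal dose ≤ 100 µOsm against ~300 mOsm basal media.

## 4. Synthetic data (`viscocell.synthdata`)

One generator per estimator, each returning its record plus a `SynthTruth`
(generator name, true parameters, seed) that serializes alongside the data.
Directional persistence uses an angular Ornstein–Uhlenbeck heading (any
stationary persistent walk suffices for the summary statistics tested);
rasterization uses the pixel-centre-inside rule; noise is additive Gaussian.
The generators emulate the *records* that microscopy pipelines export —
not the microscopy: no point-spread function, no segmentation errors, no
drift, no photobleaching. Passing recovery tests therefore demonstrates
that the estimators are correct on clean, calibrated inputs; they say
nothing about segmentation or tracking quality upstream on real data.

## 5. Workflow (`viscocell.workflow`, `viscocell.cli`)

Configs are flat key/value YAML with `include` layering (includes < file <
command-line overrides). Every run writes a JSON manifest (command, resolved
config, seeds, outputs, package version, timestamps) sufficient to reproduce
deterministic runs byte-identically; all randomness flows through explicit
seeds (replicate seeds are spawned from a base seed via `SeedSequence`). The
bundled `viscosity-demo` pipeline chains the three analyses: actin ensembles
at 0.8 vs 8 cP, two-phase speeds for both regimes ± NHE1 knockdown, and the
estimator-recovery table.

## Problem sizes and runtime

Defaults are sized for a laptop CPU: actin ensembles use 20 replicates of a
20 s simulation at dt = 0.05 s (a few hundred filaments; ~1 s per
viscosity); the two-phase solver converges in well under a second per
regime at its default mesh. The full test suite runs in well under a
minute.

## Known limitations

* The actin model's 2D geometry is a bookkeeping reduction; orientation
  statistics (e.g. the ±35° pattern of loaded networks) are outside its
  scope.
* The two-phase model is steady-state and 1D; transients, 3D shape, and the
  calcium/TRPV4/RHOA signalling layer enter only through measured regime
  constants.
* Core two-phase coefficients are stand-ins; absolute speeds are
  order-of-magnitude, and only directional comparisons should be quoted.
* The viscosity sweep holds regime constants fixed and varies only the
  hydraulic resistance, so its speed increase is small; the full
  experimental viscosity response also involves the regime constants
  (adhesion, friction, polarization) changing with viscosity.
* Estimator validation is on clean synthetic records (see §4).
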