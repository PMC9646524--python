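# Core two-phase model parameters (regime-independent).
# Units: Pa, um, s; concentrations in mM; fluxes in mM·um/s.
# Values marked "stand-in" are documented literature-magnitude defaults for
# quantities whose study-specific values are not publicly tabulated; the
# model's tested predictions are directional and hold across reasonable
# choices (see docs/methods.md).
eta_drag: 300.0        # Pa·s/(um²·mM) interfacial friction    [stand-in]
k_sigma_n: 200.0       # Pa/mM network swelling coefficient    [stand-in]
gamma_depoly: 0.001    # 1/s F-actin depolymerization          [stand-in]
D_theta_c: 10.0        # um²/s G-actin diffusion               [stand-in]
D_c: 100.0             # um²/s ion diffusion in cytoplasm      [stand-in]
alpha_f: 1.0e-4        # um/(Pa·s) water permeability, front   [stand-in]
alpha_b: 1.0e-4        # um/(Pa·s) water permeability, back    [stand-in]
RT: 2577.0             # Pa/mM (R x 310 K)
k_sol_f: 1.0           # um/s passive ion permeability, front  [stand-in]
k_sol_b: 1.0           # um/s passive ion permeability, back   [stand-in]
J_active_b: -8.0       # mM·um/s rear active flux (efflux)     [stand-in]
J_actin_f0: 0.04       # mM·um/s max polymerization flux       [stand-in]
theta_cc: 0.3          # mM polymerization saturation constant [stand-in]
theta_star: 0.6        # mM mean total actin concentration     [stand-in]
c0_f: 340.0            # mM external osmolarity, front
c0_b: 340.0            # mM external osmolarity, back
p0_f: 0.0              # Pa channel-end pressure (open channel)
p0_b: 0.0              # Pa
L0: 200.0              # um channel length (measured)
w: 3.5                 # um smallest channel dimension (measured)
front_l0_fraction: 0.5 # open channel split: half ahead, half behind
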