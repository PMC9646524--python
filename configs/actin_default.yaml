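# Stochastic leading-edge simulation defaults.
# viscosity_cp is converted to eta_visc (Pa·s) on load; 1 cP = 1e-3 Pa·s.
viscosity_cp: 0.8
k_scale: 100000        # dimensionless dashpot scaling constant
F0: 50.0               # pN/um membrane tension (literature magnitude)
kon_rate: 0.3          # um/s free-load elongation speed (literature magnitude)
branch_rate: 0.4       # 1/s per membrane-proximal filament (literature magnitude)
cap_rate: 0.3          # 1/s per growing filament (literature magnitude)
branch_angle: 1.2217   # rad (70 degrees)
edge_width: 1.0        # um, laterally periodic
delta: 0.0027          # um monomer half-size (ratchet step)
kBT: 0.0041            # pN·um at 300 K
dt: 0.05               # s; per-step event probabilities stay well below 0.1
t_load: 6.0            # s: viscous dashpot switch-on
t_end: 20.0            # s
n_seed_filaments: 100
work_band: 0.05        # um force-bearing / branch-competent band
density_band: 1.0      # um band for the density readout
branch_offset: 0.075   # um behind the mother tip for new branches
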