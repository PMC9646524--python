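# Elevated-viscosity (8 cP) regime overlay.
include: [twophase_core.yaml]
regime: HV
# Measured regime constants behind the HV preset:
#   b_adh 0.25 (quartic, front-loaded adhesion), eta_st0 8x the LV scale,
#   xi 900 Pa·s/um, gamma_polar 2.84, L_cell 125 um, mu 8 cP.
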