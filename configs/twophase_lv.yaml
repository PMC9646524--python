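# Baseline-viscosity (0.77 cP) regime overlay.
include: [twophase_core.yaml]
regime: LV
# Measured regime constants behind the LV preset:
#   b_adh 0.3 (quadratic, end-loaded adhesion), xi 180 Pa·s/um,
#   gamma_polar 1.67, L_cell 85 um, mu 0.77 cP.
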