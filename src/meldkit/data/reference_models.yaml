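# Reference score-model configuration.
#
# MELD and MELDNa are the published allocation formulas and need no
# coefficients.  The albumin-extension coefficients below are RECONSTRUCTED
# (synthetic): the exact supplementary formulas for MELD-albumin and 5vMELD
# were not available for transcription, so albumin_coeff / interaction_coeff
# were solved from the published worked examples and the requirement that the
# score never decrease as albumin falls anywhere on the 6-40 scale:
#   5vMELD(MELDNa 21.25 unrounded, albumin 2.0) = 26
#   5vMELD(MELDNa 33.75 unrounded, albumin 2.0) = 35
#   5vMELD(MELDNa 33.75 unrounded, albumin 4.0) = 34  (a 1-point reduction)
# Extended score = base + (4.0 - albumin_clamped) * (albumin_coeff
#                  + interaction_coeff * base_unrounded).
# Replace with officially published coefficients if transcribing from the
# original supplement, or regenerate with `meldkit derive`.
models:
  meld:
    base: null
    rounding: half_up
  meldna:
    base: meld
    rounding: truncate
  meld_albumin:
    base: meld
    albumin_coeff: 5.05
    interaction_coeff: -0.125
    rounding: half_up
  5vmeld:
    base: meldna
    albumin_coeff: 5.05
    interaction_coeff: -0.125
    rounding: half_up
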