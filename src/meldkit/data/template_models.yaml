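# Coefficient-file template.  MELD and MELDNa are fully specified by their
# published formulas; fill in albumin_coeff / interaction_coeff for the
# albumin extensions (transcribe published values or run `meldkit derive`).
# null coefficients are "not configured" and raise a configuration error at
# scoring time.
models:
  meld:
    base: null
    rounding: half_up
  meldna:
    base: meld
    rounding: truncate
  meld_albumin:
    base: meld
    albumin_coeff: null
    interaction_coeff: null
    rounding: half_up
  5vmeld:
    base: meldna
    albumin_coeff: null
    interaction_coeff: null
    rounding: half_up
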