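# Growth medium for the packaged toy network, analogous to a defined
# culture medium: bounded glucose and oxygen uptake, forced CO2 secretion
# and a non-growth ATP maintenance demand.  Uptake values are maximal
# uptake magnitudes (mmol/gDW/h); forced values are flux lower bounds.
uptakes:
  EX_glc_e: 10.0
  EX_o2_e: 25.0
forced:
  EX_co2_e: 0.1
  ATPM: 38.0
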