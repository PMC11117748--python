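# Free NAD concentrations (mM) per compartment used to parameterize models.
# reference = parental HEK293; "low" = chronically depleted 293mitoPARP
# measurements (60% remaining in cytosol, 10% in mitochondria).
# NADP(H) species reuse the same values unless overridden per species.
reference:
  c: 0.11
  m: 0.23
conditions:
  high:
    c: 0.11
    m: 0.23
  low:
    c: 0.066
    m: 0.023
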