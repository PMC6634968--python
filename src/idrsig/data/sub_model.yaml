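# Bundled default substitution model for the null evolution simulator.
#
# Provenance: the stationary frequencies are a disorder-biased amino-acid
# composition typical of predicted disordered regions in budding-yeast
# proteomes (polar/charged-enriched, aromatic/hydrophobic-depleted). They are
# a documented stand-in, not fitted values; supply your own model to match a
# particular proteome. Exchangeabilities default to uniform (an F81-style
# process over 20 states); a fitted symmetric exchangeability matrix can be
# provided in the same layout.
stationary_freqs:
  A: 0.070
  C: 0.005
  D: 0.060
  E: 0.080
  F: 0.020
  G: 0.070
  H: 0.020
  I: 0.030
  K: 0.080
  L: 0.050
  M: 0.010
  N: 0.080
  P: 0.070
  Q: 0.060
  R: 0.050
  S: 0.110
  T: 0.070
  V: 0.050
  W: 0.005
  Y: 0.010
exchangeabilities: uniform
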