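# Cooperative-binding feedback: marked-point reconstruction inside the
# bistable region (used for potential/noise profiles and, at larger N,
# for the system-size escape curves).
motif: cooperative
S0: 0.08
Sa: 2.0
b: 2.0
N: 300.0
gamma_m_ratio: 50.0
promoter_timescale: 1000.0
description: >-
  Cooperative feedback point (S0=0.08, Sa=2.0) with low/middle/high states
  at scaled concentrations ~0.10/0.57/1.41.
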