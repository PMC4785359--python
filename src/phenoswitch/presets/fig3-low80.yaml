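# The cooperative marked point scaled so the low state holds ~80 proteins.
motif: cooperative
S0: 0.08
Sa: 2.0
b: 2.0
N: 800.0
gamma_m_ratio: 50.0
promoter_timescale: 4000.0
description: >-
  Cooperative point (S0=0.08, Sa=2.0) at N=800: low state ~80 proteins,
  deep barriers (escape rates ~1e-6..1e-9 per protein lifetime; analytic
  estimators only at this depth).
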