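# Dimer-binding feedback with alpha = d*c = 1 and decay-rate ratio 10.
motif: dimer
S0: 0.05
Sa: 5.0
c: 10.0
d: 0.1
b: 2.0
N: 300.0
gamma_m_ratio: 50.0
promoter_timescale: 1000.0
dimer_timescale: 100.0
description: >-
  Dimer feedback with alpha = 1 (c=10, d=0.1); bistable with nearly
  balanced barriers (states ~0.14/2.8/11.1).
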