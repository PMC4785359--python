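# Dimer-binding feedback with scaled dimer decay alpha = d*c = 0.5 and
# monomer:dimer decay-rate ratio 10 (d = 0.1).
motif: dimer
S0: 0.08
Sa: 3.5
c: 5.0
d: 0.1
b: 2.0
N: 300.0
gamma_m_ratio: 50.0
promoter_timescale: 1000.0
dimer_timescale: 100.0
description: >-
  Dimer feedback with alpha = 0.5 (c=5, d=0.1); bistable with states at
  scaled total concentrations ~0.23/1.9/7.4.
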