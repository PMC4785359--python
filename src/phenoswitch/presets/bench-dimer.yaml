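# Dimer-feedback benchmark (alpha = d*c = 0.5) near the cusp of its
# bistable region, with a sparse fast-decaying dimer pool (c=0.3) so the
# monomer-dimer exchange stays affordable to simulate exactly.
motif: dimer
S0: 0.08
Sa: 3.5
c: 0.3
d: 1.6666666666666667
b: 2.0
N: 600.0
gamma_m_ratio: 50.0
promoter_timescale: 4000.0
dimer_timescale: 50.0
description: >-
  SSA benchmark, dimer motif with alpha = 0.5: states at ~66/300/700 total
  proteins, barriers ~4.7/4.2, escape times ~1e3-6e3 lifetimes.
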