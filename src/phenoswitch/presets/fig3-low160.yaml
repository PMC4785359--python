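# As fig3-low80 with the molecule scale doubled: low state ~160 proteins.
motif: cooperative
S0: 0.08
Sa: 2.0
b: 2.0
N: 1600.0
gamma_m_ratio: 50.0
promoter_timescale: 8000.0
description: >-
  Cooperative point (S0=0.08, Sa=2.0) at N=1600: low state ~160 proteins;
  doubling N doubles both pseudo-potential barriers.
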