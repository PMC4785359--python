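# Cooperative-feedback benchmark for exact-simulation comparisons: a point
# in the wide-well regime near the cusp of the bistable region, where both
# barriers are moderate (~6 k_B T-equivalents) and balanced, wells span
# hundreds of molecules (small jump-size corrections to the diffusion
# approximation), and promoter kinetics are fast enough that each
# activation burst is below one protein.
motif: cooperative
S0: 0.13
Sa: 1.8
b: 2.0
N: 1100.0
gamma_m_ratio: 50.0
promoter_timescale: 8000.0
description: >-
  SSA benchmark, cooperative motif: states at ~138/393/819 total proteins,
  pseudo-potential barriers ~6 both ways, escape times ~1e4 lifetimes.
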