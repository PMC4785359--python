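"""Map the region of basal/activated synthesis rates that supports two
phenotypic states, for both feedback motifs.

The boundary is the locus where a stable state merges with the unstable
threshold (Phi = Phi' = 0).  The printed table parameterizes it by the
monomer concentration rho* at the merge; S0*Sa -> 1/4 as rho* -> 0 is the
large-activation limit of bistability.
"""

import numpy as np

from phenoswitch import MotifParams, bistability_boundary

rho_grid = np.geomspace(0.02, 1.5, 12)

for label, template in [
    ("cooperative", MotifParams(motif="cooperative", S0=0.1, Sa=1.0, N=100.0)),
    ("dimer, alpha=0.5", MotifParams(motif="dimer", S0=0.1, Sa=1.0, N=100.0, c=5.0, d=0.1)),
    ("dimer, alpha=1.0", MotifParams(motif="dimer", S0=0.1, Sa=1.0, N=100.0, c=10.0, d=0.1)),
]:
    bc = bistability_boundary(template, rho_grid)
    print(f"\n=== {label} ===  ({bc.n_dropped} unphysical rows dropped)")
    print(f"{'rho*':>8} {'S0':>10} {'Sa':>10} {'S0*Sa':>10}  branch")
    for rho, S0, Sa, br in zip(bc.rho_star, bc.S0, bc.Sa, bc.branch):
        print(f"{rho:8.3f} {S0:10.5f} {Sa:10.4f} {S0 * Sa:10.5f}  {br}")

small = bistability_boundary(
    MotifParams(motif="cooperative", S0=0.1, Sa=1.0, N=100.0), [0.01, 0.005])
print("\nS0*Sa at rho* = 0.01, 0.005:",
      ", ".join(f"{v:.6f}" for v in small.S0 * small.Sa),
      "-> 0.25: a large activated rate Sa requires basal S0 < 1/(4 Sa) for bistability")
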