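import numpy as np
import pytest

from phenoswitch import MotifParams, COOPERATIVE, DIMER


@pytest.fixture
def coop_point() -> MotifParams:
    """A well-characterized bistable cooperative point (roots ~0.070/0.19/3.79)."""
    return MotifParams(motif=COOPERATIVE, S0=0.05, Sa=4.0, b=2.0, N=300.0)


@pytest.fixture
def dimer_point() -> MotifParams:
    """A bistable dimer-binding point with alpha = 1."""
    return MotifParams(motif=DIMER, S0=0.05, Sa=5.0, b=2.0, N=300.0, c=10.0, d=0.1)


def cooperative_cubic_roots(S0: float, Sa: float) -> np.ndarray:
    """Independent oracle: positive drift roots of the cooperative motif.

    Phi(rho) = S0 + Sa*rho^2/(1+rho^2) - rho = 0 is equivalent to the cubic
    -rho^3 + (S0+Sa)*rho^2 - rho + S0 = 0; solved by companion-matrix roots.
    """
    roots = np.roots([-1.0, S0 + Sa, -1.0, S0])
    real = roots[np.abs(roots.imag) < 1e-9].real
    return np.sort(real[real > 0])
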