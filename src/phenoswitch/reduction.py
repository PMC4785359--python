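"""State-dependent intrinsic noise of the reduced one-variable model.

The full network is collapsed to a single birth–death variable, the scaled
total protein concentration ``x = rho_T``, with three effective reactions:
bursty synthesis (events of effective stoichiometry ``q`` at propensity
``F(x)/q``, so the mean synthesis rate is ``F`` but each event moves ``q``
molecules), monomer decay (stoichiometry 1) and dimer decay (stoichiometry
2 in total-protein units).  The resulting diffusion coefficient of the
scaled SDE ``dx = Phi(x) dtau + B(x) dW`` is ``B**2 = 2*theta`` with

    theta(x) = [ q*F(x) + rho + 4*d*c*rho**2 ] / (2*N),
    F(x)     = S0 + Sa*rho**2/(1+rho**2),

each reaction contributing propensity times squared stoichiometry
(synthesis: ``(F/q)*q**2 = q*F``; dimer decay: propensity ``d*c*rho**2``
times ``2**2``).  Under rapid mRNA turnover the variance of the full
two-stage synthesis is reproduced by ``q = 1 + 2*b`` with ``b`` the
translational burst size.

``theta`` is exact (it matches the full network's fluctuation–dissipation
variance) only at the stable fixed points; carrying the same functional form
to all concentrations is the interpolating assumption that makes the
pseudo-potential integrable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import MotifParams
from .model import monomer_from_total, drift_dx

__all__ = [
    "NoiseModel",
    "effective_stoichiometry",
    "noise_theta",
    "build_noise_model",
    "reduced_variance_at_fixed_point",
]


def effective_stoichiometry(b: float) -> float:
    """Effective molecules per synthesis event, q = 1 + 2*b.

    ``b`` is the mean number of proteins translated per mRNA; bursting makes
    synthesis events rarer but larger, leaving the mean rate unchanged while
    inflating the noise.
    """
    if b < 0:
        raise ValueError(f"burst size b must be non-negative, got {b}")
    return 1.0 + 2.0 * b


def noise_theta(xT, p: MotifParams, q: float | None = None):
    """Noise intensity theta(xT) of the reduced model (scalar or array).

    ``q`` defaults to ``1 + 2*b``.  Scales as 1/N at fixed concentration:
    more molecules, relatively smaller fluctuations.
    """
    if q is None:
        q = effective_stoichiometry(p.b)
    rho = monomer_from_total(xT, p)
    rho = np.asarray(rho, dtype=float)
    synth = p.S0 + p.Sa * rho * rho / (1.0 + rho * rho)
    theta = (q * synth + rho + 4.0 * p.d * p.c * rho * rho) / (2.0 * p.N)
    return theta if theta.ndim else float(theta)


@dataclass(frozen=True)
class NoiseModel:
    """The reduced model's noise: effective stoichiometry and theta(x)."""

    q: float
    N: float
    theta: Callable

    @classmethod
    def for_params(cls, p: MotifParams, q: float | None = None) -> "NoiseModel":
        if q is None:
            q = effective_stoichiometry(p.b)
        return cls(q=q, N=p.N, theta=lambda x, _p=p, _q=q: noise_theta(x, _p, _q))


def build_noise_model(p: MotifParams, q: float | None = None) -> NoiseModel:
    """Construct the reduced noise model for ``p`` (q defaults to 1+2b)."""
    return NoiseModel.for_params(p, q=q)


def reduced_variance_at_fixed_point(p: MotifParams, x_s: float, q: float | None = None) -> float:
    """Stationary variance of the scaled concentration near a stable fixed point.

    One-variable fluctuation–dissipation relation C = -D/(2A) with
    A = Phi'(x_s) and D = 2*theta(x_s).  Multiply by N**2 for the variance in
    molecule numbers.
    """
    A = drift_dx(x_s, p)
    if A >= 0:
        raise ValueError(
            f"x_s = {x_s:.6g} is not a stable fixed point (Phi' = {A:.3g} >= 0); "
            "the linear-noise variance only exists at stable points"
        )
    D = 2.0 * noise_theta(x_s, p, q)
    return -D / (2.0 * A)
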