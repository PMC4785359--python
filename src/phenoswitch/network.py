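"""Concrete kinetics of the full reaction network, shared by FDT and SSA.

This module is the single source of truth for how the coarse parameters in
:class:`~phenoswitch.params.FullNetworkParams` translate into elementary
rate constants:

* dimerization / dissociation: ``km1 = dimer_timescale * gamma_p`` and
  ``k1 = (km1 + gamma_p2) / K1`` (concentration units).  Including the
  dimer decay rate in the association constant makes the *stationary*
  pool satisfy ``p2 = p**2/K1`` exactly at any finite exchange speed —
  the quasi-equilibrium the one-variable reduction assumes.  (With the
  naive ``k1 = km1/K1`` the pool runs ``gamma_p2/(km1+gamma_p2)`` below
  its equilibrium value; promoter occupancy enters escape barriers
  multiplied by the molecule scale ``N``, so even a percent-level pool
  deficit would bias switching times exponentially.)
* dimer–promoter binding: ``koff = promoter_timescale * gamma_p``,
  ``kon = koff / K2``;
* cooperative promoter: concerted binding of a monomer pair
  (``kon * P * (P-1)`` association, ``koff = promoter_timescale * gamma_p``
  dissociation, ``koff/kon = (K*Omega)**2``), the limit of two sequential
  site bindings with strongly asymmetric affinities.  This gives the exact
  Hill-2 occupancy ``rho**2/(1+rho**2)``; a resolved singly-bound
  intermediate would weaken the feedback by its occupancy fraction, and
  because barrier heights are ``N`` times concentration integrals even a
  percent-level occupancy deficit shifts escape times exponentially.

Promoter binding is non-sequestering: bound molecules are not removed from
the free pools (one promoter among hundreds of proteins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import FullNetworkParams, DIMER

__all__ = ["DerivedRates", "derived_rates", "occupancy", "ode_rhs"]


@dataclass(frozen=True)
class DerivedRates:
    """Elementary rate constants implied by a FullNetworkParams."""

    # dimer motif
    k1: float = 0.0       # dimerization, concentration units
    km1: float = 0.0      # dimer dissociation
    kon: float = 0.0      # promoter association: per dimer concentration
    koff: float = 0.0     # promoter dissociation
    kon_pair: float = 0.0  # cooperative: per squared monomer concentration


def derived_rates(full: FullNetworkParams) -> DerivedRates:
    fast = full.promoter_timescale * full.gamma_p
    if full.motif == DIMER:
        ts = full.dimer_timescale if full.dimer_timescale is not None else full.promoter_timescale
        fast_dim = ts * full.gamma_p
        return DerivedRates(
            k1=(fast_dim + full.gamma_p2) / full.K1,
            km1=fast_dim,
            kon=fast / full.Kprom,
            koff=fast,
        )
    return DerivedRates(koff=fast, kon_pair=fast / full.Kprom**2)


def occupancy(full: FullNetworkParams, P: float, P2: float) -> float:
    """Equilibrium probability that the promoter is in its active state.

    Dimer motif: single site bound by a dimer, ``p2/(K2 + p2)``.
    Cooperative motif: concerted pair binding, ``p^2/(K^2 + p^2)``.
    """
    if full.motif == DIMER:
        p2 = P2 / full.Omega
        return p2 / (full.Kprom + p2)
    p = P / full.Omega
    return p * p / (full.Kprom**2 + p * p)


def ode_rhs(full: FullNetworkParams, M: float, P: float, P2: float) -> tuple[float, float, float]:
    """Deterministic rates of change of (M, P, P2) in molecule numbers.

    The promoter is at quasi-equilibrium (its occupancy enters the
    transcription rate); dimerization uses the large-molecule mass-action
    form ``k1*P**2/Omega``.  Transcription rates are concentration rates, so
    the zeroth-order number flux carries a factor ``Omega``.
    """
    phi = occupancy(full, P, P2)
    dM = full.Omega * (full.k_m0 + full.k_ma * phi) - full.gamma_m * M
    if full.motif == DIMER:
        r = derived_rates(full)
        dim = r.k1 * P * P / full.Omega
        dP = full.k_p * M - full.gamma_p * P - 2.0 * dim + 2.0 * r.km1 * P2
        dP2 = dim - r.km1 * P2 - full.gamma_p2 * P2
    else:
        dP = full.k_p * M - full.gamma_p * P
        dP2 = 0.0
    return dM, dP, dP2
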