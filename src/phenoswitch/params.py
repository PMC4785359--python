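"""Parameter containers for the autoregulatory feedback motifs.

Two levels of description are used throughout the package:

* :class:`FullNetworkParams` — the unscaled kinetic rates of the full
  transcription/translation/dimerization network (the object the exact
  stochastic simulation consumes), together with the system-size parameter
  ``Omega`` that scales molecule numbers at fixed concentrations.
* :class:`MotifParams` — the scaled, reduced description in which time is
  measured in protein lifetimes (``tau = gamma_p * t``) and concentrations in
  units of the promoter dissociation scale ``K``.  The reduced drift, noise
  and escape-time machinery all operate on this form.

The mapping between the two is ``scale_full_to_motif`` /
``full_from_motif``.  For dimer-binding feedback the concentration scale is
``K = sqrt(K1 * K2)`` (monomer–dimer and dimer–promoter dissociation
constants combine), for cooperative binding ``K`` is the promoter
dissociation constant itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "COOPERATIVE",
    "DIMER",
    "FullNetworkParams",
    "MotifParams",
    "scale_full_to_motif",
    "full_from_motif",
    "ParameterError",
]

COOPERATIVE = "cooperative"
DIMER = "dimer"


class ParameterError(ValueError):
    """Raised when a kinetic parameter violates its physical constraints."""


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not (value > 0) or not math.isfinite(value):
            raise ParameterError(f"{name} must be strictly positive and finite, got {value!r}")


def _require_nonnegative(obj, names):
    for name in names:
        value = getattr(obj, name)
        if value < 0 or not math.isfinite(value):
            raise ParameterError(f"{name} must be non-negative and finite, got {value!r}")


def _check_motif(motif: str) -> str:
    if motif not in (COOPERATIVE, DIMER):
        raise ParameterError(f"motif must be {COOPERATIVE!r} or {DIMER!r}, got {motif!r}")
    return motif


@dataclass(frozen=True)
class FullNetworkParams:
    """Unscaled kinetic rates of the positive-autoregulation network.

    Parameters
    ----------
    k_m0 : float
        Basal transcription rate (concentration/time; the mRNA number flux
        is ``Omega * k_m0``).
    k_ma : float
        Extra transcription rate when the promoter is bound/active
        (concentration/time).
    gamma_m, gamma_p, gamma_p2 : float
        Decay rate constants of mRNA, protein monomers and protein dimers
        (1/time).  ``gamma_p2`` is ignored by the cooperative motif.
    k_p : float
        Translation rate per mRNA molecule (1/time).
    K1 : float
        Monomer–dimer dissociation constant (concentration).  Ignored
        (formally infinite) for the cooperative motif.
    Kprom : float
        Promoter dissociation constant: ``K2`` (dimer binds a single site)
        for the dimer motif, the effective cooperative constant ``K`` for
        the cooperative motif.
    promoter_timescale : float
        How many times faster than ``gamma_p`` the promoter binding kinetics
        relax.  The one-variable reduction assumes promoter equilibration is
        fast; beyond equilibration, each promoter activation delivers a
        transcription burst of roughly ``N*Sa/promoter_timescale`` proteins,
        so this must also be large compared to ``N*Sa`` for the reduced
        noise model to hold.  Values >= 10 are enforced.
    dimer_timescale : float or None
        Relaxation speed of the monomer-dimer exchange relative to
        ``gamma_p`` (dimer motif only); defaults to ``promoter_timescale``.
        Exchange events do not change the total protein count, so this only
        needs to be fast enough for partition quasi-equilibrium.
    Omega : float
        System-size parameter; molecule numbers are ``Omega`` times
        concentrations, so increasing ``Omega`` at fixed scaled parameters
        deepens the pseudo-potential barrier without moving fixed points.
    """

    k_m0: float
    k_ma: float
    gamma_m: float
    k_p: float
    gamma_p: float
    Omega: float
    Kprom: float
    motif: str = COOPERATIVE
    gamma_p2: float = 0.0
    K1: float = math.inf
    promoter_timescale: float = 100.0
    dimer_timescale: float | None = None

    def __post_init__(self):
        _check_motif(self.motif)
        _require_positive(self, ["k_m0", "gamma_m", "k_p", "gamma_p", "Omega", "Kprom"])
        _require_nonnegative(self, ["k_ma"])
        if self.promoter_timescale < 10:
            raise ParameterError(
                "promoter_timescale < 10 breaks the fast-equilibration regime "
                f"the reduction assumes (got {self.promoter_timescale})"
            )
        if self.dimer_timescale is not None and self.dimer_timescale < 10:
            raise ParameterError(
                f"dimer_timescale < 10 breaks dimer quasi-equilibrium (got {self.dimer_timescale})"
            )
        if self.motif == DIMER:
            if not (self.K1 > 0) or math.isinf(self.K1):
                raise ParameterError(f"K1 must be positive and finite for the dimer motif, got {self.K1!r}")
            if not (self.gamma_p2 > 0):
                raise ParameterError(f"gamma_p2 must be strictly positive for the dimer motif, got {self.gamma_p2!r}")

    @property
    def K(self) -> float:
        """Concentration scale: sqrt(K1*K2) for dimer binding, Kprom for cooperative."""
        if self.motif == DIMER:
            return math.sqrt(self.K1 * self.Kprom)
        return self.Kprom

    @property
    def burst_size(self) -> float:
        """Mean proteins translated per mRNA, b = k_p/gamma_m."""
        return self.k_p / self.gamma_m

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MotifParams:
    """Scaled parameters of the reduced one-variable model.

    ``S0`` and ``Sa`` are the basal and activated protein synthesis rates in
    units of ``gamma_p * K``; ``c = K/K1`` sets the dimer pool
    (``rho_2 = c * rho**2`` at equilibrium); ``d = gamma_p2/gamma_p`` is the
    dimer-to-monomer decay ratio, so ``alpha = d*c`` is the effective
    nonlinear-decay constant; ``b`` the translational burst size and
    ``N = Omega*K`` the number of molecules per unit scaled concentration.
    """

    motif: str
    S0: float
    Sa: float
    b: float = 2.0
    N: float = 100.0
    c: float = 0.0
    d: float = 0.0

    def __post_init__(self):
        _check_motif(self.motif)
        _require_positive(self, ["S0", "N"])
        _require_nonnegative(self, ["Sa", "b", "c", "d"])
        if self.motif == COOPERATIVE and self.c != 0.0:
            raise ParameterError("cooperative motif requires c = 0 (no dimer pool)")

    @property
    def alpha(self) -> float:
        """Effective scaled dimer decay constant, alpha = d*c."""
        return self.d * self.c

    def to_dict(self) -> dict:
        return asdict(self)


def scale_full_to_motif(full: FullNetworkParams) -> MotifParams:
    """Reduce the full kinetic rates to the scaled motif parameters.

    With ``b = k_p/gamma_m`` (burst size) and ``K`` the motif's concentration
    scale, ``S0 = k_m0*b/(gamma_p*K)`` and ``Sa = k_ma*b/(gamma_p*K)``;
    ``c = K/K1`` (0 for cooperative binding), ``d = gamma_p2/gamma_p`` and
    ``N = Omega*K``.
    """
    b = full.burst_size
    K = full.K
    if full.motif == DIMER:
        c = K / full.K1
        d = full.gamma_p2 / full.gamma_p
    else:
        c = 0.0
        d = 0.0
    return MotifParams(
        motif=full.motif,
        S0=full.k_m0 * b / (full.gamma_p * K),
        Sa=full.k_ma * b / (full.gamma_p * K),
        b=b,
        N=full.Omega * K,
        c=c,
        d=d,
    )


def full_from_motif(
    p: MotifParams,
    gamma_p: float = 1.0,
    gamma_m_ratio: float = 20.0,
    promoter_timescale: float = 100.0,
    K: float = 1.0,
    dimer_timescale: float | None = None,
) -> FullNetworkParams:
    """Construct full kinetic rates realizing the scaled parameters ``p``.

    The inverse of :func:`scale_full_to_motif` is underdetermined; the free
    choices are the absolute protein decay rate ``gamma_p`` (sets the time
    unit), the mRNA-to-protein decay ratio ``gamma_m_ratio = gamma_m/gamma_p``
    (timescale separation of the intermediate species), the promoter/dimer
    equilibration speed and the concentration scale ``K`` (``Omega = N/K``).
    """
    gamma_m = gamma_m_ratio * gamma_p
    k_p = p.b * gamma_m
    k_m0 = p.S0 * gamma_p * K / p.b
    k_ma = p.Sa * gamma_p * K / p.b
    if p.motif == DIMER:
        if p.c <= 0:
            raise ParameterError("dimer motif requires c > 0 to reconstruct K1")
        K1 = K / p.c
        Kprom = K * p.c  # K2 = K^2/K1
        gamma_p2 = p.d * gamma_p
        return FullNetworkParams(
            k_m0=k_m0, k_ma=k_ma, gamma_m=gamma_m, k_p=k_p, gamma_p=gamma_p,
            gamma_p2=gamma_p2, K1=K1, Kprom=Kprom, Omega=p.N / K, motif=DIMER,
            promoter_timescale=promoter_timescale, dimer_timescale=dimer_timescale,
        )
    return FullNetworkParams(
        k_m0=k_m0, k_ma=k_ma, gamma_m=gamma_m, k_p=k_p, gamma_p=gamma_p,
        Kprom=K, Omega=p.N / K, motif=COOPERATIVE,
        promoter_timescale=promoter_timescale,
    )
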