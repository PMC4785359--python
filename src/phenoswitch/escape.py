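"""Pseudo-potential integration and mean escape times of the two states.

The reduced dynamics ``dx = Phi(x) dtau + sqrt(2 theta(x)) dW`` define a
quasi-potential through

    dPsi/dx = -Phi(x)/theta(x),     Psi(x_L) = 0  (gauge),

whose wells sit at the stable concentrations ``x_L``, ``x_H`` and whose peak
at the unstable ``x_M`` sets the barrier heights
``dPsi = Psi(x_M) - Psi(x_{L,H})``.  Three estimators of the mean
first-passage time between the states are provided:

* ``escape_time_quadrature`` — the exact double integral of the backward
  Kolmogorov equation, e.g. for low-to-high passage (reflecting at 0,
  absorbing at ``x_H``)

      Gamma_LH = int_{x_L}^{x_H} e^{Psi(y)} int_0^{y} e^{-Psi(z)}/theta(z) dz dy,

  evaluated in log space (log-sum-exp) so deep barriers do not overflow;
* ``escape_time_parabolic`` — the saddle-point (Kramers) approximation

      Gamma = 2*pi * e^{dPsi} / ( theta(x_s) * sqrt(Psi''(x_s) |Psi''(x_M)|) ),

  with ``x_s`` the well being escaped;
* ``escape_time_constant_noise`` — the classical approximation that freezes
  ``theta`` at its value in the origin well before integrating, provided as
  the comparison baseline (it systematically over-estimates low-to-high and
  under-estimates high-to-low escape times, because the noise grows with
  the concentration).

All times are in protein-lifetime units (``tau = gamma_p t``); divide by
``gamma_p`` for absolute time.  Barrier heights scale linearly with the
molecule scale ``N``, so escape times grow exponentially with system size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_simpson
from scipy.special import logsumexp

from .params import MotifParams
from .model import FixedPoints, drift, find_fixed_points
from .reduction import NoiseModel, build_noise_model

__all__ = [
    "PotentialProfile",
    "EscapeResult",
    "pseudo_potential",
    "escape_time_parabolic",
    "escape_time_quadrature",
    "escape_time_constant_noise",
    "escape_summary",
]

PSI_EXCESS_INFINITY = 30.0  # Psi above Psi(x_H) at which the upper boundary is "infinity"


@dataclass(frozen=True)
class PotentialProfile:
    """Grids of drift, noise and pseudo-potential over the concentration axis."""

    x: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    psi: np.ndarray

    def psi_at(self, x: float) -> float:
        return float(np.interp(x, self.x, self.psi))

    def theta_at(self, x: float) -> float:
        return float(np.interp(x, self.x, self.theta))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"x": self.x, "phi": self.phi, "theta": self.theta, "psi": self.psi})


@dataclass(frozen=True)
class EscapeResult:
    """Mean switching times of the two phenotypic states.

    ``gamma_LH`` / ``gamma_HL`` are mean first-passage times low->high /
    high->low in protein-lifetime units; ``dpsi_*`` the pseudo-potential
    barriers and ``prefactor_*`` the pre-exponential factors
    (``gamma = prefactor * exp(dpsi)``).  ``method`` records the estimator.
    """

    gamma_LH: float
    gamma_HL: float
    dpsi_LH: float
    dpsi_HL: float
    prefactor_LH: float
    prefactor_HL: float
    method: str

    def to_dict(self) -> dict:
        return {
            "gamma_LH": self.gamma_LH, "gamma_HL": self.gamma_HL,
            "dpsi_LH": self.dpsi_LH, "dpsi_HL": self.dpsi_HL,
            "prefactor_LH": self.prefactor_LH, "prefactor_HL": self.prefactor_HL,
            "method": self.method,
        }


def pseudo_potential(
    p: MotifParams,
    noise: NoiseModel | None = None,
    x_max: float | None = None,
    n_grid: int = 4001,
    fp: FixedPoints | None = None,
) -> PotentialProfile:
    """Integrate Psi(x) = -int_{x_L}^{x} Phi/theta on a uniform grid.

    The grid spans ``[0, x_max]``; by default ``x_max`` extends past the high
    fixed point until the potential has climbed ``PSI_EXCESS_INFINITY`` above
    ``Psi(x_H)`` (the effective infinity of the escape integrals).  The
    cumulative integral uses Simpson's rule; the gauge ``Psi(x_L) = 0`` is
    fixed by interpolation (for a monostable system the gauge point is the
    single stable root).
    """
    if fp is None:
        fp = find_fixed_points(p)
    if noise is None:
        noise = build_noise_model(p)
    x_ref = fp.xL if fp.bistable else fp.roots[0]
    x_top = fp.xH if fp.bistable else fp.roots[-1]

    if x_max is None:
        # expand until Psi(x) - Psi(x_H) exceeds the infinity threshold
        x_max = 2.0 * x_top
        for _ in range(60):
            xs = np.linspace(max(x_top, 1e-12), x_max, 512)
            th = np.asarray(noise.theta(xs))
            if np.any(th <= 0):
                raise FloatingPointError("theta <= 0 encountered while sizing the grid")
            integrand = -np.asarray(drift(xs, p)) / th
            excess = cumulative_simpson(integrand, x=xs, initial=0.0)[-1]
            if excess >= PSI_EXCESS_INFINITY:
                break
            x_max *= 1.5
        else:  # pragma: no cover - pathological parameters
            raise FloatingPointError("could not bracket the upper reflecting boundary")

    x = np.linspace(0.0, x_max, n_grid)
    theta = np.asarray(noise.theta(x), dtype=float)
    if np.any(~np.isfinite(theta)) or np.any(theta <= 0):
        raise FloatingPointError("theta must be finite and positive on the whole grid")
    phi = np.asarray(drift(x, p), dtype=float)
    psi = cumulative_simpson(-phi / theta, x=x, initial=0.0)
    psi = psi - np.interp(x_ref, x, psi)
    return PotentialProfile(x=x, phi=phi, theta=theta, psi=psi)


def _curvature(profile: PotentialProfile, x0: float, window: float) -> float:
    """Psi'' at x0 by local quadratic least-squares fit over x0 +/- window."""
    mask = np.abs(profile.x - x0) <= window
    if mask.sum() < 5:
        # widen to the nearest 7 grid points
        idx = np.argsort(np.abs(profile.x - x0))[:7]
        mask = np.zeros_like(mask)
        mask[idx] = True
    coeff = np.polyfit(profile.x[mask] - x0, profile.psi[mask], 2)
    return 2.0 * coeff[0]


def _barriers(profile: PotentialProfile, fp: FixedPoints) -> tuple[float, float]:
    psi_L = profile.psi_at(fp.xL)
    psi_M = profile.psi_at(fp.xM)
    psi_H = profile.psi_at(fp.xH)
    return psi_M - psi_L, psi_M - psi_H


def escape_time_parabolic(
    profile: PotentialProfile,
    fp: FixedPoints,
    window_frac: float = 0.05,
    which: str = "both",
) -> EscapeResult:
    """Saddle-point (Kramers) escape times from the potential profile.

    Curvatures are taken from quadratic fits over windows of ``window_frac``
    times the inter-fixed-point distance; a profile without proper double-well
    curvature signs is rejected.  ``which`` restricts the computation to one
    direction ('LH' or 'HL'), leaving the other NaN.
    """
    if not fp.bistable:
        raise ValueError("parabolic escape time requires a bistable system")
    wL = window_frac * (fp.xM - fp.xL)
    wH = window_frac * (fp.xH - fp.xM)
    cL = _curvature(profile, fp.xL, wL)
    cM = _curvature(profile, fp.xM, min(wL, wH))
    cH = _curvature(profile, fp.xH, wH)
    if not (cL > 0 and cH > 0 and cM < 0):
        raise ValueError(
            f"not a proper double well: Psi''(xL)={cL:.3g}, Psi''(xM)={cM:.3g}, Psi''(xH)={cH:.3g}"
        )
    dpsi_LH, dpsi_HL = _barriers(profile, fp)
    g_LH = pre_LH = g_HL = pre_HL = math.nan
    if which in ("both", "LH"):
        pre_LH = 2.0 * math.pi / (profile.theta_at(fp.xL) * math.sqrt(cL * abs(cM)))
        g_LH = pre_LH * math.exp(dpsi_LH)
    if which in ("both", "HL"):
        pre_HL = 2.0 * math.pi / (profile.theta_at(fp.xH) * math.sqrt(cH * abs(cM)))
        g_HL = pre_HL * math.exp(dpsi_HL)
    return EscapeResult(
        gamma_LH=g_LH, gamma_HL=g_HL,
        dpsi_LH=dpsi_LH, dpsi_HL=dpsi_HL,
        prefactor_LH=pre_LH, prefactor_HL=pre_HL,
        method="parabolic",
    )


def _mfpt_log(x, psi, log_inv_theta, i_start, i_end, inner_from_left):
    """log of the nested MFPT double integral on the grid, trapezoid weights.

    Outer integral runs over ``x[i_start:i_end+1]``; the inner integral is the
    cumulative integral of ``e^{-psi}/theta`` from the lower reflecting
    boundary (``inner_from_left``) or from the upper reflecting boundary.
    Everything is accumulated with log-sum-exp so that arbitrarily deep wells
    (very negative psi) and high barriers never overflow.
    """
    n = len(x)
    dx = np.diff(x)
    # log of trapezoid cell integrals of e^{-psi}/theta
    g = -psi + log_inv_theta
    cell = np.logaddexp(g[:-1], g[1:]) + np.log(dx / 2.0)
    if inner_from_left:
        # inner(y_i) = integral_0^{x_i}; inner(0) = 0 -> log = -inf
        inner = np.concatenate(([-np.inf], np.logaddexp.accumulate(cell)))
    else:
        rev = np.logaddexp.accumulate(cell[::-1])[::-1]
        inner = np.concatenate((rev, [-np.inf]))
    outer_vals = psi + inner  # log integrand of the outer integral
    seg = np.logaddexp(outer_vals[i_start:i_end], outer_vals[i_start + 1 : i_end + 1]) + np.log(
        dx[i_start:i_end] / 2.0
    )
    return float(logsumexp(seg))


def escape_time_quadrature(profile: PotentialProfile, fp: FixedPoints, which: str = "both") -> EscapeResult:
    """Escape times by direct quadrature of the MFPT double integrals.

    Low-to-high: reflecting at 0, absorbing at ``x_H``; high-to-low:
    reflecting at the upper end of the grid (placed where Psi exceeds
    ``Psi(x_H) + 30``, beyond double-precision relevance), absorbing at
    ``x_L``.  This is the in-package oracle for the parabolic formula.
    ``which`` restricts the computation to one direction ('LH' or 'HL'),
    leaving the other NaN.
    """
    if not fp.bistable:
        raise ValueError("escape time requires a bistable system")
    x, psi = profile.x, profile.psi
    with np.errstate(divide="ignore"):
        log_inv_theta = -np.log(profile.theta)
    iL = int(np.searchsorted(x, fp.xL))
    iH = int(np.searchsorted(x, fp.xH))
    dpsi_LH, dpsi_HL = _barriers(profile, fp)
    g_LH = pre_LH = g_HL = pre_HL = math.nan
    for direction in ("LH", "HL"):
        if which not in ("both", direction):
            continue
        log_g = _mfpt_log(x, psi, log_inv_theta, iL, iH, inner_from_left=(direction == "LH"))
        if log_g > 700.0:
            raise FloatingPointError(
                f"escape time {direction} overflows double precision (log Gamma = {log_g:.1f}; "
                f"Psi range {psi.min():.1f}..{psi.max():.1f})"
            )
        if direction == "LH":
            g_LH = math.exp(log_g)
            pre_LH = g_LH * math.exp(-dpsi_LH)
        else:
            g_HL = math.exp(log_g)
            pre_HL = g_HL * math.exp(-dpsi_HL)
    return EscapeResult(
        gamma_LH=g_LH, gamma_HL=g_HL,
        dpsi_LH=dpsi_LH, dpsi_HL=dpsi_HL,
        prefactor_LH=pre_LH, prefactor_HL=pre_HL,
        method="quadrature",
    )


def escape_time_constant_noise(
    p: MotifParams,
    fp: FixedPoints | None = None,
    noise: NoiseModel | None = None,
    which: str = "from_low",
    method: str = "quadrature",
    n_grid: int = 4001,
) -> EscapeResult:
    """Escape times with the noise frozen at the origin well's level.

    Rebuilds the pseudo-potential with ``theta(x) = theta(x_L)`` (or
    ``theta(x_H)`` for ``which='from_high'``) and re-runs the chosen
    estimator; only the escape direction matching ``which`` is meaningful
    in the returned result.
    """
    if which not in ("from_low", "from_high"):
        raise ValueError("which must be 'from_low' or 'from_high'")
    if fp is None:
        fp = find_fixed_points(p)
    if not fp.bistable:
        raise ValueError("constant-noise escape time requires a bistable system")
    if noise is None:
        noise = build_noise_model(p)
    x0 = fp.xL if which == "from_low" else fp.xH
    theta0 = float(np.asarray(noise.theta(x0)))
    frozen = NoiseModel(q=noise.q, N=noise.N, theta=lambda x, _t=theta0: np.full_like(np.asarray(x, dtype=float), _t) if np.ndim(x) else _t)
    profile = pseudo_potential(p, noise=frozen, n_grid=n_grid, fp=fp)
    direction = "LH" if which == "from_low" else "HL"
    if method == "parabolic":
        res = escape_time_parabolic(profile, fp, which=direction)
    else:
        res = escape_time_quadrature(profile, fp, which=direction)
    return replace(res, method="constant_noise")


def escape_summary(p: MotifParams, n_grid: int = 4001) -> dict:
    """Convenience: fixed points, barriers and all analytic escape estimates."""
    fp = find_fixed_points(p)
    if not fp.bistable:
        return {"bistable": False, "roots": fp.roots}
    profile = pseudo_potential(p, n_grid=n_grid, fp=fp)
    quad = escape_time_quadrature(profile, fp)
    par = escape_time_parabolic(profile, fp)
    cn_L = escape_time_constant_noise(p, fp=fp, which="from_low", n_grid=n_grid)
    cn_H = escape_time_constant_noise(p, fp=fp, which="from_high", n_grid=n_grid)
    return {
        "bistable": True,
        "fixed_points": fp,
        "profile": profile,
        "quadrature": quad,
        "parabolic": par,
        "constant_noise_LH": cn_L.gamma_LH,
        "constant_noise_HL": cn_H.gamma_HL,
    }
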