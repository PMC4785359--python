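"""Deterministic drift, fixed points and the region of bistability.

In the fast-mRNA / fast-dimerization limit the scaled total protein
concentration ``x = rho_T = rho + 2*rho_2`` obeys

    dx/dtau = Phi(x) = S0 + Sa * rho**2/(1 + rho**2) - rho - 2*alpha*rho**2

where ``rho`` is the free-monomer concentration obtained from ``x`` through
the dimerization equilibrium ``rho + 2*c*rho**2 = x`` (``rho_2 = c*rho**2``)
and ``alpha = d*c`` collects the nonlinear dimer decay.  Cooperative binding
is the ``c = alpha = 0`` special case, where ``x = rho`` and the drift is
``S0 + Sa*rho**2/(1+rho**2) - rho``.

For parameters inside the bistable region the drift has three non-negative
roots ``xL < xM < xH`` — two stable phenotypic states separated by an
unstable threshold.  The boundary of that region is where a stable root and
the unstable root merge: ``Phi(rho*) = Phi'(rho*) = 0``, which at fixed
``rho*`` is *linear* in ``(S0, Sa)`` and hence solvable in closed form for
both motifs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .params import MotifParams, COOPERATIVE, DIMER

__all__ = [
    "FixedPoints",
    "BoundaryCurve",
    "monomer_from_total",
    "drift",
    "drift_dx",
    "find_fixed_points",
    "is_bistable",
    "bistability_boundary",
]


class RootFindingError(RuntimeError):
    """Root refinement failed to converge; carries bracketing diagnostics."""


def monomer_from_total(xT, p: MotifParams):
    """Free-monomer concentration rho solving rho + 2*c*rho**2 = xT.

    The unique non-negative root of the dimerization-equilibrium quadratic;
    reduces to the identity for cooperative binding (c = 0).  Accepts scalars
    or arrays.
    """
    xT = np.asarray(xT, dtype=float)
    if np.any(xT < 0):
        raise ValueError("total concentration xT must be non-negative")
    if p.c == 0.0:
        return xT if xT.ndim else float(xT)
    # rho = (-1 + sqrt(1 + 8 c xT)) / (4 c), written to avoid cancellation
    rho = 2.0 * xT / (1.0 + np.sqrt(1.0 + 8.0 * p.c * xT))
    return rho if rho.ndim else float(rho)


def _total_from_monomer(rho, p: MotifParams):
    return rho + 2.0 * p.c * rho * rho


def drift(xT, p: MotifParams):
    """Deterministic drift Phi(xT) of the scaled total protein concentration."""
    rho = monomer_from_total(xT, p)
    hill = rho * rho / (1.0 + rho * rho)
    return p.S0 + p.Sa * hill - rho - 2.0 * p.alpha * rho * rho


def _dphi_drho(rho, p: MotifParams):
    return p.Sa * 2.0 * rho / (1.0 + rho * rho) ** 2 - 1.0 - 4.0 * p.alpha * rho


def drift_dx(xT, p: MotifParams):
    """Derivative dPhi/dxT (chain rule through the dimer equilibrium)."""
    rho = monomer_from_total(xT, p)
    return _dphi_drho(rho, p) / (1.0 + 4.0 * p.c * rho)


@dataclass(frozen=True)
class FixedPoints:
    """Non-negative roots of the drift with their linear stability.

    ``roots`` are in units of scaled total concentration ``rho_T``, sorted
    ascending; ``stable[i]`` is True where ``Phi'(roots[i]) < 0``.  For a
    bistable system the accessors ``xL``, ``xM``, ``xH`` name the low stable,
    middle unstable and high stable concentrations.  ``marginal`` flags a
    near-degenerate (merged-root) system where escape theory is invalid.
    """

    roots: tuple
    stable: tuple
    marginal: bool = False

    @property
    def bistable(self) -> bool:
        return len(self.roots) == 3 and not self.marginal

    def _req_bistable(self):
        if not self.bistable:
            raise ValueError("system is not bistable; no xL/xM/xH labelling")

    @property
    def xL(self) -> float:
        self._req_bistable()
        return self.roots[0]

    @property
    def xM(self) -> float:
        self._req_bistable()
        return self.roots[1]

    @property
    def xH(self) -> float:
        self._req_bistable()
        return self.roots[2]


def _root_scan_upper_bound(p: MotifParams) -> float:
    # any root satisfies rho <= S0 + Sa, i.e. xT <= g(S0+Sa); factor 2 margin
    return 2.0 * _total_from_monomer(p.S0 + p.Sa, p)


def find_fixed_points(
    p: MotifParams,
    n_scan: int = 2000,
    merge_rtol: float = 1e-6,
) -> FixedPoints:
    """All non-negative roots of Phi with stability classification.

    Sign-scans Phi on a log-spaced grid over ``[x_lo, x_max]`` with
    ``x_max = 2*g(S0+Sa)`` (an upper bound on any root) and refines each
    bracket by Brent's method to 1e-12 relative tolerance.  Roots closer than
    ``merge_rtol`` (relative) are merged and the result flagged ``marginal``:
    at a vanishing barrier the escape-time machinery is not meaningful.
    """
    x_hi = _root_scan_upper_bound(p)
    x_lo = min(1e-6, 1e-3 * p.S0)
    grid = np.geomspace(x_lo, x_hi, n_scan)
    grid = np.concatenate(([0.0], grid))
    vals = drift(grid, p)

    roots = []
    if vals[0] == 0.0:  # S0 > 0 makes this impossible, but stay defensive
        roots.append(0.0)
    sign = np.sign(vals)
    for i in range(len(grid) - 1):
        if sign[i] == 0.0:
            continue
        if sign[i + 1] == 0.0:
            roots.append(float(grid[i + 1]))
        elif sign[i] * sign[i + 1] < 0:
            a, b = float(grid[i]), float(grid[i + 1])
            try:
                r = brentq(lambda x: drift(x, p), a, b, xtol=1e-300, rtol=1e-12, maxiter=200)
            except Exception as exc:  # pragma: no cover - defensive
                raise RootFindingError(
                    f"refinement failed in bracket [{a:.6g}, {b:.6g}] "
                    f"(Phi = {vals[i]:.3g}, {vals[i + 1]:.3g})"
                ) from exc
            roots.append(float(r))

    roots = sorted(set(roots))
    # merge near-degenerate roots (boundary cusp)
    merged, marginal = [], False
    for r in roots:
        if merged and abs(r - merged[-1]) <= merge_rtol * max(abs(r), 1e-30):
            marginal = True
            merged[-1] = 0.5 * (merged[-1] + r)
        else:
            merged.append(r)
    if len(merged) == 2:
        # a tangency the scan resolved as two sign changes plus a graze, or a
        # genuine double root: treat as marginal, keep the outermost pair mean
        marginal = True
    stable = tuple(bool(drift_dx(r, p) < 0) for r in merged)
    return FixedPoints(roots=tuple(merged), stable=stable, marginal=marginal)


def is_bistable(p: MotifParams, merge_rtol: float = 1e-6) -> tuple[bool, FixedPoints]:
    """Whether the deterministic system has two stable states; returns the roots too."""
    fp = find_fixed_points(p, merge_rtol=merge_rtol)
    return fp.bistable, fp


@dataclass(frozen=True)
class BoundaryCurve:
    """Parametric bistability boundary in the (Sa, S0) plane.

    Each row is the parameter pair at which the drift has a degenerate double
    root at monomer concentration ``rho_star`` (``Phi = Phi' = 0``).
    ``branch`` labels rows by their side of the cusp (the minimum of
    ``Sa(rho_star)``): 'lower' for the small-``rho_star`` branch, 'upper'
    otherwise.  ``n_dropped`` counts grid points whose closed-form solution
    had a non-positive synthesis rate (outside the physical region).
    """

    rho_star: np.ndarray
    S0: np.ndarray
    Sa: np.ndarray
    branch: np.ndarray
    n_dropped: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"rho_star": self.rho_star, "S0": self.S0, "Sa": self.Sa, "branch": self.branch}
        )


def _boundary_point(rho: float, p: MotifParams) -> tuple[float, float]:
    """Solve Phi(rho)=Phi'(rho)=0 for (S0, Sa) at fixed double-root location rho.

    Writing Phi = S0 + Sa*h(rho) - g(rho) with h = rho^2/(1+rho^2) and
    g = rho + 2*alpha*rho^2, the system is linear: Sa = g'/h', S0 = g - Sa*h.
    For cooperative binding this is Sa = (1+rho^2)^2/(2 rho),
    S0 = rho (1 - rho^2)/2.
    """
    h = rho * rho / (1.0 + rho * rho)
    hp = 2.0 * rho / (1.0 + rho * rho) ** 2
    g = rho + 2.0 * p.alpha * rho * rho
    gp = 1.0 + 4.0 * p.alpha * rho
    Sa = gp / hp
    S0 = g - Sa * h
    return S0, Sa


def bistability_boundary(p_template: MotifParams, rho_star_grid: Sequence[float]) -> BoundaryCurve:
    """Bistability boundary of the motif fixed by ``p_template`` (its c, d).

    For each requested double-root location ``rho_star`` the unique
    ``(S0, Sa)`` with ``Phi(rho_star) = Phi'(rho_star) = 0`` is computed in
    closed form; rows with non-positive ``S0`` or ``Sa`` are dropped (and
    counted), since synthesis rates must be positive.
    """
    rho_star_grid = np.asarray(rho_star_grid, dtype=float)
    if np.any(rho_star_grid <= 0):
        raise ValueError("rho_star grid values must be strictly positive")

    rows = []
    for rho in rho_star_grid:
        S0, Sa = _boundary_point(float(rho), p_template)
        rows.append((float(rho), S0, Sa))
    kept = [(r, s0, sa) for (r, s0, sa) in rows if s0 > 0 and sa > 0]
    n_dropped = len(rows) - len(kept)

    # cusp = minimum of Sa along the curve; locate on a fine auxiliary grid
    aux = np.geomspace(1e-4, 10.0, 4000)
    sa_aux = np.array([_boundary_point(float(r), p_template)[1] for r in aux])
    rho_cusp = float(aux[np.argmin(sa_aux)])

    rho_arr = np.array([r for r, _, _ in kept])
    s0_arr = np.array([s for _, s, _ in kept])
    sa_arr = np.array([s for _, _, s in kept])
    branch = np.where(rho_arr < rho_cusp, "lower", "upper")
    return BoundaryCurve(rho_star=rho_arr, S0=s0_arr, Sa=sa_arr, branch=branch, n_dropped=n_dropped)
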