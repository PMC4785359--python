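"""Fluctuation–dissipation (linear-noise) machinery on the full network.

Linearizing the reaction network around a stable stationary point gives a
multivariate Ornstein–Uhlenbeck process whose stationary covariance ``C``
solves the continuous Lyapunov equation

    J C + C J^T + D = 0,

with ``J`` the Jacobian of the deterministic rates and
``D = sum_k a_k v_k v_k^T`` the diffusion matrix built from reaction
propensities ``a_k`` and stoichiometry vectors ``v_k``.  (Written with the
drift as ``-A x``, ``A = -J``; in one dimension the relation is the familiar
``C = -D/(2A)`` with ``A = J < 0``.)

``match_q`` is the numerical route to the reduced model's effective
stoichiometry: it finds the ``q`` for which the one-variable model's
stationary variance equals the full network's total-protein variance — the
operational definition behind the rapid-mRNA-decay formula ``q = 1 + 2b``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov, eigvals
from scipy.optimize import brentq

from .params import FullNetworkParams, DIMER, scale_full_to_motif
from .network import derived_rates, occupancy, ode_rhs
from .reduction import reduced_variance_at_fixed_point

__all__ = [
    "LinearizedSystem",
    "full_stationary_points",
    "linearize",
    "stationary_covariance",
    "total_protein_variance",
    "match_q",
]


@dataclass(frozen=True)
class LinearizedSystem:
    """Jacobian J, diffusion matrix D and stationary point of the linearization.

    Species order is ``("M", "P")`` for cooperative binding and
    ``("M", "P", "P2")`` for dimer binding; the promoter is adiabatically
    eliminated (its equilibrium occupancy and occupancy derivatives enter the
    transcription row of ``J``; being non-sequestering it contributes no row
    of ``D``).
    """

    species: tuple
    J: np.ndarray
    D: np.ndarray
    x_s: np.ndarray


def full_stationary_points(full: FullNetworkParams, n_scan: int = 4000) -> list[dict]:
    """Stationary states of the full deterministic ODEs, in molecule numbers.

    Parameterized by the monomer count ``P``: mRNA and dimer are at their
    stationary values given ``P``, and the remaining scalar residual (the
    monomer balance) is sign-scanned and refined.  Returns a list of dicts
    with keys ``M``, ``P``, ``P2`` and ``stable`` (all Jacobian eigenvalues
    in the left half-plane), ordered by increasing total protein.
    """
    r = derived_rates(full)

    def _state(P: float) -> tuple[float, float, float]:
        if full.motif == DIMER:
            P2 = (r.k1 / full.Omega) * P * P / (r.km1 + full.gamma_p2)
        else:
            P2 = 0.0
        M = full.Omega * (full.k_m0 + full.k_ma * occupancy(full, P, P2)) / full.gamma_m
        return M, P, P2

    def _residual(P: float) -> float:
        M, P_, P2 = _state(P)
        return ode_rhs(full, M, P_, P2)[1]

    b = full.k_p / full.gamma_m
    P_hi = 2.0 * full.Omega * (full.k_m0 + full.k_ma) * b / full.gamma_p + 10.0
    grid = np.concatenate(([0.0], np.geomspace(1e-3, P_hi, n_scan)))
    vals = np.array([_residual(P) for P in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(_residual, grid[i], grid[i + 1], rtol=1e-12))

    out = []
    for P in roots:
        M, P_, P2 = _state(P)
        sys_ = linearize(full, np.array([M, P_, P2])[: (3 if full.motif == DIMER else 2)], check=False)
        stable = bool(np.all(eigvals(sys_.J).real < 0))
        out.append({"M": M, "P": P_, "P2": P2, "stable": stable})
    out.sort(key=lambda s: s["P"] + 2 * s["P2"])
    return out


def _occupancy_grad(full: FullNetworkParams, P: float, P2: float) -> tuple[float, float]:
    hP = 1e-6 * max(P, 1.0)
    hP2 = 1e-6 * max(P2, 1.0)
    dP = (occupancy(full, P + hP, P2) - occupancy(full, max(P - hP, 0.0), P2)) / (P + hP - max(P - hP, 0.0))
    dP2 = (occupancy(full, P, P2 + hP2) - occupancy(full, P, max(P2 - hP2, 0.0))) / (P2 + hP2 - max(P2 - hP2, 0.0))
    return dP, dP2


def linearize(full: FullNetworkParams, x_s, check: bool = True, rtol: float = 1e-6) -> LinearizedSystem:
    """Assemble Jacobian and diffusion matrix at a stationary point ``x_s``.

    ``x_s`` is ``(M, P)`` for the cooperative motif, ``(M, P, P2)`` for the
    dimer motif, in molecule numbers.  With ``check=True`` the deterministic
    stationarity of ``x_s`` is verified and a residual-bearing error raised
    otherwise.
    """
    x_s = np.asarray(x_s, dtype=float)
    dimer = full.motif == DIMER
    if dimer:
        M, P, P2 = x_s
    else:
        M, P = x_s
        P2 = 0.0

    if check:
        res = np.array(ode_rhs(full, M, P, P2))[: (3 if dimer else 2)]
        scale = max(full.Omega * (full.k_m0 + full.k_ma), full.gamma_p * max(P, 1.0))
        if np.any(np.abs(res) > rtol * scale):
            raise ValueError(
                f"x_s is not stationary: ODE residuals {res} exceed {rtol:.1e} * {scale:.3g}"
            )

    r = derived_rates(full)
    dphi_dP, dphi_dP2 = _occupancy_grad(full, P, P2)
    phi = occupancy(full, P, P2)
    a_tx = full.Omega * (full.k_m0 + full.k_ma * phi)  # transcription propensity, number units

    if dimer:
        dim_grad = 2.0 * r.k1 * P / full.Omega  # d(k1 P^2/Omega)/dP
        J = np.array([
            [-full.gamma_m, full.Omega * full.k_ma * dphi_dP, full.Omega * full.k_ma * dphi_dP2],
            [full.k_p, -full.gamma_p - 2.0 * dim_grad, 2.0 * r.km1],
            [0.0, dim_grad, -r.km1 - full.gamma_p2],
        ])
        a_dim = r.k1 * P * P / full.Omega
        reactions = [
            (a_tx, (1, 0, 0)),                          # transcription
            (full.gamma_m * M, (-1, 0, 0)),             # mRNA decay
            (full.k_p * M, (0, 1, 0)),                  # translation
            (full.gamma_p * P, (0, -1, 0)),             # monomer decay
            (a_dim, (0, -2, 1)),                        # dimerization
            (r.km1 * P2, (0, 2, -1)),                   # dissociation
            (full.gamma_p2 * P2, (0, 0, -1)),           # dimer decay
        ]
        species = ("M", "P", "P2")
    else:
        J = np.array([
            [-full.gamma_m, full.Omega * full.k_ma * dphi_dP],
            [full.k_p, -full.gamma_p],
        ])
        reactions = [
            (a_tx, (1, 0)),
            (full.gamma_m * M, (-1, 0)),
            (full.k_p * M, (0, 1)),
            (full.gamma_p * P, (0, -1)),
        ]
        species = ("M", "P")

    n = len(species)
    D = np.zeros((n, n))
    for a, v in reactions:
        v = np.asarray(v, dtype=float)
        if a > 0:
            D += a * np.outer(v, v)
    return LinearizedSystem(species=species, J=J, D=D, x_s=x_s)


def stationary_covariance(sys: LinearizedSystem) -> np.ndarray:
    """Stationary covariance solving J C + C J^T + D = 0.

    Requires a stable Jacobian (spectral abscissa < 0).  The solution is
    symmetrized and its Lyapunov residual checked to 1e-10 relative; an
    ill-conditioned solve triggers a warning carrying the condition number.
    """
    lam = eigvals(sys.J)
    if np.max(lam.real) >= 0:
        raise ValueError(f"Jacobian is not stable (eigenvalue real parts {lam.real})")
    C = solve_continuous_lyapunov(sys.J, -sys.D)
    C = 0.5 * (C + C.T)
    resid = np.linalg.norm(sys.J @ C + C @ sys.J.T + sys.D)
    scale = np.linalg.norm(sys.D)
    if scale > 0 and resid / scale > 1e-10:
        cond = np.linalg.cond(sys.J)
        warnings.warn(
            f"Lyapunov solve residual {resid / scale:.2e} (Jacobian condition number {cond:.2e})",
            RuntimeWarning,
        )
    return C


def total_protein_variance(sys: LinearizedSystem, C: np.ndarray | None = None) -> float:
    """Variance of the total protein count P + 2*P2 from the linearization."""
    if C is None:
        C = stationary_covariance(sys)
    w = np.zeros(len(sys.species))
    w[sys.species.index("P")] = 1.0
    if "P2" in sys.species:
        w[sys.species.index("P2")] = 2.0
    return float(w @ C @ w)


def match_q(full: FullNetworkParams, x_s=None) -> float:
    """Effective stoichiometry matched to the full network's variance.

    Finds the ``q`` for which the reduced one-variable model's stationary
    variance of the scaled total protein concentration equals the full
    network's linear-noise variance at the same stable stationary point
    (a scalar root solve; the reduced variance is affine in ``q``).  In the
    rapid-mRNA-decay, fast-dimerization regime the result reproduces
    ``q = 1 + 2b``.
    """
    if x_s is None:
        stables = [s for s in full_stationary_points(full) if s["stable"]]
        if len(stables) != 1:
            raise ValueError(
                f"expected a unique stable stationary point, found {len(stables)}; "
                "pass x_s explicitly"
            )
        s = stables[0]
        x_s = np.array([s["M"], s["P"], s["P2"]])[: (3 if full.motif == DIMER else 2)]

    sys_ = linearize(full, x_s)
    var_full = total_protein_variance(sys_)

    p = scale_full_to_motif(full)
    x_s = np.asarray(x_s, dtype=float)
    P = x_s[1]
    P2 = x_s[2] if full.motif == DIMER else 0.0
    x_scaled = (P + 2.0 * P2) / p.N

    def mismatch(q):
        return reduced_variance_at_fixed_point(p, x_scaled, q) * p.N**2 - var_full

    q_hi = 4.0 * (1.0 + 2.0 * p.b) + 10.0
    lo, hi = 1e-9, q_hi
    if mismatch(lo) * mismatch(hi) > 0:
        raise RuntimeError(
            f"no effective stoichiometry in ({lo:.1e}, {hi:.3g}) matches the "
            f"full-model variance {var_full:.6g}"
        )
    return float(brentq(mismatch, lo, hi, rtol=1e-12))
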