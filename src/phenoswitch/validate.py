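"""One-command validation suite tying the modules together.

Runs the package's built-in consistency checks — the analytic identities of
the drift/boundary machinery, the variance-matching route to the effective
stoichiometry, reduction fidelity in the dimer-to-cooperative limit, and
(optionally) stochastic checks against the exact simulator — and collects
the outcomes in a machine-readable report.  Failures are collected, never
short-circuited.
"""

from __future__ import annotations

import json
import time
import traceback

import numpy as np

from .params import MotifParams, full_from_motif, COOPERATIVE, DIMER
from .model import find_fixed_points, bistability_boundary
from .reduction import reduced_variance_at_fixed_point, effective_stoichiometry
from .fdt import match_q
from .escape import pseudo_potential, escape_time_quadrature, escape_time_parabolic
from .gillespie import simulate, state_at_total
from .presets import load_preset

__all__ = ["run_validation_suite"]


def _check_asymptote():
    """Boundary product S0*Sa extrapolates to 1/4 as rho* -> 0."""
    p = MotifParams(motif=COOPERATIVE, S0=0.1, Sa=1.0, N=100.0)
    rho = np.array([0.04, 0.02, 0.01, 0.005])
    bc = bistability_boundary(p, rho)
    prod = bc.S0 * bc.Sa
    # product is 1/4 + O(rho^2): extrapolate linearly in rho^2
    coef = np.polyfit(rho**2, prod, 1)
    value = float(coef[1])
    return abs(value - 0.25) < 1e-3, {"extrapolated_product": value}


def _check_hill_minimality():
    """Hill exponent 1 never yields three positive roots; exponent 2 does."""
    def roots_hill(n, S0, Sa):
        rho = np.geomspace(1e-6, 2 * (S0 + Sa), 4000)
        phi = S0 + Sa * rho**n / (1 + rho**n) - rho
        return int(np.sum(np.sign(phi[:-1]) * np.sign(phi[1:]) < 0))

    grid = [(S0, Sa) for S0 in np.geomspace(1e-3, 1.0, 12) for Sa in np.geomspace(0.1, 30.0, 12)]
    max_n1 = max(roots_hill(1, S0, Sa) for S0, Sa in grid)
    any_n2 = any(roots_hill(2, S0, Sa) == 3 for S0, Sa in grid)
    return (max_n1 <= 1) and any_n2, {"max_roots_n1": max_n1, "bistable_found_n2": any_n2}


def _check_q_slope():
    """Matched effective stoichiometry grows with slope ~2 in the burst size."""
    bs = np.arange(1.0, 11.0)
    qs = []
    for b in bs:
        p = MotifParams(motif=COOPERATIVE, S0=0.5, Sa=1e-12, b=b, N=200.0)
        full = full_from_motif(p, gamma_m_ratio=100.0)
        qs.append(match_q(full))
    slope = float(np.polyfit(bs, qs, 1)[0])
    return abs(slope - 2.0) / 2.0 < 0.01, {"slope": slope, "q_values": [round(q, 4) for q in qs]}


def _check_reduction_fidelity():
    """Dimer motif with c -> 0 reproduces the cooperative fixed points."""
    coop = MotifParams(motif=COOPERATIVE, S0=0.05, Sa=4.0, N=100.0)
    dim = MotifParams(motif=DIMER, S0=0.05, Sa=4.0, N=100.0, c=1e-9, d=0.1)
    fc, fd = find_fixed_points(coop), find_fixed_points(dim)
    err = max(abs(a - b) / a for a, b in zip(fc.roots, fd.roots))
    return fc.bistable and fd.bistable and err < 1e-6, {"max_rel_err": err}


def _check_parabolic_vs_quadrature():
    """Saddle-point escape times within 20% of exact quadrature at deep barriers."""
    p = load_preset("fig3-low80").motif_params
    fp = find_fixed_points(p)
    prof = pseudo_potential(p, fp=fp)
    quad = escape_time_quadrature(prof, fp)
    par = escape_time_parabolic(prof, fp)
    rel = max(abs(par.gamma_LH / quad.gamma_LH - 1), abs(par.gamma_HL / quad.gamma_HL - 1))
    return rel < 0.2, {"max_rel_diff": rel, "dpsi_LH": quad.dpsi_LH, "dpsi_HL": quad.dpsi_HL}


def _check_ssa_variance(seed):
    """SSA stationary variance matches the reduced C = -D/2A on a monostable preset."""
    p = MotifParams(motif=COOPERATIVE, S0=0.5, Sa=1e-12, b=2.0, N=200.0)
    full = full_from_motif(p, gamma_m_ratio=100.0)
    x_s = find_fixed_points(p).roots[0]
    var_th = reduced_variance_at_fixed_point(p, x_s) * p.N**2
    tr = simulate(full, state_at_total(full, x_s), 8000.0, seed=seed, n_samples=16000)
    pt = tr.total_protein[1000:]
    var_ssa = float(pt.var())
    # stderr of the sample variance with autocorrelation time ~1 lifetime
    n_eff = len(pt) / (2 / 0.5)
    se = var_th * np.sqrt(2.0 / n_eff)
    return abs(var_ssa - var_th) < 3 * se, {"var_ssa": var_ssa, "var_theory": var_th, "se": se}


def run_validation_suite(quick: bool = True, seed: int = 0) -> dict:
    """Execute the validation checks; returns a machine-readable report.

    ``quick=True`` runs the analytic checks only; ``quick=False`` adds the
    stochastic-simulation checks.  The report maps check names to
    ``{"passed": bool, "seconds": float, ...detail}``; the overall verdict
    is under ``"all_passed"``.
    """
    checks = {
        "bistability_asymptote": _check_asymptote,
        "hill_minimality": _check_hill_minimality,
        "effective_stoichiometry_slope": _check_q_slope,
        "reduction_fidelity": _check_reduction_fidelity,
        "parabolic_vs_quadrature": _check_parabolic_vs_quadrature,
    }
    if not quick:
        checks["ssa_stationary_variance"] = lambda: _check_ssa_variance(seed)

    report = {}
    for name, fn in checks.items():
        t0 = time.time()
        try:
            passed, detail = fn()
        except Exception:
            passed, detail = False, {"error": traceback.format_exc(limit=3)}
        detail["passed"] = bool(passed)
        detail["seconds"] = round(time.time() - t0, 2)
        report[name] = detail
    report["all_passed"] = all(v["passed"] for k, v in report.items() if isinstance(v, dict))
    report["seed"] = seed
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, default=float)
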