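"""Exact stochastic simulation (Gillespie SSA) of the full feedback network.

This module is the stochastic ground truth the reduced one-variable theory
is benchmarked against: long trajectories for stationary statistics,
first-passage sampling between the two phenotypic states, and switching-
statistics analysis (exponentiality of waiting times, cumulative switching
probability).

Times reported by this module are in protein-lifetime units
(``tau = gamma_p * t``), matching the escape-time estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .params import FullNetworkParams, MotifParams, DIMER, scale_full_to_motif
from .network import derived_rates
from .model import find_fixed_points, monomer_from_total
from . import _kernels
from ._kernels import MOTIF_COOP, MOTIF_DIMER

__all__ = [
    "NetworkState",
    "Reaction",
    "build_reactions",
    "Trajectory",
    "simulate",
    "FirstPassageSample",
    "sample_first_passage",
    "ExponentialityResult",
    "exponentiality_test",
    "switching_cdf",
]


@dataclass(frozen=True)
class NetworkState:
    """Integer copy-number state: promoter (0 basal, 1 active), M, P, P2."""

    G: int = 0
    M: int = 0
    P: int = 0
    P2: int = 0

    def __post_init__(self):
        if min(self.G, self.M, self.P, self.P2) < 0:
            raise ValueError("copy numbers must be non-negative")

    @property
    def total_protein(self) -> int:
        return self.P + 2 * self.P2


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: name, propensity(state) and state change."""

    name: str
    propensity: Callable[[NetworkState], float]
    stoich: dict


def _param_vector(full: FullNetworkParams) -> tuple[int, np.ndarray]:
    r = derived_rates(full)
    c = np.zeros(len(_kernels.PARAM_NAMES))
    # transcription rates are concentration rates: number flux carries Omega
    c[0:6] = (full.Omega * full.k_m0, full.Omega * full.k_ma,
              full.gamma_m, full.k_p, full.gamma_p, full.gamma_p2)
    c[9] = r.koff
    if full.motif == DIMER:
        c[6] = r.k1 / full.Omega        # propensity k1n * P * (P-1)
        c[7] = r.km1
        c[8] = r.kon / full.Omega       # propensity konn * P2
        return MOTIF_DIMER, c
    c[10] = r.kon_pair / full.Omega**2  # propensity konpn * P * (P-1)
    return MOTIF_COOP, c


def build_reactions(full: FullNetworkParams) -> list[Reaction]:
    """The elementary reaction list realized by the SSA kernels.

    Averaging ``propensity * stoich`` over an ensemble recovers the
    deterministic rate equations in the large-molecule limit; tests use this
    list for mean-field consistency checks and it documents exactly which
    reactions the kernels fire.
    """
    motif, c = _param_vector(full)
    rxns = [
        Reaction("transcription",
                 lambda s, c=c: c[0] + (c[1] if s.G == 1 else 0.0),
                 {"M": +1}),
        Reaction("mRNA decay", lambda s, c=c: c[2] * s.M, {"M": -1}),
        Reaction("translation", lambda s, c=c: c[3] * s.M, {"P": +1}),
        Reaction("monomer decay", lambda s, c=c: c[4] * s.P, {"P": -1}),
    ]
    if motif == MOTIF_DIMER:
        rxns += [
            Reaction("dimerization", lambda s, c=c: c[6] * s.P * (s.P - 1), {"P": -2, "P2": +1}),
            Reaction("dimer dissociation", lambda s, c=c: c[7] * s.P2, {"P": +2, "P2": -1}),
            Reaction("dimer decay", lambda s, c=c: c[5] * s.P2, {"P2": -1}),
            Reaction("promoter binding", lambda s, c=c: c[8] * s.P2 if s.G == 0 else 0.0, {"G": +1}),
        ]
    else:
        rxns += [
            Reaction("pair binding", lambda s, c=c: c[10] * s.P * (s.P - 1) if s.G == 0 else 0.0, {"G": +1}),
        ]
    rxns.append(Reaction("promoter unbinding", lambda s, c=c: c[9] if s.G == 1 else 0.0, {"G": -1}))
    return rxns


@dataclass(frozen=True)
class Trajectory:
    """SSA trajectory sampled on a uniform time grid (times in 1/gamma_p units)."""

    t: np.ndarray
    G: np.ndarray
    M: np.ndarray
    P: np.ndarray
    P2: np.ndarray
    seed: int

    @property
    def total_protein(self) -> np.ndarray:
        return self.P + 2 * self.P2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "promoter": self.G, "M": self.M, "P": self.P,
             "P2": self.P2, "P_T": self.total_protein}
        )


def _seed_stream(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32).astype(np.int64)


def simulate(
    full: FullNetworkParams,
    init: NetworkState,
    t_max: float,
    seed: int,
    n_samples: int = 1000,
) -> Trajectory:
    """Statistically exact SSA trajectory, recorded at n_samples uniform times.

    ``t_max`` is in protein-lifetime units.  Identical (seed, parameters,
    init) give bit-identical trajectories.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    motif, c = _param_vector(full)
    if not np.all(np.isfinite(c)):
        bad = [n for n, v in zip(_kernels.PARAM_NAMES, c) if not math.isfinite(v)]
        raise FloatingPointError(f"non-finite propensity constants for {bad}")
    t_abs = t_max / full.gamma_p
    sample_times = np.linspace(0.0, t_abs, n_samples)
    kseed = int(_seed_stream(seed, 1)[0])
    G, M, P, P2 = _kernels.simulate_kernel(
        motif, c, init.G, init.M, init.P, init.P2, t_abs, sample_times, kseed
    )
    return Trajectory(t=sample_times * full.gamma_p, G=G, M=M, P=P, P2=P2, seed=seed)


def state_at_total(full: FullNetworkParams, xT: float) -> NetworkState:
    """Integer state realizing scaled total concentration xT, pools at equilibrium."""
    p = scale_full_to_motif(full)
    rho = monomer_from_total(xT, p)
    PT = int(round(p.N * xT))
    P = int(round(p.N * rho))
    if (PT - P) % 2:
        P += 1
    P = min(P, PT)
    P2 = (PT - P) // 2
    phi = 0.0  # promoter equilibrates during burn-in
    M = int(round(full.Omega * (full.k_m0 + full.k_ma * phi) / full.gamma_m))
    return NetworkState(G=0, M=M, P=P, P2=P2)


@dataclass(frozen=True)
class FirstPassageSample:
    """First-passage durations between the phenotypic states (scaled time).

    ``times[i]`` is the duration of replicate ``i`` — a completed passage if
    ``completed[i]``, otherwise the censoring cap.  Censored replicates are
    recorded, never silently dropped.
    """

    times: np.ndarray
    completed: np.ndarray
    origin: str
    target_threshold: int
    saddle_threshold: int
    seed: int
    n_requested: int

    @property
    def n_completed(self) -> int:
        return int(self.completed.sum())

    @property
    def passage_times(self) -> np.ndarray:
        return self.times[self.completed]

    @property
    def mean(self) -> float:
        if self.n_completed == 0:
            raise ValueError("no completed passages")
        return float(self.passage_times.mean())

    @property
    def sem(self) -> float:
        t = self.passage_times
        return float(t.std(ddof=1) / math.sqrt(len(t))) if len(t) > 1 else math.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "completed": self.completed})


def sample_first_passage(
    full: FullNetworkParams,
    origin: str,
    n: int,
    seed: int,
    t_cap: float = 1e6,
    burnin: float = 5.0,
    max_restarts: int = 10000,
) -> FirstPassageSample:
    """Sample first-passage times from one stable state to the other.

    Each replicate starts at the integer-rounded origin fixed point of the
    reduced model, relaxes for ``burnin`` protein lifetimes confined to the
    origin basin (restarting if the deterministic saddle is crossed), then
    runs until the total protein count first reaches the opposite stable
    fixed point (the absorbing target of the mean-first-passage theory).
    All times are in protein-lifetime units.
    """
    if origin not in ("low", "high"):
        raise ValueError("origin must be 'low' or 'high'")
    if n < 1:
        raise ValueError("n must be >= 1")
    p = scale_full_to_motif(full)
    fp = find_fixed_points(p)
    if not fp.bistable:
        raise ValueError("the reduced deterministic model is not bistable for these parameters")
    to_high = origin == "low"
    x0 = fp.xL if to_high else fp.xH
    x_target = fp.xH if to_high else fp.xL
    init = state_at_total(full, x0)
    saddle = int(round(p.N * fp.xM))
    target = int(round(p.N * x_target))

    motif, c = _param_vector(full)
    gp = full.gamma_p
    seeds = _seed_stream(seed, n)
    times = np.empty(n)
    completed = np.empty(n, dtype=bool)
    for i in range(n):
        t, ok, _ = _kernels.first_passage_kernel(
            motif, c, init.G, init.M, init.P, init.P2,
            saddle, target, to_high,
            burnin / gp, t_cap / gp, int(seeds[i]), max_restarts,
        )
        if t < 0:
            raise RuntimeError(
                f"burn-in rejection exceeded {max_restarts} restarts for replicate {i}; "
                "the origin basin is too shallow for basin-confined initialization"
            )
        times[i] = t * gp
        completed[i] = ok
    return FirstPassageSample(
        times=times, completed=completed, origin=origin,
        target_threshold=target, saddle_threshold=saddle,
        seed=seed, n_requested=n,
    )


@dataclass(frozen=True)
class ExponentialityResult:
    """KS comparison of passage times against the exponential law."""

    statistic: float
    pvalue: float
    m_t: float                  # theory mean used for the primary test
    statistic_empirical: float  # secondary: exponential with the sample mean
    pvalue_empirical: float


def exponentiality_test(sample: FirstPassageSample, gamma_theory: float | None = None) -> ExponentialityResult:
    """One-sample KS test of the passage times against an exponential law.

    The primary test is parameterized by the analytic mean switching time
    ``m_t = gamma_theory`` (defaulting to the sample mean if not given —
    then primary and secondary coincide).  Memoryless one-step switching
    predicts non-rejection.
    """
    if sample.n_completed < 50:
        raise ValueError(f"need >= 50 completed passages, have {sample.n_completed}")
    censor_frac = 1.0 - sample.n_completed / len(sample.times)
    if censor_frac >= 0.05:
        raise ValueError(f"censoring fraction {censor_frac:.1%} >= 5%; raise t_cap")
    t = sample.passage_times
    m_t = float(gamma_theory) if gamma_theory is not None else float(t.mean())
    stat, p = stats.kstest(t, "expon", args=(0.0, m_t))
    stat_e, p_e = stats.kstest(t, "expon", args=(0.0, float(t.mean())))
    return ExponentialityResult(
        statistic=float(stat), pvalue=float(p), m_t=m_t,
        statistic_empirical=float(stat_e), pvalue_empirical=float(p_e),
    )


def switching_cdf(sample: FirstPassageSample, gamma_theory: float) -> pd.DataFrame:
    """Empirical switching probability P(<= t) with the exponential prediction.

    Returns a table of the sorted passage times, the empirical cumulative
    switching probability and the memoryless prediction
    ``1 - exp(-t/gamma_theory)``.
    """
    if sample.n_completed < 20:
        raise ValueError(f"need >= 20 completed passages, have {sample.n_completed}")
    t = np.sort(sample.passage_times)
    ecdf = np.arange(1, len(t) + 1) / len(t)
    theory = 1.0 - np.exp(-t / gamma_theory)
    return pd.DataFrame({"t": t, "empirical": ecdf, "theory": theory})
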