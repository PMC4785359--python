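"""Exact stochastic simulation: correctness, reproducibility, statistics."""

import numpy as np
import pytest
from scipy import stats

from phenoswitch import (
    COOPERATIVE, MotifParams, full_from_motif, find_fixed_points,
    NetworkState, build_reactions, simulate, state_at_total,
    sample_first_passage, FirstPassageSample, exponentiality_test, switching_cdf,
)
from phenoswitch.network import ode_rhs
from phenoswitch import _kernels


@pytest.fixture(scope="module")
def mono_full():
    p = MotifParams(motif=COOPERATIVE, S0=0.5, Sa=0.0, b=2.0, N=100.0)
    return p, full_from_motif(p, gamma_m_ratio=50.0)


class TestReactions:
    @pytest.mark.parametrize("motif_kw", [
        dict(motif="cooperative", S0=0.1, Sa=2.0, N=50.0),
        dict(motif="dimer", S0=0.1, Sa=2.0, N=50.0, c=1.5, d=0.3),
    ])
    def test_mean_field_recovers_rate_equations(self, motif_kw):
        """Summing propensity*stoichiometry over the reaction list reproduces
        the deterministic rates of change at promoter equilibrium."""
        p = MotifParams(**motif_kw)
        full = full_from_motif(p)
        rxns = build_reactions(full)
        for P, P2 in ((10, 3), (40, 11), (80, 0)):
            M = 5
            drift = {"M": 0.0, "P": 0.0, "P2": 0.0, "G": 0.0}
            # average over the promoter's equilibrium occupancy
            from phenoswitch.network import occupancy
            phi = occupancy(full, P, P2)
            for G, w in ((0, 1 - phi), (1, phi)):
                s = NetworkState(G=G, M=M, P=P, P2=P2)
                for r in rxns:
                    a = r.propensity(s)
                    for sp, v in r.stoich.items():
                        drift[sp] += w * a * v
            expected = ode_rhs(full, M, P, P2)
            # dimerization propensity is k1*P*(P-1)/Omega while the ODE uses
            # k1*P^2/Omega; correct for that exact finite-size difference
            from phenoswitch.network import derived_rates
            k1n = derived_rates(full).k1 / full.Omega if full.motif == "dimer" else 0.0
            assert drift["M"] == pytest.approx(expected[0], rel=1e-9)
            assert drift["P"] == pytest.approx(expected[1] + 2 * k1n * P, rel=1e-9, abs=1e-9)
            assert drift["P2"] == pytest.approx(expected[2] - k1n * P, rel=1e-9, abs=1e-9)

    def test_all_zero_rates_freeze_the_state(self):
        """Kernel-level: with every propensity zero the state never changes."""
        c = np.zeros(len(_kernels.PARAM_NAMES))
        times = np.linspace(0.0, 10.0, 20)
        G, M, P, P2 = _kernels.simulate_kernel(0, c, 1, 3, 7, 2, 10.0, times, 42)
        assert np.all(M == 3) and np.all(P == 7) and np.all(P2 == 2) and np.all(G == 1)

    def test_constitutive_stationary_mean(self, mono_full):
        """Sa = 0, no dimer: the stationary total protein mean is S0*N."""
        p, full = mono_full
        tr = simulate(full, state_at_total(full, p.S0), 3000.0, seed=3, n_samples=6000)
        pt = tr.total_protein[500:]
        mean, expected = pt.mean(), p.S0 * p.N
        se = pt.std() / np.sqrt(len(pt) / 4.0)  # ~1-lifetime autocorrelation
        assert abs(mean - expected) < 3 * se + 0.5

    def test_mrna_marginal_is_poisson(self, mono_full):
        """Constitutive transcription: the mRNA copy number is exactly Poisson."""
        p, full = mono_full
        tr = simulate(full, state_at_total(full, p.S0), 2000.0, seed=11, n_samples=4000)
        m = tr.M[400:]
        lam = full.Omega * full.k_m0 / full.gamma_m
        kmax = int(stats.poisson.ppf(0.999, lam)) + 1
        obs = np.bincount(m, minlength=kmax + 1).astype(float)
        exp_p = stats.poisson.pmf(np.arange(kmax + 1), lam)
        # pool the tail, thin to ~independent samples
        obs_pooled = np.append(obs[:kmax], obs[kmax:].sum())
        exp_pooled = np.append(exp_p[:kmax], 1 - exp_p[:kmax].sum()) * len(m)
        keep = exp_pooled > 5
        chi2 = np.sum((obs_pooled[keep] - exp_pooled[keep]) ** 2 / exp_pooled[keep])
        # autocorrelation inflates chi2; allow a generous factor
        assert chi2 < 5 * keep.sum()

    def test_reproducible_and_seed_sensitive(self, mono_full):
        p, full = mono_full
        init = state_at_total(full, p.S0)
        a = simulate(full, init, 50.0, seed=5, n_samples=100)
        b = simulate(full, init, 50.0, seed=5, n_samples=100)
        c = simulate(full, init, 50.0, seed=6, n_samples=100)
        np.testing.assert_array_equal(a.P, b.P)
        np.testing.assert_array_equal(a.M, b.M)
        assert not np.array_equal(a.P, c.P)

    def test_bimodal_occupancy_at_small_system_size(self):
        """At a shallow barrier the total protein distribution is bimodal,
        with a dip near the deterministic saddle."""
        p = MotifParams(motif=COOPERATIVE, S0=0.13, Sa=1.8, b=2.0, N=300.0)
        full = full_from_motif(p, gamma_m_ratio=50.0, promoter_timescale=2000.0)
        fp = find_fixed_points(p)
        tr = simulate(full, state_at_total(full, fp.xL), 4000.0, seed=9, n_samples=8000)
        pt = tr.total_protein[500:]
        edges = [0, int(p.N * fp.xL * 1.4), int(p.N * fp.xM * 1.3), int(pt.max()) + 1]
        low = np.mean(pt < edges[1])
        mid = np.mean((pt >= edges[1]) & (pt < edges[2]))
        high = np.mean(pt >= edges[2])
        assert low > 0.1 and high > 0.1     # both basins visited
        assert mid < min(low, high)          # saddle region depleted


class TestFirstPassage:
    def test_censoring_is_recorded_not_dropped(self):
        p = MotifParams(motif=COOPERATIVE, S0=0.13, Sa=1.8, b=2.0, N=600.0)
        full = full_from_motif(p, gamma_m_ratio=50.0, promoter_timescale=2000.0)
        s = sample_first_passage(full, "low", 4, seed=1, t_cap=0.5)
        assert s.n_completed == 0
        assert np.all(~s.completed) and np.all(s.times == pytest.approx(0.5))

    def test_passage_reaches_the_opposite_state(self):
        p = MotifParams(motif=COOPERATIVE, S0=0.13, Sa=1.8, b=2.0, N=300.0)
        full = full_from_motif(p, gamma_m_ratio=50.0, promoter_timescale=2000.0)
        fp = find_fixed_points(p)
        s = sample_first_passage(full, "low", 8, seed=4, t_cap=1e5)
        assert s.n_completed == 8
        assert s.target_threshold == int(round(p.N * fp.xH))
        assert np.all(s.passage_times > 0)

    def test_origin_must_be_bistable(self, mono_full):
        _, full = mono_full
        with pytest.raises(ValueError, match="not bistable"):
            sample_first_passage(full, "low", 2, seed=0)


def _fake_sample(times, origin="low"):
    t = np.asarray(times, dtype=float)
    return FirstPassageSample(times=t, completed=np.ones(len(t), dtype=bool),
                              origin=origin, target_threshold=100,
                              saddle_threshold=50, seed=0, n_requested=len(t))


class TestSwitchingStatistics:
    def test_ks_null_calibration(self):
        """Exponential samples are rejected at alpha=0.01 about 1% of the time."""
        rng = np.random.default_rng(12345)
        rejections = sum(
            exponentiality_test(_fake_sample(rng.exponential(7.0, size=100))).pvalue < 0.01
            for _ in range(200)
        )
        assert rejections <= 7  # Poisson(2) upper tail

    def test_degenerate_times_strongly_rejected(self):
        et = exponentiality_test(_fake_sample(np.full(100, 3.0)), gamma_theory=3.0)
        assert et.pvalue < 1e-10

    def test_preconditions(self):
        with pytest.raises(ValueError, match=">= 50"):
            exponentiality_test(_fake_sample(np.ones(10)))
        s = FirstPassageSample(times=np.ones(100), completed=np.arange(100) < 60,
                               origin="low", target_threshold=1, saddle_threshold=1,
                               seed=0, n_requested=100)
        with pytest.raises(ValueError, match="censoring"):
            exponentiality_test(s)

    def test_switching_cdf_properties(self):
        rng = np.random.default_rng(7)
        sample = _fake_sample(rng.exponential(5.0, size=200))
        gamma = 5.0
        cdf = switching_cdf(sample, gamma)
        # empirical CDF at the median is 1/2 by construction
        med = np.median(sample.passage_times)
        assert np.interp(med, cdf.t, cdf.empirical) == pytest.approx(0.5, abs=0.01)
        assert (cdf.empirical.diff().dropna() >= 0).all()
        assert cdf.empirical.iloc[-1] == pytest.approx(1.0)
        # sup distance equals the KS statistic of the same comparison
        et = exponentiality_test(sample, gamma_theory=gamma)
        ecdf_lo = cdf.empirical - 1 / len(cdf)
        sup = np.maximum(np.abs(cdf.empirical - cdf.theory),
                         np.abs(ecdf_lo - cdf.theory)).max()
        assert sup == pytest.approx(et.statistic, abs=1e-12)
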