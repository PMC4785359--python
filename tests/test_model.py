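"""Drift, fixed points and the bistability region."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenoswitch import (
    COOPERATIVE, DIMER, FullNetworkParams, MotifParams, ParameterError,
    scale_full_to_motif, full_from_motif, monomer_from_total, drift, drift_dx,
    find_fixed_points, is_bistable, bistability_boundary,
)

from conftest import cooperative_cubic_roots


class TestScaling:
    def test_symmetric_cooperative_mapping(self):
        full = FullNetworkParams(
            k_m0=0.2, k_ma=0.2, gamma_m=1.0, k_p=3.0, gamma_p=1.0,
            Omega=50.0, Kprom=2.0, motif=COOPERATIVE,
        )
        p = scale_full_to_motif(full)
        assert p.c == 0.0
        assert p.S0 == pytest.approx(p.Sa)
        assert p.b == pytest.approx(3.0)
        assert p.N == pytest.approx(100.0)

    def test_dimer_concentration_scale_is_geometric_mean(self):
        full = FullNetworkParams(
            k_m0=0.1, k_ma=1.0, gamma_m=10.0, k_p=20.0, gamma_p=1.0,
            gamma_p2=0.1, K1=4.0, Kprom=9.0, Omega=10.0, motif=DIMER,
        )
        p = scale_full_to_motif(full)
        assert full.K == pytest.approx(6.0)  # sqrt(K1*K2)
        assert p.c == pytest.approx(1.5)     # K/K1
        assert p.d == pytest.approx(0.1)     # monomer:dimer decay ratio 10

    def test_validation_names_offending_field(self):
        with pytest.raises(ParameterError, match="gamma_m"):
            FullNetworkParams(k_m0=0.1, k_ma=0.0, gamma_m=-1.0, k_p=1.0,
                              gamma_p=1.0, Omega=10.0, Kprom=1.0)

    def test_roundtrip_through_full_network(self, dimer_point):
        back = scale_full_to_motif(full_from_motif(dimer_point))
        for name in ("S0", "Sa", "b", "N", "c", "d"):
            assert getattr(back, name) == pytest.approx(getattr(dimer_point, name))


class TestMonomerFromTotal:
    @pytest.mark.parametrize("c, xT, expected", [
        (0.0, 0.37, 0.37),   # cooperative identity
        (0.5, 2.0, 1.0),     # 1 + 2*0.5*1 = 2
        (10.0, 0.0, 0.0),
    ])
    def test_known_values(self, c, xT, expected):
        motif = COOPERATIVE if c == 0 else DIMER
        p = MotifParams(motif=motif, S0=0.1, Sa=1.0, N=10.0, c=c, d=0.1 if c else 0.0)
        assert monomer_from_total(xT, p) == pytest.approx(expected)

    def test_negative_total_rejected(self, dimer_point):
        with pytest.raises(ValueError):
            monomer_from_total(-0.1, dimer_point)

    @given(c=st.floats(0.0, 50.0), xT=st.floats(0.0, 100.0))
    @settings(max_examples=200, deadline=None)
    def test_inverts_dimer_equilibrium(self, c, xT):
        motif = COOPERATIVE if c == 0 else DIMER
        p = MotifParams(motif=motif, S0=0.1, Sa=1.0, N=10.0, c=c, d=0.0)
        rho = monomer_from_total(xT, p)
        assert rho >= 0
        assert rho + 2 * c * rho**2 == pytest.approx(xT, abs=1e-9 * (1 + xT))


class TestDrift:
    def test_zero_concentration_gives_basal_rate(self, coop_point, dimer_point):
        assert drift(0.0, coop_point) == pytest.approx(coop_point.S0)
        assert drift(0.0, dimer_point) == pytest.approx(dimer_point.S0)

    def test_sign_changes_match_cubic_oracle(self, coop_point):
        roots = cooperative_cubic_roots(coop_point.S0, coop_point.Sa)
        assert len(roots) == 3
        # oracle roots are ~0.070, 0.19, 3.79; drift changes sign at each
        eps = 1e-4
        for r in roots:
            assert drift(r * (1 - eps), coop_point) * drift(r * (1 + eps), coop_point) < 0

    def test_dimer_decay_lowers_drift_at_fixed_monomer(self):
        coop = MotifParams(motif=COOPERATIVE, S0=0.1, Sa=2.0, N=10.0)
        dim = MotifParams(motif=DIMER, S0=0.1, Sa=2.0, N=10.0, c=2.0, d=0.5)
        for rho in (0.1, 0.5, 1.5):
            xT = rho + 2 * dim.c * rho**2
            assert drift(xT, dim) < drift(rho, coop)

    @given(xT=st.floats(1e-6, 50.0))
    @settings(max_examples=200, deadline=None)
    def test_reduction_identity(self, xT):
        """Drift through the equilibrium map equals the direct formula in rho."""
        p = MotifParams(motif=DIMER, S0=0.07, Sa=3.0, N=10.0, c=1.5, d=0.4)
        rho = monomer_from_total(xT, p)
        direct = p.S0 + p.Sa * rho**2 / (1 + rho**2) - rho - 2 * p.alpha * rho**2
        assert drift(xT, p) == pytest.approx(direct, rel=1e-12)


class TestFixedPoints:
    def test_cooperative_roots_match_cubic_oracle(self, coop_point):
        fp = find_fixed_points(coop_point)
        oracle = cooperative_cubic_roots(coop_point.S0, coop_point.Sa)
        assert fp.bistable
        np.testing.assert_allclose(fp.roots, oracle, rtol=1e-9)
        assert fp.stable == (True, False, True)
        assert drift_dx(fp.xM, coop_point) > 0

    def test_no_activation_gives_single_stable_root(self):
        p = MotifParams(motif=COOPERATIVE, S0=0.37, Sa=0.0, N=10.0)
        fp = find_fixed_points(p)
        assert len(fp.roots) == 1 and fp.stable == (True,)
        assert fp.roots[0] == pytest.approx(0.37)

    def test_boundary_point_is_degenerate(self):
        template = MotifParams(motif=COOPERATIVE, S0=0.1, Sa=1.0, N=10.0)
        bc = bistability_boundary(template, [0.4])
        p = MotifParams(motif=COOPERATIVE, S0=float(bc.S0[0]), Sa=float(bc.Sa[0]), N=10.0)
        assert abs(drift(0.4, p)) < 1e-10
        assert abs(drift_dx(0.4, p)) < 1e-8
        fp = find_fixed_points(p)
        assert not fp.bistable  # double root merged or tangent: no proper bistability

    @pytest.mark.parametrize("S0, Sa, expect", [
        (0.05, 4.0, True),
        (1.0, 4.0, False),   # basal synthesis far above the boundary
        (0.05, 0.0, False),  # no feedback at all
    ])
    def test_is_bistable(self, S0, Sa, expect):
        flag, _ = is_bistable(MotifParams(motif=COOPERATIVE, S0=S0, Sa=Sa, N=10.0))
        assert flag is expect


class TestBistabilityBoundary:
    def test_cooperative_closed_form(self):
        template = MotifParams(motif=COOPERATIVE, S0=0.1, Sa=1.0, N=10.0)
        bc = bistability_boundary(template, [0.5])
        assert bc.Sa[0] == pytest.approx(1.5625)   # (1+rho^2)^2/(2 rho)
        assert bc.S0[0] == pytest.approx(0.1875)   # rho (1-rho^2)/2

    def test_rows_satisfy_double_root_conditions(self, dimer_point):
        bc = bistability_boundary(dimer_point, np.geomspace(0.05, 1.5, 40))
        for rho, S0, Sa in zip(bc.rho_star, bc.S0, bc.Sa):
            p = MotifParams(motif=DIMER, S0=S0, Sa=Sa, N=10.0,
                            c=dimer_point.c, d=dimer_point.d)
            xT = rho + 2 * p.c * rho**2
            assert abs(drift(xT, p)) < 1e-10
            assert abs(drift_dx(xT, p)) < 1e-8

    def test_unphysical_rows_dropped(self):
        template = MotifParams(motif=COOPERATIVE, S0=0.1, Sa=1.0, N=10.0)
        bc = bistability_boundary(template, [0.5, 2.0])  # rho*=2 gives S0<0
        assert bc.n_dropped == 1 and len(bc.rho_star) == 1

    def test_product_monotone_to_quarter_asymptote(self):
        template = MotifParams(motif=COOPERATIVE, S0=0.1, Sa=1.0, N=10.0)
        rho = np.geomspace(3e-3, 0.3, 25)
        bc = bistability_boundary(template, rho)
        prod = bc.S0 * bc.Sa
        # product (1+rho^2-rho^4-rho^6)/4 decreases monotonically to 1/4 as rho* -> 0
        assert np.all(np.diff(prod) > 0)
        assert prod[0] == pytest.approx(0.25, abs=1e-4)
        assert np.all(prod > 0.25)

    def test_dimer_boundary_reduces_to_cooperative(self):
        rho = np.geomspace(0.05, 0.9, 15)
        coop = bistability_boundary(MotifParams(motif=COOPERATIVE, S0=0.1, Sa=1.0, N=10.0), rho)
        dim = bistability_boundary(
            MotifParams(motif=DIMER, S0=0.1, Sa=1.0, N=10.0, c=1e-10, d=0.1), rho)
        np.testing.assert_allclose(dim.S0, coop.S0, rtol=1e-8)
        np.testing.assert_allclose(dim.Sa, coop.Sa, rtol=1e-8)


def test_dimer_fixed_points_reach_cooperative_limit(coop_point):
    dim = MotifParams(motif=DIMER, S0=coop_point.S0, Sa=coop_point.Sa,
                      N=coop_point.N, c=1e-9, d=0.1)
    fc, fd = find_fixed_points(coop_point), find_fixed_points(dim)
    assert fd.bistable
    np.testing.assert_allclose(fd.roots, fc.roots, rtol=1e-6)
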