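"""Tests for fixed-point computation, stability and regime conditions.

Numeric oracles: nullcline composition + bracketing for root sets, grid
bisection for threshold locations, long stiff ODE integration for
attractors, and closed-form Jacobians for the linearization.
"""

import dataclasses
import math

import numpy as np
import pytest

from cisi.equilibria import (
    CubicCoefficients,
    NotAnEquilibriumError,
    RegimeError,
    _cubic_positive_roots,
    _trig_roots,
    base_equilibria,
    base_k_thresholds,
    base_positive_roots,
    classify_base_regime,
    cubic_discriminant,
    nkctl_equilibria,
    nkctl_plausibility,
    saturation_bistability,
    saturation_cubic_coeffs,
    saturation_equilibria,
    saturation_multistability,
    stability_of,
)
from cisi.models import BaseParams, NkCtlParams, SaturationParams, base_rhs

from conftest import (
    base_tumor_nullcline,
    integrate_to_attractor,
    nullcline_positive_roots,
)

# frozen multistable saturation example (verified by both routes below)
MULTISTABLE_SAT = SaturationParams(
    a=0.314, b=1.31e-8, k=1.675e-5, sigma=37.3, d=6.75e-3,
    b_e=0.699, kappa_e=375.5, d_e=5.35, kappa_d=4.42e5,
)


class TestBaseEquilibria:
    def test_always_contains_cancer_free(self, table1, fig2):
        for p in (table1, fig2, table1.with_k(5.0)):
            eqs = base_equilibria(p)
            assert eqs[0].state == (0.0, p.sigma / p.d)

    def test_fig2_bistable_window_structure(self, fig2):
        k_l, k_u = base_k_thresholds(fig2)
        p = fig2.with_k(math.sqrt(k_l * k_u))
        eqs = base_equilibria(p)
        assert len(eqs) == 3
        assert [e.stability for e in eqs] == ["stable", "unstable", "stable"]
        assert eqs[0].T == 0.0
        # oracle 1: root count by nullcline composition
        oracle = nullcline_positive_roots(base_tumor_nullcline(p), 1.0, 2.0 / p.b)
        np.testing.assert_allclose(oracle, [e.T for e in eqs[1:]], rtol=1e-6)
        # oracle 2: long integration from bracketing initial conditions
        lo = integrate_to_attractor(p, (eqs[1].T / 10.0, p.sigma / p.d))
        hi = integrate_to_attractor(p, (eqs[1].T * 10.0, eqs[2].E))
        assert lo[0] == pytest.approx(0.0, abs=1e-3)
        assert hi[0] == pytest.approx(eqs[2].T, rel=1e-5)

    def test_k_zero_pure_logistic(self, table1):
        eqs = base_equilibria(table1.with_k(0.0))
        assert [e.T for e in eqs] == [0.0, pytest.approx(1.0 / table1.b)]

    def test_m_zero_reduced_branch(self):
        with pytest.warns(UserWarning):
            p = BaseParams(a=0.5, b=1e-9, k=1e-4, sigma=10.0, d=1e-2, m=0.0)
        roots = base_positive_roots(p)
        assert len(roots) == 1
        # E* is pinned at sigma/d; T* solves a(1-bT) = k sigma/d
        T = roots[0]
        assert p.a * (1 - p.b * T) == pytest.approx(p.k * p.sigma / p.d)

    def test_negative_E_star_filtered(self, fig2):
        # above k_u only the cancer-free point survives
        _, k_u = base_k_thresholds(fig2)
        eqs = base_equilibria(fig2.with_k(10 * k_u))
        assert len(eqs) == 1 and eqs[0].T == 0.0


class TestBaseThresholds:
    def test_closed_form_values_table1(self, table1):
        k_l, k_u = base_k_thresholds(table1)
        L = np.longdouble
        assert k_l == pytest.approx(
            float(L(table1.a) * L(table1.d) / L(table1.sigma)), rel=1e-14
        )
        assert k_u > k_l

    def test_bracket_root_count_change_by_bisection(self, fig2):
        k_l, k_u = base_k_thresholds(fig2)

        def n_roots(k):
            return len(base_positive_roots(fig2.with_k(k)))

        # oracle: bisect the count-change location over a k-interval
        def bisect_change(lo, hi, n_lo):
            for _ in range(80):
                mid = math.sqrt(lo * hi)
                if n_roots(mid) == n_lo:
                    lo = mid
                else:
                    hi = mid
            return lo, hi

        # floating rounding of the discriminant blurs the switch location by
        # a few ulps relative; allow 1e-6 relative slack
        lo, hi = bisect_change(k_l / 10, math.sqrt(k_l * k_u), n_roots(k_l / 10))
        assert lo * (1 - 1e-6) <= k_l <= hi * (1 + 1e-6)
        lo, hi = bisect_change(math.sqrt(k_l * k_u), 10 * k_u, 2)
        assert lo * (1 - 1e-6) <= k_u <= hi * (1 + 1e-6)

    def test_sigma_scaling(self, fig2):
        k_l, k_u = base_k_thresholds(fig2)
        p = dataclasses.replace(fig2, sigma=fig2.sigma * 1e6)
        k_l2, k_u2 = base_k_thresholds(p)
        assert k_l2 == pytest.approx(k_l / 1e6)
        assert (k_u2 - k_l2) == pytest.approx((k_u - k_l) / 1e6)

    def test_regime_errors(self):
        with pytest.warns(UserWarning):
            p = BaseParams(a=0.5, b=1e-9, k=1e-4, sigma=10.0, d=1e-2, m=1e-6)
        with pytest.raises(RegimeError):
            base_k_thresholds(p)
        # m < 0 but m + b*d >= 0
        p2 = BaseParams(a=0.5, b=1e-2, k=1e-4, sigma=10.0, d=1.0, m=-1e-6)
        with pytest.raises(RegimeError):
            base_k_thresholds(p2)


class TestClassifyBaseRegime:
    def test_cases(self, fig2):
        k_l, k_u = base_k_thresholds(fig2)
        assert classify_base_regime(fig2.with_k(10 * k_u)).case_label == "i"
        rc = classify_base_regime(fig2.with_k(k_l / 2))
        assert rc.case_label == "ii"
        assert rc.n_positive_roots == 1
        rc = classify_base_regime(fig2.with_k((k_l + k_u) / 2))
        assert rc.case_label == "iii"
        assert rc.n_positive_roots == 2

    def test_marginal_at_thresholds(self, fig2):
        k_l, k_u = base_k_thresholds(fig2)
        assert classify_base_regime(fig2.with_k(k_l)).case_label == "marginal"
        assert classify_base_regime(fig2.with_k(k_u)).case_label == "marginal"

    def test_conditions_map(self, fig2):
        k_l, k_u = base_k_thresholds(fig2)
        rc = classify_base_regime(fig2.with_k((k_l + k_u) / 2))
        assert rc.conditions_satisfied == {
            "eq5": True, "eq6": True, "eq7": True, "eq8": True,
        }


class TestSaturationCubic:
    def test_reduces_to_base_m0_when_no_modulation(self):
        p = SaturationParams(
            a=0.514, b=1.02e-9, k=1e-3, sigma=10.0, d=1e-2,
            b_e=0.0, kappa_e=1e4, d_e=0.0, kappa_d=1e4,
        )
        roots = _cubic_positive_roots(saturation_cubic_coeffs(p))
        with pytest.warns(UserWarning):
            base_p = BaseParams(a=p.a, b=p.b, k=p.k, sigma=p.sigma, d=p.d, m=0.0)
        np.testing.assert_allclose(roots, base_positive_roots(base_p), rtol=1e-9)

    def test_sign_of_A(self):
        for be, de in ((0.1, 2.0), (3.0, 0.5), (0.5, 0.2)):
            p = SaturationParams(
                a=0.514, b=1.02e-9, k=1e-3, sigma=10.0, d=1e-2,
                b_e=be, kappa_e=1e4, d_e=de, kappa_d=1e4,
            )
            c = saturation_cubic_coeffs(p)
            assert np.sign(c.A) == np.sign(p.a * p.b * (be - de - p.d))

    @pytest.mark.parametrize("seed", range(5))
    def test_cubic_roots_match_assembled_rational_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = SaturationParams(
            a=10 ** rng.uniform(-1, 0),
            b=10 ** rng.uniform(-10, -7),
            k=10 ** rng.uniform(-5, -2),
            sigma=10 ** rng.uniform(0, 2),
            d=10 ** rng.uniform(-3, -1),
            b_e=10 ** rng.uniform(-2, 0.5),
            kappa_e=10 ** rng.uniform(2, 6),
            d_e=10 ** rng.uniform(-1, 1),
            kappa_d=10 ** rng.uniform(2, 6),
        )
        c = saturation_cubic_coeffs(p)
        roots = _cubic_positive_roots(c)

        # oracle: assemble the equilibrium condition directly from the RHS
        def f(T):
            denom = (
                p.d
                - p.b_e * T / (p.kappa_e + T)
                + p.d_e * T / (p.kappa_d + T)
            )
            if denom <= 0:
                return np.nan
            E = p.sigma / denom
            return p.a * (1.0 - p.b * T) - p.k * E

        oracle = nullcline_positive_roots(f, 1e-4, 4.0 / p.b)
        # the oracle only sees physical roots (E* = sigma/denom > 0, i.e.
        # T* < 1/b); the raw cubic may carry an extra root with E* < 0
        physical = [r for r in roots if r < 1.0 / p.b]
        np.testing.assert_allclose(sorted(oracle), sorted(physical), rtol=1e-5)


class TestSaturationRegimes:
    def test_default_preset_is_bistable(self, saturation_default):
        bistable, rc = saturation_bistability(saturation_default)
        assert bistable
        assert rc.n_positive_roots == 2
        assert rc.conditions_satisfied == {"eq12": True, "eq13": True, "eq14": True}
        assert not saturation_multistability(saturation_default)

    def test_k_zero_not_bistable(self):
        p = SaturationParams(
            a=0.514, b=1.02e-9, k=0.0, sigma=10.0, d=1e-2,
            b_e=0.1, kappa_e=1e4, d_e=2.0, kappa_d=1e4,
        )
        c = saturation_cubic_coeffs(p)
        assert c.D == pytest.approx(p.kappa_d * p.kappa_e * p.a * p.d)
        assert c.D > 0
        bistable, _ = saturation_bistability(p)
        assert not bistable

    def test_bistability_common_in_high_exhaustion_region(self):
        rng = np.random.default_rng(42)
        n, hits = 200, 0
        for _ in range(n):
            p = SaturationParams(
                a=0.514, b=1.02e-9, sigma=10.0, d=1e-2,
                k=10 ** rng.uniform(np.log10(5e-4), -1),
                b_e=10 ** rng.uniform(-2, 0),
                d_e=10 ** rng.uniform(0, 1),
                kappa_e=10 ** rng.uniform(2, 6),
                kappa_d=10 ** rng.uniform(2, 6),
            )
            if saturation_bistability(p)[0]:
                hits += 1
        assert hits / n >= 0.5

    def test_multistable_example(self):
        assert saturation_multistability(MULTISTABLE_SAT)
        roots = _cubic_positive_roots(saturation_cubic_coeffs(MULTISTABLE_SAT))
        assert len(roots) == 3
        eqs = saturation_equilibria(MULTISTABLE_SAT)
        assert len(eqs) == 4
        assert [e.stability for e in eqs] == [
            "unstable", "stable", "unstable", "stable",
        ]
        bistable, _ = saturation_bistability(MULTISTABLE_SAT)
        assert not bistable  # labels are mutually exclusive

    def test_be_zero_never_multistable(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = SaturationParams(
                a=0.514, b=1.02e-9, sigma=10.0, d=1e-2,
                k=10 ** rng.uniform(-5, -1),
                b_e=0.0,
                d_e=10 ** rng.uniform(-2, 1),
                kappa_e=10 ** rng.uniform(2, 6),
                kappa_d=10 ** rng.uniform(2, 6),
            )
            assert not saturation_multistability(p)

    def test_trig_root_representation_vs_numpy_roots(self):
        # construct cubics with three known real roots; the trig forms must
        # reproduce the smallest and middle roots
        rng = np.random.default_rng(3)
        for _ in range(200):
            r = np.sort(rng.uniform(-10, 10, size=3))
            A = rng.choice([-1, 1]) * 10 ** rng.uniform(-3, 3)
            B = -A * r.sum()
            C = A * (r[0] * r[1] + r[0] * r[2] + r[1] * r[2])
            D = -A * r.prod()
            c = CubicCoefficients(A=A, B=B, C=C, D=D)
            if cubic_discriminant(c) <= 0:
                continue
            tr = _trig_roots(c)
            assert tr is not None
            np.testing.assert_allclose(tr, [r[0], r[1]], rtol=1e-6, atol=1e-8)


class TestNkCtl:
    def test_plausibility_sign_bookkeeping(self, nkctl_default):
        # exhaustion-dominated default: both bracket factors negative
        assert nkctl_plausibility(nkctl_default)
        p = dataclasses.replace(
            nkctl_default, c=0.0, k=0.0, sigma=10.0, omega=0.0,
            b_e=1.0, d_e=0.1, d=0.1,  # (be-de-d) > 0
        )
        assert not nkctl_plausibility(p)

    def test_plausibility_vs_longdouble(self, nkctl_default):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = dataclasses.replace(
                nkctl_default,
                b_e=10 ** rng.uniform(-2, 1),
                d_e=10 ** rng.uniform(-2, 1),
                b_n=10 ** rng.uniform(-2, 1),
                d_n=10 ** rng.uniform(-2, 1),
                k=10 ** rng.uniform(-6, -2),
                omega=10 ** rng.uniform(-10, -5),
            )
            L = np.longdouble
            expr = -L(p.a) * L(p.b) * (
                (L(p.b_e) - L(p.d_e) - L(p.d)) * (L(p.b_n) - L(p.d_n) - L(p.mu))
            ) - L(p.k) * L(p.sigma) * L(p.omega)
            assert nkctl_plausibility(p) == (float(expr) < 0)

    def test_plausibility_independent_of_kappas(self, nkctl_default):
        rng = np.random.default_rng(5)
        base_val = nkctl_plausibility(nkctl_default)
        for _ in range(50):
            p = dataclasses.replace(
                nkctl_default,
                kappa_be=10 ** rng.uniform(1, 8),
                kappa_de=10 ** rng.uniform(1, 8),
                kappa_bn=10 ** rng.uniform(1, 8),
                kappa_dn=10 ** rng.uniform(1, 8),
            )
            assert nkctl_plausibility(p) == base_val

    def test_contains_tumor_free_point(self, nkctl_default):
        eqs = nkctl_equilibria(nkctl_default)
        assert eqs[0].state == (0.0, nkctl_default.sigma / nkctl_default.mu, 0.0)

    def test_default_preset_bistable_vs_integration_oracle(self, nkctl_default):
        eqs = nkctl_equilibria(nkctl_default)
        stables = [e for e in eqs if e.stability == "stable"]
        unstables = [e for e in eqs if e.stability == "unstable"]
        assert len(stables) == 2 and len(unstables) >= 1
        assert stables[0].T == 0.0 and stables[1].T > 1e8
        # oracle: integrate from a lattice of initial tumor sizes
        attractor_Ts = set()
        for T0 in (1.0, 1e2, 1e4, 1e6, 1e8, 1e9):
            end = integrate_to_attractor(
                nkctl_default, (T0, nkctl_default.sigma / nkctl_default.mu, 0.0),
                t_end=20000.0,
            )
            attractor_Ts.add(round(math.log10(max(end[0], 1e-3)), 1))
        assert len(attractor_Ts) == 2  # two distinct attractors

    def test_at_most_six_fixed_points(self, nkctl_default):
        rng = np.random.default_rng(13)
        for _ in range(10):
            p = dataclasses.replace(
                nkctl_default,
                b_n=10 ** rng.uniform(-2, 0),
                d_n=10 ** rng.uniform(-1, 1),
                b_e=10 ** rng.uniform(-2, 0),
                d_e=10 ** rng.uniform(-1, 1),
                omega=10 ** rng.uniform(-9, -6),
            )
            assert len(nkctl_equilibria(p)) <= 6


class TestStability:
    def test_cancer_free_unstable_below_kl(self, fig2):
        k_l, _ = base_k_thresholds(fig2)
        p = fig2.with_k(k_l / 2)
        label, eigs = stability_of((0.0, p.sigma / p.d), p)
        assert label == "unstable"
        assert max(e.real for e in eigs) == pytest.approx(
            p.a - p.k * p.sigma / p.d, rel=1e-5
        )

    def test_cancer_free_stable_above_ku(self, fig2):
        _, k_u = base_k_thresholds(fig2)
        p = fig2.with_k(2 * k_u)
        label, _ = stability_of((0.0, p.sigma / p.d), p)
        assert label == "stable"

    def test_fd_jacobian_matches_closed_form(self, fig2):
        k_l, k_u = base_k_thresholds(fig2)
        p = fig2.with_k(math.sqrt(k_l * k_u))
        for eq in base_equilibria(p):
            T, E = eq.state
            J = np.array(
                [
                    [p.a - 2 * p.a * p.b * T - p.k * E, -p.k * T],
                    [p.m * E, -p.d + p.m * T],
                ]
            )
            expected = np.sort(np.linalg.eigvals(J).real)
            got = np.sort(np.array([ev.real for ev in eq.eigenvalues]))
            np.testing.assert_allclose(got, expected, rtol=1e-4, atol=1e-12)

    def test_not_an_equilibrium_raises(self, fig2):
        with pytest.raises(NotAnEquilibriumError):
            stability_of((1e6, 1e6), fig2)

    def test_labels_confirmed_by_integration(self, fig2):
        k_l, k_u = base_k_thresholds(fig2)
        p = fig2.with_k(math.sqrt(k_l * k_u))
        eqs = base_equilibria(p)
        mid = eqs[1]
        # perturb off the unstable point: trajectories leave
        for fac in (0.9, 1.1):
            end = integrate_to_attractor(p, (mid.T * fac, mid.E), t_end=3000.0)
            assert abs(end[0] - mid.T) > 0.5 * mid.T
        # stable point attracts its neighborhood
        big = eqs[2]
        end = integrate_to_attractor(p, (big.T * 0.9, big.E), t_end=3000.0)
        assert end[0] == pytest.approx(big.T, rel=1e-4)
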