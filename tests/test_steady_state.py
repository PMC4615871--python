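"""Closed-form stationary distributions and parameter relations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nbinom, poisson

import hemaclone as hc
from hemaclone.presets import matched_mechanistic_pair


def make_params(**kw):
    base = dict(alpha=0.5, p=10.0, mu_p=6.0, mu_d=2.0, eta=0.5, omega=4.0,
                K=2000.0, U=200.0, C=1000.0)
    base.update(kw)
    return hc.ModelParams(**base)


class TestGrowthRate:
    def test_hill_limits(self):
        assert hc.growth_rate(0.0, 10.0, 1e4) == 10.0
        assert hc.growth_rate(1e4, 10.0, 1e4) == pytest.approx(5.0)

    def test_monotone_to_zero(self):
        N = np.geomspace(1, 1e12, 60)
        r = hc.growth_rate(N, 10.0, 1e4)
        assert np.all(np.diff(r) < 0)
        assert r[-1] < 1e-6


class TestSteadyStateNp:
    def test_zero_influx_closed_form(self):
        p = make_params(alpha=0.0)
        Np, rbar, delta = hc.steady_state_Np(p)
        assert Np == pytest.approx(p.K * (p.p - p.mu) / p.mu)
        assert rbar == pytest.approx(1.0)  # r(N_p*) = mu exactly

    def test_balance_residual(self):
        p = make_params()
        Np, rbar, delta = hc.steady_state_Np(p)
        r = hc.growth_rate(Np, p.p, p.K)
        residual = p.alpha * (p.U + p.C) + (r - p.mu) * Np
        assert abs(residual) < 1e-8 * p.mu * Np

    def test_subcritical_no_root(self):
        with pytest.raises(ValueError):
            hc.steady_state_Np(make_params(alpha=0.0, p=4.0))

    def test_differentiated_pool_balance(self):
        p = make_params()
        Np, _, _ = hc.steady_state_Np(p)
        Nd = p.w * Np
        assert (1 + p.eta) * p.omega * Np - p.mu_d * Nd == pytest.approx(0.0, abs=1e-9)


class TestDeltaApprox:
    def test_no_hsc_gives_zero(self):
        assert hc.delta_approx(make_params(U=0.0, C=1.0, alpha=0.0)) == 0.0

    def test_inverse_in_K(self):
        p1, p2 = make_params(K=1e6), make_params(K=2e6)
        assert hc.delta_approx(p1) == pytest.approx(2 * hc.delta_approx(p2))

    def test_direct_evaluation(self):
        # alpha=0.2, mu=5, U+C=1e4, K=1e9 -> 0.2*1e4/(5*1e9) = 4e-7
        p = make_params(alpha=0.2, p=10.0, mu_p=5.0, eta=0.0, omega=4.0,
                        U=9000.0, C=1000.0, K=1e9)
        assert hc.delta_approx(p) == pytest.approx(4e-7)

    def test_agrees_with_exact_root_at_small_delta(self):
        p = make_params(alpha=0.05, K=1e7)
        _, _, delta = hc.steady_state_Np(p)
        approx = hc.delta_approx(p)
        assert delta < 1e-2
        # relative error is O(delta) with an O(p/(p-mu)) prefactor
        assert abs(approx / delta - 1.0) < 10 * delta


class TestProgenitorCloneDist:
    def test_geometric_special_case(self):
        # a=1, rbar=0.5 is geometric: P_k = 0.5^(k+1)
        P = hc.progenitor_clone_dist(1.0, 0.5, k_max=40)
        assert np.allclose(P.values, 0.5 ** (np.arange(41) + 1.0), rtol=1e-12)
        assert P.values[0] == pytest.approx(0.5)  # (1-rbar)^a

    def test_one_step_balance(self):
        # (alpha + r k) P_k = mu (k+1) P_{k+1} with a=alpha/r, rbar=r/mu
        a, rbar = 0.07, 0.9
        r, mu = rbar, 1.0
        alpha = a * r
        P = hc.progenitor_clone_dist(a, rbar, k_max=300).values
        k = np.arange(300)
        lhs = (alpha + r * k) * P[:-1]
        rhs = mu * (k + 1) * P[1:]
        assert np.allclose(lhs, rhs, rtol=1e-12)

    def test_log_series_limit_slope(self):
        # for a << 1: P_k ~ rbar^k k^(a-1), so ln P_k - (a-1) ln k is linear
        # with slope ln rbar
        a, rbar = 0.01, 0.99
        P = hc.progenitor_clone_dist(a, rbar, k_max=200).values
        k = np.arange(1, 101)
        y = np.log(P[1:101]) - (a - 1.0) * np.log(k)
        slope = np.polyfit(k, y, 1)[0]
        assert abs(slope / math.log(rbar) - 1.0) < 0.01

    def test_tail_auto_extension(self):
        P = hc.progenitor_clone_dist(0.05, 0.999)
        assert P.truncated_mass < 1e-12
        assert P.values.sum() == pytest.approx(1.0, abs=1e-11)


class TestPeripheralCloneDist:
    def test_empty_clone_stays_empty(self):
        assert hc.peripheral_conditional(0, 3.0).pmf(0) == 1.0

    def test_total_expectation(self):
        P = hc.progenitor_clone_dist(0.5, 0.8, k_max=200)
        w = 2.5
        y = hc.peripheral_clone_dist(P, w)
        assert y.mean() == pytest.approx(w * P.mean(), rel=1e-8)

    def test_mixture_normalization(self):
        P = hc.progenitor_clone_dist(0.5, 0.8, k_max=200)
        y = hc.peripheral_clone_dist(P, 1.5)
        assert y.values.sum() + y.truncated_mass == pytest.approx(1.0, abs=1e-9)


class TestSampledCloneDist:
    def test_zero_sampling(self):
        m = hc.sampled_clone_dist(0.1, 0.9, 0.0, q_max=5)
        assert m.values[0] == 1.0
        assert np.all(m.values[1:] == 0.0)

    def test_clone_conservation(self):
        m = hc.sampled_clone_dist(0.05, 0.995, 1e-3)
        assert m.values.sum() + m.truncated_mass == pytest.approx(1.0, abs=1e-10)

    def test_generating_function_identity(self):
        # detected fraction from the q-sum equals the closed form
        a, delta, ew = 0.1, 1e-3, 5e-5
        m = hc.sampled_clone_dist(a, 1.0 - delta, ew, tail_tol=1e-12)
        exact = hc.sampled_clone_fraction(a, delta, ew, form="exact")
        assert abs(m.values[1:].sum() - exact) < 1e-8

    def test_kernel_sum_cross_check(self):
        a, rbar, ew = 0.04, 1.0 - 1e-4, 5e-5
        m = hc.sampled_clone_dist(a, rbar, ew)
        mk = hc.sampled_clone_dist(a, rbar, ew, q_max=m.values.size - 1,
                                   method="kernel-sum")
        rel = np.abs(m.values - mk.values) / np.maximum(m.values, 1e-300)
        assert rel.max() < 1e-8

    def test_two_stage_collapse_at_small_eps(self):
        # the single-Poisson collapse converges to the exact two-stage sum:
        # total variation O(eps), per-entry relative error O(eps*(1+q)^2)
        a, rbar, w = 0.5, 0.97, 3.0
        eps = 1e-3
        m1 = hc.sampled_clone_dist(a, rbar, eps * w, q_max=30)
        m2 = hc.sampled_clone_dist_two_stage(a, rbar, eps, w, q_max=30)
        tv = 0.5 * np.sum(np.abs(m1.values[:31] - m2.values))
        assert tv < 0.2 * eps
        q = np.arange(10)
        rel = np.abs(m1.values[:10] - m2.values[:10]) / m1.values[:10]
        assert np.all(rel < 2.0 * eps * (1.0 + q) ** 2)

    def test_monotone_decreasing_small_a(self):
        for a in (0.0025, 0.01, 0.1):
            m = hc.sampled_clone_dist(a, math.exp(-5e-5 / 70.0), 5e-5,
                                      q_max=1000)
            assert np.all(np.diff(m.values[1:]) < 0)

    def test_a_rescales_distribution(self):
        # varying a at fixed R nearly rescales <m_q>; the residual drift of
        # the ratio follows the gamma-form prediction q^-(a2-a1)
        rbar = math.exp(-5e-5 / 70.0)
        m = {a: hc.sampled_clone_dist(a, rbar, 5e-5, q_max=1000).values[1:]
             for a in (0.0025, 0.01, 0.1)}
        ratio_small = m[0.0025] / m[0.01]
        med = np.median(ratio_small)
        assert ratio_small.max() < 1.10 * med
        assert ratio_small.min() > 0.90 * med
        ratio_wide = m[0.0025] / m[0.1]
        drift = ratio_wide.max() / ratio_wide.min()
        assert drift < 1.1 * 1000 ** (0.1 - 0.0025)

    @settings(max_examples=20, deadline=None)
    @given(a=st.floats(0.005, 2.0), delta=st.floats(1e-4, 0.2),
           lam_rel=st.floats(0.05, 20.0))
    def test_normalization_property(self, a, delta, lam_rel):
        ew = lam_rel * delta
        m = hc.sampled_clone_dist(a, 1.0 - delta, ew)
        assert m.values.min() >= 0.0
        assert m.values.sum() + m.truncated_mass == pytest.approx(1.0, abs=1e-9)


class TestCumulativeQ:
    def test_point_mass(self):
        m = hc.SizeDistribution(np.array([0.0, 5.0]))
        q, Q = hc.cumulative_F_and_Q(m, S=1)
        assert Q[-1] == 1.0 and Q[0] == 1.0

    def test_scale_invariance_and_monotone(self):
        m = hc.sampled_clone_dist(0.1, 0.99, 1e-3, q_max=200)
        q, Q1 = hc.cumulative_F_and_Q(m, S=200)
        m2 = hc.SizeDistribution(7.5 * m.values)
        _, Q2 = hc.cumulative_F_and_Q(m2, S=200)
        assert np.allclose(Q1, Q2, rtol=1e-12)
        assert np.all(np.diff(Q1) >= 0)
        assert Q1[-1] == pytest.approx(1.0)

    def test_no_detected_clones_error(self):
        m = hc.SizeDistribution(np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            hc.cumulative_F_and_Q(m, S=2)


class TestSampledCloneFraction:
    def test_zero_sampling_zero(self):
        assert hc.sampled_clone_fraction(0.1, 0.01, 0.0, "exact") == 0.0
        v, _ = hc.sampled_clone_fraction(0.1, 0.01, 0.0, "log_approx")
        assert v == 0.0

    def test_deep_sampling_limit(self):
        # eps_w -> infinity: every clone present in the progenitor pool is
        # seen, so C_s/C -> 1 - delta^a
        a, delta = 0.05, 0.01
        v = hc.sampled_clone_fraction(a, delta, 200.0, "exact")
        assert v == pytest.approx(1.0 - delta ** a, rel=1e-9)

    def test_log_approx_at_rq5427_scale(self):
        a, ew = 0.01, 5e-5
        delta = ew / 70.0
        v, valid = hc.sampled_clone_fraction(a, delta, ew, "log_approx")
        assert v == pytest.approx(0.01 * math.log(71.0), rel=1e-9)
        assert v == pytest.approx(0.0426, abs=2e-4)
        assert valid
        # the logarithmic approximation overshoots the exact form by ~2.1%
        # here (the gap is deterministic; it shrinks with eps_w/delta)
        exact = hc.sampled_clone_fraction(a, delta, ew, "exact")
        assert abs(v / exact - 1.0) < 0.025


class TestEffectiveFromMechanistic:
    def test_R_delta_epsw_consistency(self):
        p = make_params(alpha=0.05, K=1e7, S=1e4)
        eff = hc.effective_from_mechanistic(p)
        assert eff.delta < 1e-2
        ratio = eff.R * eff.delta / eff.eps_w
        assert 1.0 - eff.delta <= ratio <= 1.0 + 1e-12

    def test_matched_mechanistic_sets_identical_Q(self):
        p1, p2 = matched_mechanistic_pair()
        e1 = hc.effective_from_mechanistic(p1)
        e2 = hc.effective_from_mechanistic(p2)
        m1 = hc.sampled_clone_dist(e1.a, e1.rbar, e1.eps_w, q_max=500)
        m2 = hc.sampled_clone_dist(e2.a, e2.rbar, e2.eps_w, q_max=500)
        _, Q1 = hc.cumulative_F_and_Q(m1, 500)
        _, Q2 = hc.cumulative_F_and_Q(m2, 500)
        assert np.max(np.abs(Q1 - Q2)) < 1e-6

    def test_alpha_to_zero(self):
        effs = [hc.effective_from_mechanistic(make_params(alpha=al, S=100.0))
                for al in (1e-3, 1e-5)]
        assert effs[1].a < effs[0].a < 1e-3
        m = hc.sampled_clone_dist(effs[1].a, effs[1].rbar, effs[1].eps_w,
                                  q_max=20)
        assert m.values[1:].sum() < 1e-4
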