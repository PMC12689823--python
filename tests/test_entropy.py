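"""Entropy flow estimators against the enumeration oracle."""

import numpy as np
import pytest

import sskim
from sskim import (
    entropy_flow_meanfield,
    entropy_flow_sampling,
    entropy_flow_steady,
    exact_entropy_flow,
    exact_two_step,
    mean_field_rates,
)
from sskim.entropy import log_transition_matrix


def _stationary_marginal(fields, couplings, iters=5000):
    trans = np.exp(log_transition_matrix(fields, couplings))
    p = np.full(trans.shape[0], 1.0 / trans.shape[0])
    for _ in range(iters):
        p_new = trans.T @ p
        if np.abs(p_new - p).max() < 1e-15:
            break
        p = p_new
    return p / p.sum()


class TestExactTwoStep:
    def test_independent_stationary_no_flow_no_production(self):
        fields = np.array([-0.7, 0.4])
        couplings = np.zeros((2, 2))
        p = _stationary_marginal(fields, couplings)
        flow, prod, *_ = exact_two_step(fields, couplings, p)
        assert abs(flow) < 1e-12
        assert abs(prod) < 1e-12

    def test_production_identity(self):
        rng = np.random.default_rng(0)
        fields = rng.normal(0, 1, 3)
        couplings = rng.normal(0, 0.8, (3, 3))
        p = np.abs(rng.random(8))
        p /= p.sum()
        flow, prod, s_prev, s_curr, _ = exact_two_step(fields, couplings, p)
        assert prod == pytest.approx((s_curr - s_prev) + flow, abs=1e-10)

    def test_symmetric_couplings_stationary_detailed_balance(self):
        rng = np.random.default_rng(1)
        j = rng.normal(0, 0.6, (4, 4))
        j = 0.5 * (j + j.T)
        fields = rng.normal(-0.5, 0.5, 4)
        p = _stationary_marginal(fields, j)
        _, prod, *_ = exact_two_step(fields, j, p)
        assert prod < 1e-8

    def test_second_law_random_systems(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            fields = rng.normal(0, 1, 3)
            couplings = rng.normal(0, 0.8, (3, 3))
            p = np.abs(rng.random(8))
            p /= p.sum()
            _, prod, *_ = exact_two_step(fields, couplings, p)
            assert prod >= -1e-12

    def test_rejects_unnormalized_marginal(self):
        with pytest.raises(ValueError):
            exact_two_step(np.zeros(2), np.zeros((2, 2)), np.full(4, 0.3))

    def test_capacity_limit(self):
        n = 5
        with pytest.raises(ValueError):
            exact_two_step(np.zeros(n), np.zeros((n, n)), np.full(2**n, 2.0**-n), n_max=4)


class TestExactSeries:
    def test_entropy_change_bounded_by_total_flow(self, small_params):
        series = exact_entropy_flow(small_params)
        s = series.system_entropy
        assert s[-1] - s[0] >= -series.flow.sum() - 1e-8

    def test_transient_flow_excursion_on_rate_drop(self):
        # a step decrease in fields forces entropy dissipation at the step
        n, T = 3, 20
        fields = np.full((n, T), 0.0)
        fields[:, 10:] = -3.0
        params = sskim.ParamTrajectory(fields, np.zeros((n, n, T)))
        series = exact_entropy_flow(params)
        assert series.flow[10] > series.flow[:9].max() + 0.1
        assert series.flow[10] > 0


class TestSamplingEstimator:
    def test_zero_couplings_flow_near_zero(self):
        # start at the stationary rate so every bin is flow-free
        from scipy.special import expit

        params = sskim.ParamTrajectory(np.full((3, 8), -0.5), np.zeros((3, 3, 8)))
        series = entropy_flow_sampling(params, n_s=4000, seed=0, p0=float(expit(-0.5)))
        assert (np.abs(series.flow) < 4 * series.stderr + 1e-9).all()

    def test_matches_exact_within_monte_carlo_error(self, small_params):
        exact = exact_entropy_flow(small_params)
        samp = entropy_flow_sampling(small_params, n_s=20_000, seed=1)
        z = np.abs(samp.flow - exact.flow) / samp.stderr
        assert z.max() < 4.0

    def test_decomposition_identity(self, small_params):
        samp = entropy_flow_sampling(small_params, n_s=2000, seed=2)
        assert np.abs(samp.flow + samp.forward - samp.backward).max() < 1e-12


class TestMeanField:
    def test_uncoupled_rates_exact(self):
        rng = np.random.default_rng(3)
        fields = rng.normal(-1, 1, (4, 6))
        params = sskim.ParamTrajectory(fields, np.zeros((4, 4, 6)))
        mf = mean_field_rates(params, m0=np.full(4, 0.5))
        expected = 1.0 / (1.0 + np.exp(-fields))
        assert np.allclose(mf.m[:, 1:], expected, atol=1e-12)
        assert np.allclose(mf.d_prev, 0.0)

    def test_weak_coupling_rates_near_exact(self):
        rng = np.random.default_rng(4)
        n, T = 5, 8
        fields = rng.normal(-0.5, 0.5, (n, T))
        couplings = rng.uniform(-0.3, 0.3, (n, n, T)) / np.sqrt(n)
        params = sskim.ParamTrajectory(fields, couplings)
        mf = mean_field_rates(params, m0=np.full(n, 0.5))
        # exact marginal rates by enumeration
        from sskim.entropy import all_states

        states = all_states(n)
        p = np.full(2**n, 2.0**-n)
        for t in range(1, T + 1):
            f_t, c_t = params.at(t)
            trans = np.exp(log_transition_matrix(f_t, c_t))
            p = trans.T @ p
            exact_rates = states.T @ p
            assert np.abs(mf.m[:, t] - exact_rates).max() < 0.01

    def test_uncoupled_constant_fields_zero_flow(self):
        fields = np.full((3, 5), -0.8)
        params = sskim.ParamTrajectory(fields, np.zeros((3, 3, 5)))
        m0 = 1.0 / (1.0 + np.exp(0.8)) * np.ones(3)
        series = entropy_flow_meanfield(params, m0=m0)
        assert np.abs(series.flow).max() < 1e-12

    def test_all_zero_params_gives_nlog2_entropies(self):
        n = 4
        params = sskim.ParamTrajectory(np.zeros((n, 6)), np.zeros((n, n, 6)))
        series = entropy_flow_meanfield(params, m0=np.full(n, 0.5))
        assert np.allclose(series.forward, n * np.log(2))
        assert np.allclose(series.backward, n * np.log(2))
        assert np.allclose(series.flow, 0.0)

    def test_per_neuron_contributions_sum_to_flow(self, small_params):
        series = entropy_flow_meanfield(small_params, m0=np.full(3, 0.5))
        assert np.allclose(series.per_neuron.sum(axis=0), series.flow, atol=1e-12)
        assert np.abs(series.flow + series.forward - series.backward).max() < 1e-12

    def test_weak_coupling_flow_close_to_exact(self):
        rng = np.random.default_rng(5)
        n, T = 6, 10
        fields = rng.normal(-1.0, 0.5, (n, T))
        couplings = rng.uniform(-0.3, 0.3, (n, n, T)) / np.sqrt(n)
        params = sskim.ParamTrajectory(fields, couplings)
        exact = exact_entropy_flow(params)
        mf = entropy_flow_meanfield(params, m0=np.full(n, 0.5))
        tol = np.maximum(0.02 * n, 0.1 * np.abs(exact.flow))
        assert (np.abs(mf.flow - exact.flow) <= tol).all()


class TestSteadyState:
    def test_uncoupled_zero_flow(self):
        flow, m = entropy_flow_steady(np.array([-1.0, 0.5]), np.zeros((2, 2)))
        assert flow == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(m, 1.0 / (1.0 + np.exp(-np.array([-1.0, 0.5]))))

    def test_consistent_with_dynamic_meanfield_after_burn_in(self):
        rng = np.random.default_rng(6)
        n, T = 8, 60
        fields = rng.normal(-0.5, 0.3, n)
        couplings = rng.normal(0, 0.4 / np.sqrt(n), (n, n))
        flow, m_fixed = entropy_flow_steady(fields, couplings)
        params = sskim.ParamTrajectory(
            np.tile(fields[:, None], (1, T)), np.tile(couplings[:, :, None], (1, 1, T))
        )
        dyn = entropy_flow_meanfield(params, m0=np.full(n, 0.5))
        assert abs(dyn.flow[-1] - flow) < 1e-6

    def test_quadrature_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        n = 4
        fields = rng.normal(-0.5, 0.5, n)
        couplings = rng.normal(0, 0.5, (n, n))
        flow, m = entropy_flow_steady(fields, couplings)
        # Monte-Carlo evaluation of the same Gaussian integral
        g = fields + couplings @ m
        delta = (couplings**2) @ (m * (1 - m))
        z = rng.standard_normal(1_000_000)
        vals = []
        for i in range(n):
            x = (1.0 / (1.0 + np.exp(-(g[i] + z * np.sqrt(delta[i])))) - m[i]) * z * np.sqrt(delta[i])
            vals.append(x)
        vals = np.array(vals).sum(axis=0)
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean() - flow) < 4 * se
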