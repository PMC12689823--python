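"""Entropy flow and entropy production of the kinetic Ising model.

Entropy flow at bin t is the expected log-ratio of forward to time-reversed
transition probabilities,

    sigma_t^flow = E_{p(x_t, x_{t-1})} [ log p(x_t | x_{t-1})
                                         - log p(x_{t-1} | x_t) ],

where the reverse conditional applies the bin-t transition kernel backwards
(the probability that the forward model at time t generates ``x_{t-1}``
from ``x_t``).  It splits into forward and backward conditional entropies,
``flow = -forward + backward``, and relates to entropy production through
``sigma_t = (S_t - S_{t-1}) + sigma_t^flow >= 0``.

Four estimators are provided:

* :func:`exact_two_step` / :func:`exact_entropy_flow` -- enumeration over
  all ``2^N`` states (the oracle, feasible for small N);
* :func:`entropy_flow_sampling` -- Monte-Carlo average of the model
  log-ratio over independently simulated chains;
* :func:`mean_field_rates` + :func:`entropy_flow_meanfield` -- the dynamic
  mean-field estimator: population input to each neuron is treated as a
  Gaussian whose mean and variance follow from independent marginal rates,
  and the conditional entropies become one-dimensional Gaussian integrals;
* :func:`entropy_flow_steady` -- the stationary mean-field formula at the
  self-consistent fixed point of the rate equation.

Gaussian integrals use 100-node Gauss-Hermite quadrature; entropies are in
nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from ._seeding import child_rng
from .core import EntropyFlowSeries, ParamTrajectory

__all__ = [
    "MeanFieldState",
    "all_states",
    "log_transition_matrix",
    "exact_two_step",
    "exact_entropy_flow",
    "entropy_flow_sampling",
    "mean_field_rates",
    "entropy_flow_meanfield",
    "entropy_flow_steady",
]

_TAG_FLOW_SAMPLING = 5

# Gauss-Hermite rule (physicists' convention); the change of variables
# z = sqrt(2) x turns the standard-normal expectation into sum(w f(sqrt(2) x)) / sqrt(pi)
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(100)
_GH_Z = np.sqrt(2.0) * _GH_NODES
_GH_W = _GH_WEIGHTS / np.sqrt(np.pi)

_VAR_FLOOR = 1e-12


def _gauss_expect(fun, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    """E[fun(mean + z * sqrt(var))] for standard-normal z, elementwise.

    Degenerate components (var below 1e-12) are evaluated at the mean.
    """
    mean = np.asarray(mean, dtype=float)
    var = np.asarray(var, dtype=float)
    mean, var = np.broadcast_arrays(mean, var)
    sd = np.sqrt(np.clip(var, 0.0, None))
    vals = fun(mean[..., None] + sd[..., None] * _GH_Z) @ _GH_W
    if np.any(var < _VAR_FLOOR):
        vals = np.where(var < _VAR_FLOOR, fun(mean), vals)
    return vals


# ---------------------------------------------------------------------------
# exact enumeration
# ---------------------------------------------------------------------------


def all_states(n: int) -> np.ndarray:
    """All ``2^n`` binary states, shape ``(2^n, n)``; bit j of the row index
    gives column j."""
    idx = np.arange(2**n)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(float)


def log_transition_matrix(fields_t: np.ndarray, couplings_t: np.ndarray) -> np.ndarray:
    """Dense log transition matrix ``log p(x_t = col | x_{t-1} = row)``."""
    states = all_states(fields_t.shape[0])
    h = states @ couplings_t.T + fields_t  # (P, N): input to each neuron given row state
    psi_sum = np.logaddexp(0.0, h).sum(axis=1)
    return h @ states.T - psi_sum[:, None]


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def exact_two_step(
    fields_t: np.ndarray,
    couplings_t: np.ndarray,
    marginal_prev: np.ndarray,
    n_max: int = 12,
):
    """One exact flow/production step by enumeration over ``2^N`` states.

    Builds the transition matrix of bin t, propagates the marginal, forms
    the joint ``p(x_t, x_{t-1})`` and evaluates entropy flow, entropy
    production and the two Shannon entropies.  The reverse conditional
    applies the same bin-t kernel backwards; because the kernel is the same
    function of (conditioning state, outcome), its log-matrix is the
    transpose companion of the forward one.

    Returns ``(flow, production, S_prev, S_curr, marginal_curr)``.
    """
    n = fields_t.shape[0]
    if n > n_max:
        raise ValueError(f"exact enumeration limited to N <= {n_max}, got N = {n}")
    marginal_prev = np.asarray(marginal_prev, dtype=float)
    if marginal_prev.shape != (2**n,):
        raise ValueError(f"marginal_prev must have length 2^N = {2 ** n}")
    if abs(marginal_prev.sum() - 1.0) > 1e-9 or (marginal_prev < -1e-15).any():
        raise ValueError("marginal_prev must be a probability vector (sum 1 within 1e-9)")

    log_t = log_transition_matrix(fields_t, couplings_t)
    trans = np.exp(log_t)
    marginal_curr = trans.T @ marginal_prev
    joint = marginal_prev[:, None] * trans  # joint[prev, curr]
    # log-ratio log p(curr|prev) - log p(prev|curr); kernel-reverse = log_t[curr, prev]
    flow = float((joint * (log_t - log_t.T)).sum())
    s_prev = _shannon(marginal_prev)
    s_curr = _shannon(marginal_curr)
    production = (s_curr - s_prev) + flow
    return flow, production, s_prev, s_curr, marginal_curr


def _bernoulli_product_marginal(n: int, p0: float) -> np.ndarray:
    states = all_states(n)
    with np.errstate(divide="ignore"):
        logp = states @ np.full(n, np.log(p0) if p0 > 0 else -np.inf) + (1 - states) @ np.full(
            n, np.log1p(-p0) if p0 < 1 else -np.inf
        )
    out = np.exp(logp)
    return out / out.sum()


def exact_entropy_flow(
    params: ParamTrajectory,
    p0: float = 0.5,
    marginal0: Optional[np.ndarray] = None,
    n_max: int = 12,
) -> EntropyFlowSeries:
    """Exact entropy-flow series by propagating the state marginal.

    Starts from the independent-Bernoulli(``p0``) distribution over bin 0
    (or an explicit ``marginal0``) and applies :func:`exact_two_step` at
    every bin.  Also fills production and system entropies.
    """
    n, T = params.n_neurons, params.n_steps
    marg = (
        np.asarray(marginal0, dtype=float)
        if marginal0 is not None
        else _bernoulli_product_marginal(n, p0)
    )
    flow = np.empty(T)
    production = np.empty(T)
    entropy = np.empty(T + 1)
    entropy[0] = _shannon(marg)
    forward = np.empty(T)
    backward = np.empty(T)
    for t in range(1, T + 1):
        f_t, c_t = params.at(t)
        log_tm = log_transition_matrix(f_t, c_t)
        trans = np.exp(log_tm)
        joint = marg[:, None] * trans
        forward[t - 1] = -float((joint * log_tm).sum())
        backward[t - 1] = -float((joint * log_tm.T).sum())
        flow[t - 1], production[t - 1], _, entropy[t], marg = exact_two_step(
            f_t, c_t, marg, n_max=n_max
        )
    return EntropyFlowSeries(
        flow=flow,
        forward=forward,
        backward=backward,
        method="exact",
        production=production,
        system_entropy=entropy,
    )


# ---------------------------------------------------------------------------
# sampling estimator
# ---------------------------------------------------------------------------


def entropy_flow_sampling(
    params: ParamTrajectory,
    n_s: int = 10_000,
    seed: int = 0,
    p0: float = 0.5,
) -> EntropyFlowSeries:
    """Monte-Carlo entropy flow from ``n_s`` independently simulated chains.

    Each chain starts at an i.i.d. Bernoulli(``p0``) state and evolves under
    the model; at every bin the model log-ratio
    ``log p(x_t | x_{t-1}) - log p(x_{t-1} | x_t)`` is averaged over the
    empirical joint of sampled ``(x_{t-1}, x_t)`` pairs.  A per-bin
    Monte-Carlo standard error accompanies the estimate.
    """
    if n_s < 1:
        raise ValueError("n_s must be >= 1")
    rng = child_rng(seed, _TAG_FLOW_SAMPLING)
    n, T = params.n_neurons, params.n_steps
    x_prev = (rng.random((n_s, n)) < p0).astype(float)
    flow = np.empty(T)
    forward = np.empty(T)
    backward = np.empty(T)
    stderr = np.empty(T)
    for t in range(1, T + 1):
        f_t, c_t = params.at(t)
        h_fwd = x_prev @ c_t.T + f_t  # (n_s, N)
        x_curr = (rng.random((n_s, n)) < expit(h_fwd)).astype(float)
        log_fwd = ((x_curr * h_fwd) - np.logaddexp(0.0, h_fwd)).sum(axis=1)
        h_bwd = x_curr @ c_t.T + f_t
        log_bwd = ((x_prev * h_bwd) - np.logaddexp(0.0, h_bwd)).sum(axis=1)
        ratio = log_fwd - log_bwd
        flow[t - 1] = ratio.mean()
        stderr[t - 1] = ratio.std(ddof=1) / np.sqrt(n_s) if n_s > 1 else np.nan
        forward[t - 1] = -log_fwd.mean()
        backward[t - 1] = -log_bwd.mean()
        x_prev = x_curr
    return EntropyFlowSeries(
        flow=flow, forward=forward, backward=backward, method="sampling", stderr=stderr
    )


# ---------------------------------------------------------------------------
# mean-field estimator
# ---------------------------------------------------------------------------


@dataclass
class MeanFieldState:
    """Mean-field rates and Gaussian input statistics.

    ``m[i, t]`` is the mean-field activation rate at bin ``t = 0..T``.  For
    each modelled bin ``t = 1..T`` (stored 0-based), ``g_prev``/``d_prev``
    are the mean and variance of the input ``h_{i,t}(x_{t-1})`` built from
    the rates at ``t - 1``, and ``g_curr``/``d_curr`` the same quantities
    built from the rates at ``t`` (used by the backward entropy).
    """

    m: np.ndarray  # (N, T + 1)
    g_prev: np.ndarray  # (N, T)
    d_prev: np.ndarray  # (N, T)
    g_curr: np.ndarray  # (N, T)
    d_curr: np.ndarray  # (N, T)

    def __post_init__(self) -> None:
        if (self.m < -1e-12).any() or (self.m > 1 + 1e-12).any():
            raise ValueError("mean-field rates must lie in [0, 1]")
        if (self.d_prev < -1e-12).any() or (self.d_curr < -1e-12).any():
            raise ValueError("input variances must be nonnegative")


def mean_field_rates(params: ParamTrajectory, m0: np.ndarray) -> MeanFieldState:
    """Forward mean-field recursion of activation rates.

    Treating neurons as independent with rates ``m_{:, t-1}``, the input to
    neuron i at bin t is Gaussian with

        g = theta_{i,t} + sum_j theta_{ij,t} m_{j,t-1},
        Delta = sum_j theta_{ij,t}^2 m_{j,t-1} (1 - m_{j,t-1}),

    and the next rate is the Gaussian average of the logistic function,
    ``m_{i,t} = E_z[ r(g + z sqrt(Delta)) ]``.  A natural choice of ``m0``
    is each neuron's spiking probability averaged over all bins and trials.
    """
    m0 = np.asarray(m0, dtype=float)
    n, T = params.n_neurons, params.n_steps
    if m0.shape != (n,):
        raise ValueError(f"m0 must have shape ({n},)")
    if (m0 < 0).any() or (m0 > 1).any():
        raise ValueError("m0 must lie in [0, 1]")
    m = np.empty((n, T + 1))
    m[:, 0] = m0
    g_prev = np.empty((n, T))
    d_prev = np.empty((n, T))
    g_curr = np.empty((n, T))
    d_curr = np.empty((n, T))
    for t in range(1, T + 1):
        f_t, c_t = params.at(t)
        mp = m[:, t - 1]
        g_prev[:, t - 1] = f_t + c_t @ mp
        d_prev[:, t - 1] = (c_t**2) @ (mp * (1.0 - mp))
        m[:, t] = np.clip(_gauss_expect(expit, g_prev[:, t - 1], d_prev[:, t - 1]), 0.0, 1.0)
        mc = m[:, t]
        g_curr[:, t - 1] = f_t + c_t @ mc
        d_curr[:, t - 1] = (c_t**2) @ (mc * (1.0 - mc))
    return MeanFieldState(m=m, g_prev=g_prev, d_prev=d_prev, g_curr=g_curr, d_curr=d_curr)


def _chi(h: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, h) - expit(h) * h


def entropy_flow_meanfield(
    params: ParamTrajectory,
    mf: MeanFieldState | None = None,
    m0: Optional[np.ndarray] = None,
) -> EntropyFlowSeries:
    """Dynamic mean-field entropy flow with per-neuron contributions.

    The forward conditional entropy of neuron i is the Gaussian average of
    the Bernoulli entropy ``chi`` over its input at ``t - 1``; the backward
    entropy averages ``phi_{i,t}(h) = -[m_{i,t-1} h - psi(h)]`` over the
    input built from the rates at ``t``.  ``flow = -forward + backward``
    holds exactly, per neuron and in total.
    """
    if mf is None:
        if m0 is None:
            m0 = np.full(params.n_neurons, 0.5)
        mf = mean_field_rates(params, m0)
    fwd_i = _gauss_expect(_chi, mf.g_prev, mf.d_prev)  # (N, T)
    psi_term = _gauss_expect(lambda h: np.logaddexp(0.0, h), mf.g_curr, mf.d_curr)
    bwd_i = -(mf.m[:, :-1] * mf.g_curr - psi_term)
    per_neuron = -fwd_i + bwd_i
    return EntropyFlowSeries(
        flow=per_neuron.sum(axis=0),
        forward=fwd_i.sum(axis=0),
        backward=bwd_i.sum(axis=0),
        method="meanfield",
        per_neuron=per_neuron,
    )


def entropy_flow_steady(
    fields: np.ndarray,
    couplings: np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-12,
    m_init: Optional[np.ndarray] = None,
):
    """Steady-state mean-field entropy flow for constant parameters.

    Iterates the rate recursion to its fixed point ``m`` and evaluates

        sigma^flow = sum_i E_z[ (r(g_i + z sqrt(Delta_i)) - m_i) * z sqrt(Delta_i) ],

    the covariance between each neuron's rate deviation and its input
    fluctuation.  Returns ``(flow, m_fixed)``.
    """
    fields = np.asarray(fields, dtype=float)
    couplings = np.asarray(couplings, dtype=float)
    n = fields.shape[0]
    m = np.full(n, 0.5) if m_init is None else np.asarray(m_init, dtype=float).copy()
    for _ in range(max_iter):
        g = fields + couplings @ m
        delta = (couplings**2) @ (m * (1.0 - m))
        m_new = np.clip(_gauss_expect(expit, g, delta), 0.0, 1.0)
        resid = np.abs(m_new - m).max()
        m = m_new
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"mean-field fixed point not reached in {max_iter} iterations "
            f"(residual {resid:.3e})"
        )
    g = fields + couplings @ m
    delta = (couplings**2) @ (m * (1.0 - m))
    sd = np.sqrt(np.clip(delta, 0.0, None))
    inputs = g[:, None] + sd[:, None] * _GH_Z
    integrand = (expit(inputs) - m[:, None]) * (sd[:, None] * _GH_Z)
    flow = float((integrand @ _GH_W).sum())
    return flow, m
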