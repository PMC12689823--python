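"""Sequential Bayesian estimation of time-varying kinetic-Ising parameters.

Each neuron's natural-parameter vector ``theta_t^i = [field, couplings]``
follows a Gaussian random walk (state model), while spikes follow the
logistic observation model.  Because the state model factorizes over
neurons, filtering, smoothing and hyperparameter optimization are carried
out independently per neuron:

* E-step: a forward pass alternates one-step prediction (random-walk
  spread) with a Laplace update -- the filter mean is the MAP of the
  concave per-bin posterior, found by damped Newton-Raphson, and the
  filter covariance is the inverse Hessian at the mode; a backward
  fixed-interval (RTS) recursion then yields the smoothed posterior and
  the lag-one covariances.
* M-step: closed-form updates of the transition covariance Q^i (optionally
  constrained to diagonal or scalar form) and of the initial mean and
  covariance.
* Convergence is monitored through the Laplace approximation of the log
  marginal likelihood accumulated during the forward pass.

The per-bin likelihood over trials only depends on the multiset of
(previous pattern, spike outcome) pairs, so trials are collapsed onto the
unique previous patterns once per fit; all Newton iterations then run on
these sufficient statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, logit

from .core import Hyperparams, PosteriorEstimate, SpikeTensor

__all__ = [
    "FitConfig",
    "predict_step",
    "filter_step",
    "smooth",
    "lag_one_covariance",
    "m_step",
    "marginal_log_likelihood",
    "fit_em",
]


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs for the EM fit; defaults suit the study conditions."""

    max_em_iter: int = 200
    em_rel_tol: float = 1e-6
    newton_max_iter: int = 100
    newton_grad_tol: float = 1e-8
    newton_max_halvings: int = 30
    q_structure: str = "full"  # full | diagonal | scalar
    init_q_scale: float = 1e-3
    optimize_initial: bool = True
    freeze_q: bool = False  # hold Q at its initial value (0 => stationary fit)

    def __post_init__(self) -> None:
        if self.max_em_iter < 1 or self.newton_max_iter < 1:
            raise ValueError("iteration caps must be >= 1")
        if self.em_rel_tol <= 0 or self.newton_grad_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.q_structure not in ("full", "diagonal", "scalar"):
            raise ValueError(f"unknown q_structure {self.q_structure!r}")


def _sym(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m + m.swapaxes(-1, -2))


def _spd_inverse(m: np.ndarray):
    """Cholesky-based inverse; returns (inverse, log-determinant of m)."""
    c, low = cho_factor(m, lower=True, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    inv = cho_solve((c, low), np.eye(m.shape[0]), check_finite=False)
    return _sym(inv), logdet


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------


def _bin_stats(x_t: np.ndarray, x_prev: np.ndarray):
    """Collapse trials onto unique previous patterns for one bin.

    Parameters are the ``N x L`` spike matrices of the current and previous
    bin.  Returns ``(U, c, S)`` where ``U`` is ``(K, N + 1)`` with a leading
    column of ones, ``c`` the pattern multiplicities and ``S[i, k]`` the
    number of trials with pattern ``k`` in which neuron ``i`` spiked.
    """
    x_t = np.asarray(x_t)
    x_prev = np.asarray(x_prev)
    if x_t.shape != x_prev.shape or x_t.ndim != 2:
        raise ValueError("x_t and x_prev must both be N x L matrices")
    n, L = x_t.shape
    patterns, inv, counts = np.unique(
        x_prev.T, axis=0, return_inverse=True, return_counts=True
    )
    k = patterns.shape[0]
    u = np.hstack([np.ones((k, 1)), patterns.astype(float)])
    s = np.empty((n, k))
    for i in range(n):
        s[i] = np.bincount(inv, weights=x_t[i].astype(float), minlength=k)
    return u, counts.astype(float), s


def _spike_stats(data: np.ndarray):
    """Per-bin sufficient statistics for all of ``data`` (shape N, T+1, L)."""
    return [_bin_stats(data[:, t, :], data[:, t - 1, :]) for t in range(1, data.shape[1])]


# ---------------------------------------------------------------------------
# E-step primitives
# ---------------------------------------------------------------------------


def predict_step(filt_mean: np.ndarray, filt_cov: np.ndarray, q: np.ndarray):
    """One-step prediction of the random-walk state model.

    The mean is carried over unchanged and the covariance inflates by the
    transition covariance: ``(theta, W + Q)``.
    """
    return filt_mean.copy(), _sym(filt_cov + q)


def _laplace_update(pred_mean, pred_cov, u, c, s_i, cfg: FitConfig):
    """MAP + Laplace covariance for one neuron at one bin.

    Maximizes the concave objective

        f(theta) = sum_k [ s_k * u_k.theta - c_k * psi(u_k.theta) ]
                   - 0.5 (theta - theta_pred)' W_pred^-1 (theta - theta_pred)

    by damped Newton-Raphson with step halving.  Returns the MAP, the
    inverse-Hessian covariance, the number of Newton iterations, the value
    ``q(theta) = f(theta_map)`` entering the Laplace marginal likelihood and
    the log-determinants of the filter and prediction covariances.
    """
    prec, logdet_pred = _spd_inverse(pred_cov)

    def objective(theta):
        h = u @ theta
        d = theta - pred_mean
        return float(s_i @ h - c @ np.logaddexp(0.0, h) - 0.5 * d @ prec @ d)

    theta = pred_mean.copy()
    obj = objective(theta)
    n_iter = 0
    for n_iter in range(1, cfg.newton_max_iter + 1):
        h = u @ theta
        r = expit(h)
        grad = u.T @ (s_i - c * r) - prec @ (theta - pred_mean)
        if np.abs(grad).max() < cfg.newton_grad_tol:
            n_iter -= 1
            break
        w = c * r * (1.0 - r)
        hess = u.T @ (u * w[:, None]) + prec
        try:
            ch = cho_factor(_sym(hess), lower=True, check_finite=False)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"filter Hessian not positive definite: {err}")
        step = cho_solve(ch, grad, check_finite=False)
        # Newton decrement: predicted objective gain; stop at the floating-
        # point plateau even if the raw gradient sits at its noise floor
        if 0.5 * float(grad @ step) < 1e-13 * (1.0 + abs(obj)):
            theta = theta + step
            obj = objective(theta)
            n_iter -= 1
            break
        alpha = 1.0
        for _ in range(cfg.newton_max_halvings):
            cand = theta + alpha * step
            cand_obj = objective(cand)
            if cand_obj >= obj:
                break
            alpha *= 0.5
        else:
            break  # no ascent direction left; keep current iterate
        theta, obj = cand, cand_obj
    else:
        warnings.warn(
            f"Newton-Raphson did not reach gradient tolerance in {cfg.newton_max_iter} "
            "iterations; using best iterate",
            RuntimeWarning,
        )

    h = u @ theta
    r = expit(h)
    w = c * r * (1.0 - r)
    hess = _sym(u.T @ (u * w[:, None]) + prec)
    filt_cov, logdet_hess = _spd_inverse(hess)
    return theta, filt_cov, n_iter, obj, -logdet_hess, -logdet_pred


def filter_step(pred_mean, pred_cov, x_t, x_prev, neuron: int, cfg: FitConfig | None = None):
    """Laplace filter update for ``neuron`` from raw spike matrices.

    ``x_t`` and ``x_prev`` are ``N x L`` binary matrices of the current and
    previous bin.  Returns ``(filt_mean, filt_cov, newton_iters)``.
    """
    cfg = cfg or FitConfig()
    u, c, s = _bin_stats(x_t, x_prev)
    mean, cov, iters, _, _, _ = _laplace_update(pred_mean, pred_cov, u, c, s[neuron], cfg)
    return mean, cov, iters


def lag_one_covariance(filt_cov: np.ndarray, pred_cov_next: np.ndarray, smooth_cov: np.ndarray) -> np.ndarray:
    """Lag-one smoothing covariance ``W_filt (W_pred_next)^-1 W_smooth``.

    With the smoother gain ``A = W_filt W_pred_next^-1`` this equals
    ``A @ smooth_cov``; passing the smoothed covariance of the later bin
    yields Cov(theta_t, theta_{t+1} | all data).
    """
    c, low = cho_factor(pred_cov_next, lower=True)
    return filt_cov @ cho_solve((c, low), smooth_cov)


def smooth(filt_means, filt_covs, pred_means, pred_covs):
    """Fixed-interval (RTS) smoother for one neuron.

    Inputs are stacked over bins ``t = 1..T`` (axis 0).  Returns smoothed
    means, covariances and the gains ``A_t = W_{t|t} (W_{t+1|t})^-1`` for
    ``t = 1..T-1``.
    """
    T = filt_means.shape[0]
    d = filt_means.shape[1]
    smooth_means = filt_means.copy()
    smooth_covs = filt_covs.copy()
    gains = np.empty((max(T - 1, 0), d, d))
    for t in range(T - 2, -1, -1):
        c, low = cho_factor(pred_covs[t + 1], lower=True, check_finite=False)
        # A_t = W_{t|t} W_{t+1|t}^{-1}  (symmetric matrices)
        a = filt_covs[t] @ cho_solve((c, low), np.eye(d), check_finite=False)
        gains[t] = a
        smooth_means[t] = filt_means[t] + a @ (smooth_means[t + 1] - pred_means[t + 1])
        smooth_covs[t] = _sym(
            filt_covs[t] + a @ (smooth_covs[t + 1] - pred_covs[t + 1]) @ a.T
        )
    return smooth_means, smooth_covs, gains


# ---------------------------------------------------------------------------
# E-step driver (one neuron)
# ---------------------------------------------------------------------------


def _estep_neuron(stats, neuron, mu, sigma, q, cfg: FitConfig):
    """Forward Laplace filter + backward smoother for one neuron.

    Returns a dict of stacked posterior pieces and this neuron's
    contribution to the approximate log marginal likelihood.
    """
    T = len(stats)
    d = mu.shape[0]
    pred_means = np.empty((T, d))
    pred_covs = np.empty((T, d, d))
    filt_means = np.empty((T, d))
    filt_covs = np.empty((T, d, d))
    ll = 0.0

    mean, cov = mu, sigma
    for t in range(T):
        if t == 0:
            pred_means[t], pred_covs[t] = mean.copy(), _sym(cov)
        else:
            pred_means[t], pred_covs[t] = predict_step(filt_means[t - 1], filt_covs[t - 1], q)
        u, c, s = stats[t]
        try:
            fm, fc, _, q_val, logdet_filt, neg_logdet_pred = _laplace_update(
                pred_means[t], pred_covs[t], u, c, s[neuron], cfg
            )
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"E-step failed at neuron {neuron}, bin {t + 1}: {err}")
        filt_means[t], filt_covs[t] = fm, fc
        ll += 0.5 * logdet_filt + 0.5 * neg_logdet_pred + q_val

    smooth_means, smooth_covs, gains = smooth(filt_means, filt_covs, pred_means, pred_covs)
    # lag-one: Cov(theta_t, theta_{t+1} | T) = A_t W_{t+1|T}
    lag_one = np.empty((max(T - 1, 0), d, d))
    for t in range(T - 1):
        lag_one[t] = gains[t] @ smooth_covs[t + 1]
    return {
        "pred_mean": pred_means,
        "pred_cov": pred_covs,
        "filt_mean": filt_means,
        "filt_cov": filt_covs,
        "smooth_mean": smooth_means,
        "smooth_cov": smooth_covs,
        "lag_one": lag_one,
        "ll": ll,
    }


# ---------------------------------------------------------------------------
# M-step and marginal likelihood
# ---------------------------------------------------------------------------


def _psd_project(m: np.ndarray) -> np.ndarray:
    """Clip tiny negative eigenvalues introduced by the Laplace approximation."""
    m = _sym(m)
    vals, vecs = np.linalg.eigh(m)
    if vals.min() >= 0:
        return m
    vals = np.clip(vals, 0.0, None)
    return _sym(vecs @ (vals[:, None] * vecs.T))


def m_step(posterior: PosteriorEstimate, cfg: FitConfig, current: Hyperparams) -> Hyperparams:
    """Closed-form hyperparameter updates from the smoothed posterior.

    The transition covariance update averages the expected squared state
    increments over bins 2..T:

        Q^i = 1/(T-1) * sum_t [ d_t d_t' + W_{t|T} + W_{t-1|T} - C_t - C_t' ]

    with ``d_t = theta_{t|T} - theta_{t-1|T}`` and ``C_t`` the lag-one
    covariance Cov(theta_{t-1}, theta_t | T).  Diagonal and scalar structures
    take the diagonal or trace of the full update.  When
    ``cfg.optimize_initial`` is set, the initial mean moves to
    ``theta_{1|T}`` (the joint maximizer), reducing the initial-covariance
    update to ``Sigma^i = W_{1|T}``.
    """
    n, T, d = posterior.smooth_mean.shape
    if T < 2 and not cfg.freeze_q:
        raise ValueError("Q update requires T >= 2")
    new_mu = current.mu.copy()
    new_sigma = current.sigma.copy()
    new_q = current.q.copy()
    for i in range(n):
        if not cfg.freeze_q:
            sm = posterior.smooth_mean[i]
            sc = posterior.smooth_cov[i]
            lag = posterior.lag_one_cov[i]
            acc = np.zeros((d, d))
            for t in range(1, T):
                dvec = sm[t] - sm[t - 1]
                c_t = lag[t - 1]  # Cov(theta_{t-1}, theta_t | T)
                acc += np.outer(dvec, dvec) + sc[t] + sc[t - 1] - c_t - c_t.T
            q_i = acc / (T - 1)
            if cfg.q_structure == "diagonal":
                q_i = np.diag(np.clip(np.diag(q_i), 0.0, None))
            elif cfg.q_structure == "scalar":
                q_i = max(np.trace(q_i) / d, 0.0) * np.eye(d)
            else:
                q_i = _psd_project(q_i)
            new_q[i] = q_i
        if cfg.optimize_initial:
            new_mu[i] = posterior.smooth_mean[i, 0]
            new_sigma[i] = _psd_project(posterior.smooth_cov[i, 0]) + 1e-10 * np.eye(d)
    return Hyperparams(mu=new_mu, sigma=new_sigma, q=new_q, q_structure=cfg.q_structure)


def marginal_log_likelihood(
    posterior: PosteriorEstimate, spikes: SpikeTensor, include_x0: bool = False
) -> float:
    """Laplace approximation of the log marginal likelihood.

    Accumulates, over neurons and bins,

        1/2 log|W_{t|t}| - 1/2 log|W_{t|t-1}| + q(theta_{t|t}),

    where ``q`` is the log-likelihood-plus-prior exponent of the filter
    density evaluated at the MAP.  The initial-state term ``log p(x_0)`` is
    zero under the conditioned-on-x0 convention used throughout the package
    and is stored separately on the posterior.
    """
    stats = _spike_stats(spikes.data)
    n, T = posterior.n_neurons, posterior.n_steps
    total = posterior.log_marginal_x0 if include_x0 else 0.0
    for i in range(n):
        for t in range(T):
            u, c, s = stats[t]
            theta = posterior.filt_mean[i, t]
            h = u @ theta
            dvec = theta - posterior.pred_mean[i, t]
            prec, logdet_pred = _spd_inverse(posterior.pred_cov[i, t])
            q_val = float(s[i] @ h - c @ np.logaddexp(0.0, h) - 0.5 * dvec @ prec @ dvec)
            _, logdet_filt = _spd_inverse(posterior.filt_cov[i, t])
            total += 0.5 * logdet_filt - 0.5 * logdet_pred + q_val
    return total


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def _initial_hyperparams(spikes: SpikeTensor, cfg: FitConfig) -> Hyperparams:
    n = spikes.n_neurons
    d = n + 1
    tl = spikes.n_steps * spikes.n_trials
    lo = 1.0 / (tl + 2.0)
    rates = np.clip(spikes.mean_rates(), lo, 1.0 - lo)
    mu = np.zeros((n, d))
    mu[:, 0] = logit(rates)
    sigma = np.broadcast_to(np.eye(d), (n, d, d)).copy()
    q_scale = 0.0 if cfg.freeze_q and cfg.init_q_scale == 0.0 else cfg.init_q_scale
    q = np.broadcast_to(q_scale * np.eye(d), (n, d, d)).copy()
    return Hyperparams(mu=mu, sigma=sigma, q=q, q_structure=cfg.q_structure)


def fit_em(
    spikes: SpikeTensor,
    cfg: FitConfig | None = None,
    seed: int = 0,
    init: Hyperparams | None = None,
    verbose: bool = False,
):
    """EM fit of the state-space kinetic Ising model.

    Alternates the per-neuron Laplace E-step with the closed-form M-step
    until the relative change of the approximate log marginal likelihood
    drops below ``cfg.em_rel_tol`` or ``cfg.max_em_iter`` is reached.
    Neurons are independent under the state model, so results do not depend
    on the order in which they are processed.

    Returns ``(PosteriorEstimate, Hyperparams, ll_trace)``.
    """
    del seed  # the fit is deterministic; accepted for interface uniformity
    cfg = cfg or FitConfig()
    if spikes.n_steps < 2 and not cfg.freeze_q:
        raise ValueError("need T >= 2 unless the state noise is frozen (stationary fit)")
    stats = _spike_stats(spikes.data)
    hp = init if init is not None else _initial_hyperparams(spikes, cfg)
    if cfg.freeze_q and init is None and cfg.init_q_scale != 0.0:
        # stationary mode: freeze the state noise at exactly zero
        hp = replace_q_with_zero(hp)
    n, T, d = spikes.n_neurons, spikes.n_steps, spikes.n_neurons + 1

    ll_trace: list[float] = []
    posterior = None
    static_hypers = cfg.freeze_q and not cfg.optimize_initial
    for it in range(cfg.max_em_iter):
        pieces = [_estep_neuron(stats, i, hp.mu[i], hp.sigma[i], hp.q[i], cfg) for i in range(n)]
        posterior = PosteriorEstimate(
            pred_mean=np.stack([p["pred_mean"] for p in pieces]),
            pred_cov=np.stack([p["pred_cov"] for p in pieces]),
            filt_mean=np.stack([p["filt_mean"] for p in pieces]),
            filt_cov=np.stack([p["filt_cov"] for p in pieces]),
            smooth_mean=np.stack([p["smooth_mean"] for p in pieces]),
            smooth_cov=np.stack([p["smooth_cov"] for p in pieces]),
            lag_one_cov=np.stack([p["lag_one"] for p in pieces]),
        )
        ll = float(sum(p["ll"] for p in pieces))
        posterior.log_marginal = ll
        ll_trace.append(ll)
        if verbose:
            print(f"EM iter {it + 1}: log marginal likelihood = {ll:.6f}")
        if len(ll_trace) >= 2:
            prev = ll_trace[-2]
            if abs(ll - prev) <= cfg.em_rel_tol * max(abs(prev), 1.0):
                break
        if static_hypers:
            break  # nothing to update; a single E-step is the fit
        if it < cfg.max_em_iter - 1:
            hp = m_step(posterior, cfg, hp)
    return posterior, hp, np.asarray(ll_trace)


def replace_q_with_zero(hp: Hyperparams) -> Hyperparams:
    """Copy of the hyperparameters with the transition covariance zeroed."""
    return Hyperparams(
        mu=hp.mu.copy(),
        sigma=hp.sigma.copy(),
        q=np.zeros_like(hp.q),
        q_structure=hp.q_structure,
    )
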