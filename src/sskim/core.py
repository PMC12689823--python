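"""Domain containers and elementary kinetic-Ising model functions.

The kinetic Ising model is a Markov chain over binary population states
``x_t in {0,1}^N``.  Given the previous state, neurons are conditionally
independent and spike with logistic probability

    p(x_{i,t} = 1 | x_{t-1}) = r(h_{i,t}),
    h_{i,t} = theta_{i,t} + sum_j theta_{ij,t} x_{j,t-1},

where ``theta_{i,t}`` is a time-varying field (bias) and ``theta_{ij,t}`` a
time-varying causal coupling from neuron j at the previous bin onto neuron i,
including the self-coupling ``theta_{ii,t}``.

Conventions used throughout the package:

* the per-neuron natural-parameter vector is ordered
  ``[field, coupling_{i1}, ..., coupling_{iN}]`` (dimension ``N + 1``);
* time bins are half-open intervals ``[t0 + t*delta, t0 + (t+1)*delta)``;
* bin 0 holds the initial state and carries no parameters: parameter
  trajectories are indexed ``t = 1..T`` and stored 0-based, so array column
  ``k`` holds the parameters of bin ``k + 1``;
* probabilities are handled in the log domain and entropies are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit


__all__ = [
    "SpikeTensor",
    "ParamTrajectory",
    "Hyperparams",
    "PosteriorEstimate",
    "EntropyFlowSeries",
    "scalar_links",
    "conditional_field",
    "log_transition_probability",
    "transition_probability",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SpikeTensor:
    """Binarized population activity, shape ``(N, T + 1, L)``.

    ``data[i, t, l]`` is 1 if neuron ``i`` fired at least once in bin ``t``
    of trial ``l``.  Bin 0 is the initial condition; bins ``1..T`` are
    modelled by the observation model.

    Parameters
    ----------
    data:
        Binary array of shape ``(N, T + 1, L)``.
    bin_width:
        Bin width ``delta`` in milliseconds.
    t0:
        Time of the left edge of bin 0, in milliseconds.
    """

    data: np.ndarray
    bin_width: float = 10.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-d (N, T+1, L), got shape {self.data.shape}")
        n, tp1, l = self.data.shape
        if n < 1 or tp1 < 2 or l < 1:
            raise ValueError(f"need N >= 1, T >= 1, L >= 1; got shape {self.data.shape}")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("spike tensor entries must be 0 or 1")
        if not np.isfinite(self.bin_width) or self.bin_width <= 0:
            raise ValueError("bin_width must be a positive, finite duration")
        self.data = self.data.astype(np.uint8, copy=False)

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_steps(self) -> int:
        """T, the number of modelled bins (excluding bin 0)."""
        return self.data.shape[1] - 1

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def mean_rates(self) -> np.ndarray:
        """Per-neuron spiking probability averaged over all bins and trials."""
        return self.data.reshape(self.n_neurons, -1).mean(axis=1)


@dataclass
class ParamTrajectory:
    """Time-indexed natural parameters of the kinetic Ising model.

    ``fields[i, k]`` is the field of neuron ``i`` at bin ``t = k + 1`` and
    ``couplings[i, j, k]`` the coupling from neuron ``j`` (at bin ``t - 1``)
    onto neuron ``i`` (at bin ``t``); the diagonal carries self-couplings.
    """

    fields: np.ndarray  # (N, T)
    couplings: np.ndarray  # (N, N, T)

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        self.couplings = np.asarray(self.couplings, dtype=float)
        if self.fields.ndim != 2 or self.couplings.ndim != 3:
            raise ValueError("fields must be (N, T) and couplings (N, N, T)")
        n, t = self.fields.shape
        if self.couplings.shape != (n, n, t):
            raise ValueError(
                f"couplings shape {self.couplings.shape} inconsistent with fields {self.fields.shape}"
            )
        if not (np.isfinite(self.fields).all() and np.isfinite(self.couplings).all()):
            raise ValueError("parameters must be finite")

    @property
    def n_neurons(self) -> int:
        return self.fields.shape[0]

    @property
    def n_steps(self) -> int:
        return self.fields.shape[1]

    def at(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(fields, couplings)`` for bin ``t`` (1-based, ``1..T``)."""
        if not 1 <= t <= self.n_steps:
            raise ValueError(f"t must be in 1..{self.n_steps}, got {t}")
        return self.fields[:, t - 1], self.couplings[:, :, t - 1]

    def natural(self) -> np.ndarray:
        """Stacked per-neuron parameter vectors, shape ``(N, T, N + 1)``."""
        return np.concatenate(
            [self.fields[:, :, None], np.moveaxis(self.couplings, 1, 2)], axis=2
        )

    @classmethod
    def from_natural(cls, theta: np.ndarray) -> "ParamTrajectory":
        """Inverse of :meth:`natural`; ``theta`` has shape ``(N, T, N + 1)``."""
        theta = np.asarray(theta, dtype=float)
        return cls(fields=theta[:, :, 0], couplings=np.moveaxis(theta[:, :, 1:], 2, 1))

    def rescaled(self, beta: float) -> "ParamTrajectory":
        """All fields and couplings multiplied by ``beta``."""
        return ParamTrajectory(self.fields * beta, self.couplings * beta)


@dataclass
class Hyperparams:
    """Per-neuron state-model hyperparameters.

    The parameters of neuron ``i`` follow a Gaussian random walk with initial
    law ``N(mu[i], sigma[i])`` and transition covariance ``q[i]``; each matrix
    is ``(N + 1) x (N + 1)``.
    """

    mu: np.ndarray  # (N, N+1)
    sigma: np.ndarray  # (N, N+1, N+1)
    q: np.ndarray  # (N, N+1, N+1)
    q_structure: str = "full"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q_structure not in ("full", "diagonal", "scalar"):
            raise ValueError(f"unknown q_structure {self.q_structure!r}")
        n, d = self.mu.shape
        if self.sigma.shape != (n, d, d) or self.q.shape != (n, d, d):
            raise ValueError("sigma and q must be stacked (N, N+1, N+1) matrices")
        for name, mats, strict in (("sigma", self.sigma, True), ("q", self.q, False)):
            if not np.allclose(mats, np.swapaxes(mats, 1, 2), atol=1e-10):
                raise ValueError(f"{name} matrices must be symmetric")
            eig = np.linalg.eigvalsh(mats)
            lo = eig.min()
            if strict and lo <= 0:
                raise ValueError(f"{name} must be positive definite (min eig {lo:.3g})")
            if not strict and lo < -1e-10 * max(1.0, float(eig.max())):
                raise ValueError(f"{name} must be positive semidefinite (min eig {lo:.3g})")

    @property
    def n_neurons(self) -> int:
        return self.mu.shape[0]

    @property
    def dim(self) -> int:
        return self.mu.shape[1]


@dataclass
class PosteriorEstimate:
    """Gaussian (Laplace) posterior summaries per neuron and bin.

    All mean arrays have shape ``(N, T, D)`` and covariance arrays
    ``(N, T, D, D)`` with ``D = N + 1``; time axis index ``k`` refers to bin
    ``t = k + 1``.  ``lag_one_cov[i, k]`` holds Cov(theta_t, theta_{t+1} | x_{0:T})
    for ``t = k + 1`` (``k = 0..T-2``).
    """

    pred_mean: np.ndarray
    pred_cov: np.ndarray
    filt_mean: np.ndarray
    filt_cov: np.ndarray
    smooth_mean: np.ndarray
    smooth_cov: np.ndarray
    lag_one_cov: np.ndarray
    log_marginal: float = np.nan
    log_marginal_x0: float = 0.0

    @property
    def n_neurons(self) -> int:
        return self.pred_mean.shape[0]

    @property
    def n_steps(self) -> int:
        return self.pred_mean.shape[1]

    def smoothed_params(self) -> ParamTrajectory:
        """Posterior-mean parameter trajectory (theta_{t|T})."""
        return ParamTrajectory.from_natural(self.smooth_mean)

    def smoothed_sd(self) -> np.ndarray:
        """Marginal posterior s.d. of each parameter, shape ``(N, T, D)``."""
        diag = np.diagonal(self.smooth_cov, axis1=2, axis2=3)
        return np.sqrt(np.clip(diag, 0.0, None))


@dataclass
class EntropyFlowSeries:
    """Per-bin entropy flow with its forward/backward decomposition.

    ``flow[k]`` is the entropy flow of bin ``t = k + 1`` in nats, and
    ``flow = -forward + backward`` holds exactly for every estimator.
    Exact enumeration additionally fills entropy production and the system
    entropies; the mean-field route fills per-neuron contributions.
    """

    flow: np.ndarray
    forward: np.ndarray
    backward: np.ndarray
    method: str
    per_neuron: Optional[np.ndarray] = None  # (N, T)
    production: Optional[np.ndarray] = None  # (T,)
    system_entropy: Optional[np.ndarray] = None  # (T + 1,), S_0..S_T
    stderr: Optional[np.ndarray] = None  # (T,), sampling only

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        self.forward = np.asarray(self.forward, dtype=float)
        self.backward = np.asarray(self.backward, dtype=float)
        if not (self.flow.shape == self.forward.shape == self.backward.shape):
            raise ValueError("flow, forward and backward must share one shape")

    @property
    def total(self) -> float:
        """Total entropy flow summed across all time bins."""
        return float(self.flow.sum())


# ---------------------------------------------------------------------------
# elementary functions
# ---------------------------------------------------------------------------


def scalar_links(h):
    """Logistic rate, log-partition and Bernoulli entropy of an input ``h``.

    Returns ``(r(h), psi(h), chi(h))`` with

        r(h)   = 1 / (1 + exp(-h)),
        psi(h) = log(1 + exp(h))        (stable softplus),
        chi(h) = -r(h) * h + psi(h)     (entropy of a Bernoulli(r(h))).

    All three are evaluated elementwise; ``h`` may be a scalar or array.
    """
    h = np.asarray(h, dtype=float)
    if not np.isfinite(h).all():
        raise ValueError("h must be finite")
    rate = expit(h)
    log_partition = np.logaddexp(0.0, h)
    bern_entropy = -rate * h + log_partition
    # roundoff can produce tiny negative entropies in the saturated tails
    bern_entropy = np.clip(bern_entropy, 0.0, None)
    if h.ndim == 0:
        return float(rate), float(log_partition), float(bern_entropy)
    return rate, log_partition, bern_entropy


def _check_binary(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if not np.isin(x, (0, 1)).all():
        raise ValueError(f"{name} entries must be 0 or 1")
    return x.astype(float)


def conditional_field(fields_t: np.ndarray, couplings_t: np.ndarray, x_prev: np.ndarray) -> np.ndarray:
    """Conditional input ``h_i = theta_{i,t} + sum_j theta_{ij,t} x_{j,t-1}``.

    ``x_prev`` may be a single state of shape ``(N,)`` or a batch ``(N, L)``;
    the result has the same trailing shape.
    """
    fields_t = np.asarray(fields_t, dtype=float)
    couplings_t = np.asarray(couplings_t, dtype=float)
    x_prev = _check_binary(x_prev, "x_prev")
    n = fields_t.shape[0]
    if couplings_t.shape != (n, n) or x_prev.shape[0] != n:
        raise ValueError(
            f"shape mismatch: fields {fields_t.shape}, couplings {couplings_t.shape}, "
            f"x_prev {x_prev.shape}"
        )
    h = couplings_t @ x_prev
    if x_prev.ndim == 1:
        return fields_t + h
    return fields_t[:, None] + h


def log_transition_probability(
    fields_t: np.ndarray,
    couplings_t: np.ndarray,
    x_prev: np.ndarray,
    x_curr: np.ndarray,
) -> float:
    """Log probability of the one-step transition ``x_prev -> x_curr``.

    ``log p = sum_i [x_curr_i * h_i - psi(h_i)]`` with ``h`` from
    :func:`conditional_field`.
    """
    x_curr = _check_binary(x_curr, "x_curr")
    h = conditional_field(fields_t, couplings_t, x_prev)
    if x_curr.shape != h.shape:
        raise ValueError(f"x_curr shape {x_curr.shape} does not match {h.shape}")
    psi = np.logaddexp(0.0, h)
    return float(np.sum(x_curr * h - psi))


def transition_probability(
    fields_t: np.ndarray,
    couplings_t: np.ndarray,
    x_prev: np.ndarray,
    x_curr: np.ndarray,
) -> float:
    """Probability of the one-step transition ``x_prev -> x_curr``."""
    return float(np.exp(log_transition_probability(fields_t, couplings_t, x_prev, x_curr)))
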