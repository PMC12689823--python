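"""Ground-truth generation for the kinetic Ising model, plus trial shuffling.

Time-varying fields and couplings are drawn independently from Gaussian
processes with a squared-exponential kernel

    k(t, s) = k0 * exp(-(t - s)^2 / (2 * tau^2)),

with time measured in bins.  The default configurations reproduce the
simulation conditions used to validate the estimator: couplings scale with
population size following the Sherrington-Kirkpatrick convention
(mean 5/N, variance 10/N, length-scale 30/sqrt(N)) while fields use
mean -3, variance 1, length-scale 50, keeping the population sparsely
active.

Every stochastic operation derives an independent child stream from the
global integer seed and the identity of the object being drawn (trajectory
kind and neuron indices), so the parameter set generated for a population of
size N is exactly the leading sub-block of the set generated for a larger
population under the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._seeding import child_rng
from .core import ParamTrajectory, SpikeTensor, conditional_field

__all__ = [
    "GPConfig",
    "field_gp",
    "coupling_gp",
    "sample_gp_trajectory",
    "sample_param_trajectories",
    "simulate_spikes",
    "trial_shuffle",
]

# integer tags used to derive independent child seed streams
_TAG_FIELD = 1
_TAG_COUPLING = 2
_TAG_SPIKES = 3
_TAG_SHUFFLE = 4


@dataclass(frozen=True)
class GPConfig:
    """Squared-exponential Gaussian-process prior for one parameter series.

    Parameters
    ----------
    mean:
        Constant GP mean.
    amplitude:
        Kernel variance ``k0`` (value of ``k(t, t)``).
    length_scale:
        Kernel length-scale ``tau`` in bins.
    jitter:
        Initial diagonal jitter added before Cholesky, as a fraction of
        ``k0``; escalated tenfold (up to ``1e-4 * k0``) on failure.
    """

    mean: float
    amplitude: float
    length_scale: float
    jitter: float = 1e-10

    def __post_init__(self) -> None:
        if not (self.amplitude > 0 and self.length_scale > 0 and self.jitter >= 0):
            raise ValueError("amplitude and length_scale must be > 0, jitter >= 0")

    def kernel(self, T: int) -> np.ndarray:
        t = np.arange(T, dtype=float)
        d = t[:, None] - t[None, :]
        return self.amplitude * np.exp(-(d**2) / (2.0 * self.length_scale**2))


def field_gp() -> GPConfig:
    """Study default for field trajectories: mean -3, k0 = 1, tau = 50."""
    return GPConfig(mean=-3.0, amplitude=1.0, length_scale=50.0)


def coupling_gp(n: int) -> GPConfig:
    """Study default for coupling trajectories at population size ``n``.

    Mean 5/N and variance 10/N follow the Sherrington-Kirkpatrick scaling;
    the length-scale is 30/sqrt(N) bins.
    """
    return GPConfig(mean=5.0 / n, amplitude=10.0 / n, length_scale=30.0 / np.sqrt(n))


def _chol_with_jitter(k: np.ndarray, k0: float, jitter0: float) -> np.ndarray:
    jitter = max(jitter0, 1e-10) * k0
    last_err: Exception | None = None
    while jitter <= 1e-4 * k0:
        try:
            return np.linalg.cholesky(k + jitter * np.eye(k.shape[0]))
        except np.linalg.LinAlgError as err:  # pragma: no cover - pathological kernels
            last_err = err
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        f"GP kernel not positive definite even with jitter {jitter / k0:.1e} * k0"
    ) from last_err


def sample_gp_trajectory(T: int, cfg: GPConfig, seed) -> np.ndarray:
    """One GP draw of length ``T``; deterministic given ``seed``.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``-compatible
    entropy tuple.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = child_rng(seed)
    chol = _chol_with_jitter(cfg.kernel(T), cfg.amplitude, cfg.jitter)
    return cfg.mean + chol @ rng.standard_normal(T)


def sample_param_trajectories(
    N: int,
    T: int,
    field_cfg: GPConfig | None = None,
    coupling_cfg: GPConfig | None = None,
    seed: int = 0,
) -> ParamTrajectory:
    """Draw N field and N^2 coupling series as independent GP trajectories.

    Each series uses a child stream keyed by ``(seed, kind, i[, j])``, so the
    trajectories for a population of size N coincide with the leading
    ``N x N`` (+ N fields) block of any larger population drawn with the same
    seed, enabling nested system-size comparisons.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if field_cfg is None:
        field_cfg = field_gp()
    if coupling_cfg is None:
        coupling_cfg = coupling_gp(N)
    fields = np.empty((N, T))
    couplings = np.empty((N, N, T))
    for i in range(N):
        fields[i] = sample_gp_trajectory(T, field_cfg, (seed, _TAG_FIELD, i))
        for j in range(N):
            couplings[i, j] = sample_gp_trajectory(T, coupling_cfg, (seed, _TAG_COUPLING, i, j))
    return ParamTrajectory(fields=fields, couplings=couplings)


def simulate_spikes(
    params: ParamTrajectory,
    L: int,
    seed: int = 0,
    p0: float = 0.5,
    bin_width: float = 10.0,
) -> SpikeTensor:
    """Generate binary spike data from the kinetic Ising model.

    Bin 0 is i.i.d. Bernoulli(``p0``) for every neuron and trial; bins
    ``1..T`` are drawn from the logistic transition law given the previous
    bin, independently across trials.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be a probability")
    rng = child_rng(seed, _TAG_SPIKES)
    N, T = params.n_neurons, params.n_steps
    data = np.zeros((N, T + 1, L), dtype=np.uint8)
    data[:, 0, :] = rng.random((N, L)) < p0
    for t in range(1, T + 1):
        f_t, c_t = params.at(t)
        h = conditional_field(f_t, c_t, data[:, t - 1, :])
        data[:, t, :] = rng.random((N, L)) < expit(h)
    return SpikeTensor(data=data, bin_width=bin_width)


def trial_shuffle(spikes: SpikeTensor, seed: int = 0) -> SpikeTensor:
    """Permute trial identities independently for each neuron.

    The per-neuron PSTH and within-trial single-neuron temporal structure
    (hence self-coupling statistics) are preserved bit-for-bit, while
    same-trial alignment across neurons -- the footprint of cross-neuron
    couplings -- is destroyed.  With a single trial the output equals the
    input.
    """
    data = spikes.data.copy()
    L = spikes.n_trials
    for i in range(spikes.n_neurons):
        rng = child_rng(seed, _TAG_SHUFFLE, i)
        data[i] = data[i][:, rng.permutation(L)]
    return SpikeTensor(data=data, bin_width=spikes.bin_width, t0=spikes.t0)
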