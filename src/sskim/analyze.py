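"""Summary statistics and perturbation analyses for fitted models.

These are the downstream quantities used to compare behavioral or
experimental conditions once a state-space kinetic Ising model has been
fitted: sparsity of firing-rate distributions, asymmetry of reciprocal
couplings, credible-interval screening of couplings, beta-rescaled
entropy-flow surfaces, shuffle subtraction and per-spike normalization,
and the d-prime behavioral sensitivity index.

Moment statistics use population conventions by default (divide by n, not
n - 1); pass ``sample=True`` for the sample conventions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.stats import norm

from .core import EntropyFlowSeries, ParamTrajectory, PosteriorEstimate
from .entropy import entropy_flow_meanfield

__all__ = [
    "sparsity_cv",
    "sparsification_skewness",
    "coupling_asymmetry",
    "significant_couplings",
    "rescale_entropy_scan",
    "beta_range_average",
    "flow_normalizations",
    "dprime",
]


def sparsity_cv(rates: np.ndarray, sample: bool = False) -> float:
    """Coefficient of variation (sd / mean) of a nonnegative rate vector.

    Used as a sparsity index of firing-rate distributions: a population in
    which a few neurons carry most of the activity has a high CV.
    """
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("rates must be nonnegative")
    mean = rates.mean()
    if mean <= 0:
        raise ValueError("CV undefined: mean rate is zero")
    return float(rates.std(ddof=1 if sample else 0) / mean)


def sparsification_skewness(rate_diff: np.ndarray, sample: bool = False) -> float:
    """Standardized third moment of per-neuron rate differences.

    A uniform change across neurons gives skewness 0; negative skewness
    means only a subset of neurons reduced their rates (sparsification).
    """
    x = np.asarray(rate_diff, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    c = x - x.mean()
    m2 = (c**2).mean()
    if m2 <= 0:
        raise ValueError("skewness undefined: zero variance")
    g1 = (c**3).mean() / m2**1.5
    if sample:
        n = x.size
        g1 *= np.sqrt(n * (n - 1)) / (n - 2)
    return float(g1)


def coupling_asymmetry(couplings_time_avg: np.ndarray) -> float:
    """Mean absolute difference of reciprocal couplings.

    Averages ``|theta_ij - theta_ji|`` over unordered pairs ``i < j``
    (self-pairs excluded) of a time-averaged coupling matrix.  Zero for a
    symmetric matrix; invariant under transposition.
    """
    m = np.asarray(couplings_time_avg, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n) or n < 2:
        raise ValueError("need a square matrix with N >= 2")
    iu = np.triu_indices(n, k=1)
    return float(np.abs(m[iu] - m.T[iu]).mean())


def significant_couplings(
    posterior: PosteriorEstimate,
    window: tuple[int, int],
    level: float = 0.95,
    include_self: bool = False,
) -> np.ndarray:
    """Couplings whose credible interval excludes zero somewhere in a window.

    ``mask[i, j]`` is True when the level-credible interval of
    ``theta_{ij,t}`` (posterior mean +- z * sd from the smoothed covariance
    diagonal) excludes 0 for at least one bin ``t`` in the inclusive
    1-based window.  Self-couplings are masked out unless requested; note
    the >= 1-bin union makes the screen anti-conservative relative to the
    per-bin level.
    """
    lo, hi = window
    n, T = posterior.n_neurons, posterior.n_steps
    if not 1 <= lo <= hi <= T:
        raise ValueError(f"window {window} outside 1..{T}")
    z = norm.ppf(0.5 + level / 2.0)
    sl = slice(lo - 1, hi)
    mean = posterior.smooth_mean[:, sl, 1:]  # (N, bins, N) couplings
    sd = posterior.smoothed_sd()[:, sl, 1:]
    excludes = np.abs(mean) - z * sd > 0
    mask = excludes.any(axis=1)  # (N, N): i <- j
    if not include_self:
        np.fill_diagonal(mask, False)
    return mask


def rescale_entropy_scan(
    params: ParamTrajectory,
    betas: np.ndarray,
    m0: Optional[np.ndarray] = None,
    shuffled_params: Optional[ParamTrajectory] = None,
) -> dict:
    """Mean-field entropy flow under global parameter rescaling theta -> beta*theta.

    Returns a dict with the ``flow``, ``forward`` and ``backward`` surfaces
    of shape ``(len(betas), T)``; if a shuffled-fit parameter set is given,
    its surface is computed the same way and a ``shuffle_subtracted``
    surface is included.  ``beta = 1`` reproduces the unperturbed estimate;
    ``beta = 0`` has zero flow with forward = backward = N log 2.
    """
    betas = np.asarray(betas, dtype=float)
    if not np.isfinite(betas).all() or (betas < 0).any():
        raise ValueError("betas must be finite and >= 0")
    if m0 is None:
        m0 = np.full(params.n_neurons, 0.5)

    def surface(p: ParamTrajectory):
        flows, fwds, bwds = [], [], []
        for b in betas:
            series = entropy_flow_meanfield(p.rescaled(b), m0=m0)
            flows.append(series.flow)
            fwds.append(series.forward)
            bwds.append(series.backward)
        return np.array(flows), np.array(fwds), np.array(bwds)

    flow, forward, backward = surface(params)
    out = {"betas": betas, "flow": flow, "forward": forward, "backward": backward}
    if shuffled_params is not None:
        sh_flow, _, _ = surface(shuffled_params)
        out["shuffled_flow"] = sh_flow
        out["shuffle_subtracted"] = flow - sh_flow
    return out


def beta_range_average(
    scan: dict, beta_range: tuple[float, float] = (0.2, 1.0), key: str = "flow"
) -> float:
    """Average a scan surface over a beta interval and all bins."""
    betas = scan["betas"]
    sel = (betas >= beta_range[0]) & (betas <= beta_range[1])
    if not sel.any():
        raise ValueError(f"no beta values inside {beta_range}")
    return float(scan[key][sel].mean())


def flow_normalizations(
    flow: EntropyFlowSeries,
    flow_shuffled: EntropyFlowSeries,
    rates: np.ndarray,
    per_spike_mode: str = "per_neuron",
):
    """Shuffle subtraction, total flow and flow per activity rate.

    Returns ``(shuffle_subtracted_series, total, per_spike)`` where the
    total sums the (unsubtracted) flow across bins and ``per_spike``
    normalizes flow by activity.  With ``per_spike_mode='per_neuron'``
    (default) it is the mean over neurons of each neuron's summed flow
    contribution divided by its mean rate, which requires per-neuron
    contributions on ``flow``; ``'population'`` divides the total flow by
    the population mean rate times N.
    """
    if flow.flow.shape != flow_shuffled.flow.shape:
        raise ValueError("flow series lengths do not match")
    rates = np.asarray(rates, dtype=float)
    subtracted = flow.flow - flow_shuffled.flow
    total = flow.total
    if per_spike_mode == "per_neuron":
        if flow.per_neuron is None:
            raise ValueError("per-neuron flow contributions unavailable on this estimator")
        if rates.shape != (flow.per_neuron.shape[0],):
            raise ValueError("rates must be per-neuron")
        if (rates <= 0).any():
            raise ValueError("per-neuron rates must be positive for per-spike flow")
        per_spike = float((flow.per_neuron.sum(axis=1) / rates).mean())
    elif per_spike_mode == "population":
        per_spike = float(total / (rates.mean() * rates.size))
    else:
        raise ValueError(f"unknown per_spike_mode {per_spike_mode!r}")
    return subtracted, total, per_spike


def dprime(hit_rate: float, fa_rate: float, n_trials: int = 100) -> float:
    """Behavioral sensitivity: z(hit rate) - z(false-alarm rate).

    Rates are clamped to ``[1/(2n), 1 - 1/(2n)]`` with ``n = n_trials``
    before the probit transform so that perfect rates remain finite.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    lo = 1.0 / (2.0 * n_trials)
    hit = np.clip(hit_rate, lo, 1.0 - lo)
    fa = np.clip(fa_rate, lo, 1.0 - lo)
    return float(norm.ppf(hit) - norm.ppf(fa))
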