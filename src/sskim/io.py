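"""Spike-event ingestion, neuron selection and HDF5 serialization.

Spike events come as TSV tables with a header row ``trial\tneuron\ttime_ms``
(tab-separated, ``#`` comments); trial and neuron ids may be arbitrary
integers and are densely remapped.  Binarization follows the standard
convention: an element is 1 if the neuron fired one or more times in the
half-open bin ``[t_start + t*delta, t_start + (t+1)*delta)``.

All domain containers round-trip through HDF5 as named groups with a
``sskim_kind`` attribute and layout version 1.
"""

from __future__ import annotations

import logging
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .core import (
    EntropyFlowSeries,
    Hyperparams,
    ParamTrajectory,
    PosteriorEstimate,
    SpikeTensor,
)

__all__ = [
    "read_spike_events",
    "bin_spikes",
    "select_top_neurons",
    "save_hdf5",
    "load_hdf5",
]

logger = logging.getLogger("sskim")

_LAYOUT_VERSION = 1


# ---------------------------------------------------------------------------
# spike events
# ---------------------------------------------------------------------------


def read_spike_events(path) -> pd.DataFrame:
    """Read a TSV spike-event table with columns (trial, neuron, time_ms)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"trial", "neuron", "time_ms"}
    if not required.issubset(df.columns):
        raise ValueError(f"event table must have columns {sorted(required)}, got {list(df.columns)}")
    if not np.isfinite(df["time_ms"]).all():
        raise ValueError("event times must be finite")
    return df


def bin_spikes(
    events: pd.DataFrame,
    bin_width: float,
    t_start: float = 0.0,
    n_bins: int | None = None,
) -> SpikeTensor:
    """Binarize a spike-event table into a spike tensor.

    ``n_bins`` is the total number of bins ``T + 1`` (bin 0 included).  An
    element is 1 when the neuron has at least one event in the half-open
    bin; an event exactly on a right edge belongs to the next bin.  Events
    outside the window are dropped (logged).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if n_bins is None or n_bins < 2:
        raise ValueError("n_bins (total bins, >= 2) is required")
    trials = np.sort(events["trial"].unique())
    neurons = np.sort(events["neuron"].unique())
    if len(trials) == 0:
        logger.warning("empty event table; returning all-zero 1x%dx1 tensor", n_bins)
        return SpikeTensor(np.zeros((1, n_bins, 1), dtype=np.uint8), bin_width, t_start)
    trial_idx = {t: k for k, t in enumerate(trials)}
    neuron_idx = {u: k for k, u in enumerate(neurons)}
    data = np.zeros((len(neurons), n_bins, len(trials)), dtype=np.uint8)
    b = np.floor((events["time_ms"].to_numpy() - t_start) / bin_width).astype(int)
    inside = (b >= 0) & (b < n_bins)
    dropped = int((~inside).sum())
    if dropped:
        logger.info("dropped %d events outside the binning window", dropped)
    sub = events.loc[inside]
    data[
        sub["neuron"].map(neuron_idx).to_numpy(),
        b[inside],
        sub["trial"].map(trial_idx).to_numpy(),
    ] = 1
    return SpikeTensor(data=data, bin_width=bin_width, t0=t_start)


def select_top_neurons(spikes: SpikeTensor, n_keep: int):
    """Keep the ``n_keep`` neurons with the highest grand-mean spike rate.

    Ties are broken by original index (lower index kept).  Returns the
    reduced tensor and the array of original indices retained, in order.
    """
    if not 1 <= n_keep <= spikes.n_neurons:
        raise ValueError(f"n_keep must be in 1..{spikes.n_neurons}")
    rates = spikes.mean_rates()
    # stable sort on negated rates implements the lower-index tie rule
    order = np.argsort(-rates, kind="stable")[:n_keep]
    kept = np.sort(order)
    return (
        SpikeTensor(spikes.data[kept], spikes.bin_width, spikes.t0),
        kept,
    )


# ---------------------------------------------------------------------------
# HDF5 serialization
# ---------------------------------------------------------------------------

Serializable = Union[SpikeTensor, ParamTrajectory, Hyperparams, PosteriorEstimate, EntropyFlowSeries]


def _write_group(g: h5py.Group, kind: str, arrays: dict, attrs: dict) -> None:
    g.attrs["sskim_kind"] = kind
    g.attrs["sskim_layout"] = _LAYOUT_VERSION
    for k, v in arrays.items():
        if v is not None:
            g.create_dataset(k, data=v)
    for k, v in attrs.items():
        g.attrs[k] = v


def save_hdf5(obj: Serializable, path, group: str = "/") -> None:
    """Serialize a domain container to an HDF5 file (layout version 1)."""
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        if isinstance(obj, SpikeTensor):
            _write_group(
                g,
                "spike_tensor",
                {"data": obj.data},
                {
                    "bin_width": obj.bin_width,
                    "t0": obj.t0,
                    "n_neurons": obj.n_neurons,
                    "n_steps": obj.n_steps,
                    "n_trials": obj.n_trials,
                },
            )
        elif isinstance(obj, ParamTrajectory):
            _write_group(g, "param_trajectory", {"fields": obj.fields, "couplings": obj.couplings}, {})
        elif isinstance(obj, Hyperparams):
            _write_group(
                g,
                "hyperparams",
                {"mu": obj.mu, "sigma": obj.sigma, "q": obj.q},
                {"q_structure": obj.q_structure},
            )
        elif isinstance(obj, PosteriorEstimate):
            _write_group(
                g,
                "posterior",
                {
                    "pred_mean": obj.pred_mean,
                    "pred_cov": obj.pred_cov,
                    "filt_mean": obj.filt_mean,
                    "filt_cov": obj.filt_cov,
                    "smooth_mean": obj.smooth_mean,
                    "smooth_cov": obj.smooth_cov,
                    "lag_one_cov": obj.lag_one_cov,
                },
                {"log_marginal": obj.log_marginal, "log_marginal_x0": obj.log_marginal_x0},
            )
        elif isinstance(obj, EntropyFlowSeries):
            _write_group(
                g,
                "entropy_flow",
                {
                    "flow": obj.flow,
                    "forward": obj.forward,
                    "backward": obj.backward,
                    "per_neuron": obj.per_neuron,
                    "production": obj.production,
                    "system_entropy": obj.system_entropy,
                    "stderr": obj.stderr,
                },
                {"method": obj.method},
            )
        else:
            raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def load_hdf5(path, group: str = "/") -> Serializable:
    """Load any container written by :func:`save_hdf5`."""
    with h5py.File(path, "r") as f:
        g = f[group]
        kind = g.attrs.get("sskim_kind")
        if kind == "spike_tensor":
            return SpikeTensor(g["data"][()], float(g.attrs["bin_width"]), float(g.attrs["t0"]))
        if kind == "param_trajectory":
            return ParamTrajectory(g["fields"][()], g["couplings"][()])
        if kind == "hyperparams":
            return Hyperparams(
                g["mu"][()], g["sigma"][()], g["q"][()], str(g.attrs["q_structure"])
            )
        if kind == "posterior":
            return PosteriorEstimate(
                pred_mean=g["pred_mean"][()],
                pred_cov=g["pred_cov"][()],
                filt_mean=g["filt_mean"][()],
                filt_cov=g["filt_cov"][()],
                smooth_mean=g["smooth_mean"][()],
                smooth_cov=g["smooth_cov"][()],
                lag_one_cov=g["lag_one_cov"][()],
                log_marginal=float(g.attrs["log_marginal"]),
                log_marginal_x0=float(g.attrs["log_marginal_x0"]),
            )
        if kind == "entropy_flow":
            opt = {k: (g[k][()] if k in g else None) for k in ("per_neuron", "production", "system_entropy", "stderr")}
            return EntropyFlowSeries(
                flow=g["flow"][()],
                forward=g["forward"][()],
                backward=g["backward"][()],
                method=str(g.attrs["method"]),
                **opt,
            )
        raise ValueError(f"group {group!r} in {path} holds no known container (kind={kind!r})")
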