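"""Single-neuron accuracy measures against a precise reference.

Four measures compare a discrete-backend spike train / voltage trace
with the precise (off-grid spike time) reference: cross-correlation
histograms of spike times at half-step bin width, Pearson correlation
between membrane traces on the common grid, the accumulated fractional
lead or lag of the spike times, and the RMSE of the spike times after
warping out the average lead or lag.

Sign convention: a negative lead/lag fraction means the discrete
simulation *leads* (fires early); positive means it lags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spikebench.errors import InvalidParameterError

__all__ = [
    "SpikeTrainPair",
    "CCH",
    "LeadLagResult",
    "RMSEResult",
    "cross_correlation_histogram",
    "membrane_correlation",
    "accumulated_lead_lag",
    "warped_rmse",
    "compare_single",
]


@dataclass(frozen=True)
class SpikeTrainPair:
    """A precise reference spike train and a discrete one (both ms,
    sorted ascending). ``N`` is the number of spikes used by the
    lead/lag and RMSE measures."""

    precise: np.ndarray
    discrete: np.ndarray

    @staticmethod
    def make(precise, discrete) -> "SpikeTrainPair":
        p = np.asarray(precise, dtype=float)
        d = np.asarray(discrete, dtype=float)
        if np.any(np.diff(p) < 0) or np.any(np.diff(d) < 0):
            raise InvalidParameterError("spike trains must be sorted ascending")
        return SpikeTrainPair(precise=p, discrete=d)

    @property
    def N(self) -> int:
        return min(len(self.precise), len(self.discrete))


@dataclass(frozen=True)
class CCH:
    """Cross-correlation histogram of ``t_discrete - t_precise`` lags.

    ``edges`` are symmetric around zero with bin width ``h/2``;
    ``counts`` may be normalized to sum 1 if requested.
    """

    edges: np.ndarray
    counts: np.ndarray
    window: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class LeadLagResult:
    """Accumulated fractional lead (negative) or lag (positive) of the
    discrete train: ``(t_discrete(N) - t_precise(N)) / t_discrete(N)``."""

    fraction: float


@dataclass(frozen=True)
class RMSEResult:
    """RMSE (ms) of the discrete spike times after warping by
    ``t_precise(N)/t_discrete(N)`` so the last considered spikes
    coincide."""

    rmse: float
    warp_factor: float


def cross_correlation_histogram(pair: SpikeTrainPair, h: float,
                                window: float = 5.0,
                                normalize: bool = False) -> CCH:
    """Histogram of all pairwise lags ``t_discrete - t_precise`` within
    ``±window`` ms, binned at ``h/2``.

    ``window`` must be a multiple of ``h/2``; the bin layout is symmetric
    around zero with a bin centered at zero lag. Empty trains give an
    all-zero histogram.
    """
    if h <= 0 or window <= 0:
        raise InvalidParameterError("h and window must be positive")
    binw = h / 2.0
    n_half = round(window / binw)
    if abs(n_half * binw - window) > 1e-9:
        raise InvalidParameterError("window must be a multiple of h/2")
    # symmetric layout: bin centered on zero plus n_half bins per side
    edges = (np.arange(-n_half, n_half + 2) - 0.5) * binw
    counts = np.zeros(len(edges) - 1)
    p, d = pair.precise, pair.discrete
    if len(p) and len(d):
        # pairwise differences restricted to the window, O(n * window
        # occupancy) via searchsorted
        lo = np.searchsorted(p, d - edges[-1], side="left")
        hi = np.searchsorted(p, d - edges[0], side="right")
        diffs = np.concatenate([
            d[i] - p[lo[i]:hi[i]] for i in range(len(d))
        ]) if np.any(hi > lo) else np.empty(0)
        if diffs.size:
            inside = (diffs >= edges[0]) & (diffs <= edges[-1])
            counts, _ = np.histogram(diffs[inside], bins=edges)
            counts = counts.astype(float)
    if normalize and counts.sum() > 0:
        counts = counts / counts.sum()
    return CCH(edges=edges, counts=counts, window=window)


def membrane_correlation(trace_a: np.ndarray, trace_b: np.ndarray) -> float:
    """Pearson correlation between two voltage traces on a common grid.

    Returns NaN for zero-variance traces (undefined)."""
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidParameterError("traces must have equal length")
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def accumulated_lead_lag(pair: SpikeTrainPair) -> LeadLagResult:
    """Fractional lead/lag over the first ``N`` spikes; NaN if either
    train is empty."""
    N = pair.N
    if N == 0:
        return LeadLagResult(fraction=float("nan"))
    td = pair.discrete[N - 1]
    tp = pair.precise[N - 1]
    if td <= 0:
        raise InvalidParameterError("t_discrete(N) must be positive")
    return LeadLagResult(fraction=(td - tp) / td)


def warped_rmse(pair: SpikeTrainPair) -> RMSEResult:
    """RMSE of spike times after removing the average lead or lag.

    The discrete times are scaled by ``t_precise(N)/t_discrete(N)`` so
    the ``N``-th spikes coincide; the residual of the last spike is
    exactly zero by construction.
    """
    N = pair.N
    if N == 0:
        return RMSEResult(rmse=float("nan"), warp_factor=float("nan"))
    td = pair.discrete[:N]
    tp = pair.precise[:N]
    if td[-1] <= 0:
        raise InvalidParameterError("t_discrete(N) must be positive")
    warp = tp[-1] / td[-1]
    resid = td * warp - tp
    return RMSEResult(rmse=float(np.sqrt(np.mean(resid ** 2))),
                      warp_factor=float(warp))


def compare_single(precise_spikes, discrete_spikes, h: float,
                   precise_trace=None, discrete_trace=None,
                   window: float = 5.0) -> dict:
    """Full single-neuron comparison report as a JSON-serializable dict."""
    pair = SpikeTrainPair.make(precise_spikes, discrete_spikes)
    cch = cross_correlation_histogram(pair, h, window=window)
    report = {
        "n_spikes_precise": int(len(pair.precise)),
        "n_spikes_discrete": int(len(pair.discrete)),
        "cch": {
            "edges_ms": cch.edges.tolist(),
            "counts": cch.counts.tolist(),
            "window_ms": cch.window,
        },
        "lead_lag_fraction": accumulated_lead_lag(pair).fraction,
    }
    r = warped_rmse(pair)
    report["rmse_ms"] = r.rmse
    report["warp_factor"] = r.warp_factor
    if precise_trace is not None and discrete_trace is not None:
        report["pearson_r"] = membrane_correlation(precise_trace,
                                                   discrete_trace)
    return report
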