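"""Raw-data and fit quality metrics for sFCS correlation curves.

Two complementary metrics:

* ``nrmsd`` — normalised residual metric of a fit: the root of the *summed*
  squared residuals over the fitted lag range, divided by the fitted
  amplitude G(0).  Note the sum (not mean) under the root; a mean-normalised
  variant is available via ``per_lag=True``.
* ``snr`` — chunked signal-to-noise of a correlation curve: the trace is cut
  into equal-length chunks, each chunk is correlated, and the per-lag
  variance across chunks over the first 9 lags gauges the noise of the
  full-trace curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .correlate import CorrelationCurve, IntensityTrace, autocorrelate

__all__ = ["QualityMetrics", "nrmsd", "snr", "snr_from_curves"]


@dataclass(frozen=True)
class QualityMetrics:
    nrmsd: float
    snr: float
    n_lags_used: int
    n_chunks: int


def nrmsd(curve: CorrelationCurve, fit, per_lag: bool = False) -> float:
    """Normalised residual metric of an FCS fit.

    sqrt(sum_i (G(tau_i) - fit(tau_i))^2) / G(0)_fit over all lags in the
    fit range.  ``per_lag=True`` divides the sum by the number of lags first
    (a true root-mean-square), for comparisons across different lag grids.
    """
    g0 = fit.g0
    if g0 <= 0:
        raise ValueError("fitted amplitude must be positive")
    res = np.asarray(fit.residuals, dtype=float)
    ss = float(np.sum(res**2))
    if per_lag:
        ss /= res.size
    return float(np.sqrt(ss) / g0)


def snr(
    trace: IntensityTrace,
    n_lags: int = 9,
    n_chunks: int = 3,
    scheme: str = "multi_tau",
) -> float:
    """Chunked signal-to-noise ratio of a correlation curve.

    The trace is split into ``n_chunks`` equal-length chunks (samples beyond
    an integer multiple are dropped); each chunk is autocorrelated and the
    sample variance across chunks is taken per lag over the first ``n_lags``
    lags.  SNR = (1/N_k) * sum_i G_full(tau_i) / sqrt(var_i), with G_full
    the full-trace correlation.  Zero variance at any lag makes the ratio
    undefined; NaN is returned with a warning.
    """
    if n_chunks < 2:
        raise ValueError("need at least 2 chunks to estimate a variance")
    x = trace.counts
    chunk_len = x.size // n_chunks
    if chunk_len < 2 * n_lags:
        raise ValueError(
            f"chunks of {chunk_len} samples are too short for {n_lags} lags"
        )
    full = autocorrelate(trace, scheme=scheme)
    if full.g.size < n_lags:
        raise ValueError("full-trace curve has fewer lags than requested")

    chunk_g = np.empty((n_chunks, n_lags))
    for c in range(n_chunks):
        seg = IntensityTrace(
            x[c * chunk_len : (c + 1) * chunk_len],
            trace.sampling_interval_s,
            trace.pixel_index,
        )
        gc = autocorrelate(seg, scheme=scheme).g
        chunk_g[c] = gc[:n_lags]

    return snr_from_curves(full.g[:n_lags], chunk_g)


def snr_from_curves(g_full: np.ndarray, chunk_g: np.ndarray) -> float:
    """SNR from a full-trace curve and a (n_chunks, n_lags) chunk-curve matrix.

    Per-lag noise is the sample variance (ddof=1) across chunks; the signal
    is the full-trace correlation at the same lag.
    """
    g_full = np.asarray(g_full, dtype=float)
    chunk_g = np.asarray(chunk_g, dtype=float)
    if chunk_g.ndim != 2 or chunk_g.shape[1] != g_full.size:
        raise ValueError("chunk_g must be (n_chunks, n_lags) matching g_full")
    if chunk_g.shape[0] < 2:
        raise ValueError("need at least 2 chunks")
    var = chunk_g.var(axis=0, ddof=1)
    if np.any(var == 0.0):
        warnings.warn(
            "snr: zero variance across chunks at some lag; SNR undefined",
            stacklevel=2,
        )
        return float("nan")
    return float(np.mean(g_full / np.sqrt(var)))
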