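"""Similarity metrics and summaries for waveforms and weighting vectors.

Implements the shift-compensated cross-correlation (with the time shift in
% gait cycle), RMSE, per-component weighting similarity, and median/IQR/
histogram summaries used to report performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


__all__ = [
    "SummaryStats",
    "xcorr_with_shift",
    "rmse",
    "weighting_similarity",
    "summarize",
]


@dataclass
class SummaryStats:
    median: float
    iqr: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    n: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("correlation undefined for a constant signal")
    return float(np.dot(a, b) / denom)


def xcorr_with_shift(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Shift-compensated cross-correlation between two cycle waveforms.

    Searches all circular shifts s of ``b`` for the one maximizing the
    Pearson correlation with ``a``, and returns ``(r at best shift,
    shift as % of the cycle)``. Positive shift means ``b`` lags ``a``.
    Shifts are scanned from -n/2 to n/2-1 samples; ties resolve to the
    first (most negative) maximizing shift.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    n = len(a)
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom == 0:
        raise ValueError("correlation undefined for a constant signal")
    # circular cross-correlation via FFT: corr[k] = sum_t ac[t] * bc[t - k];
    # aligning b back by s compares ac[t] with bc[t + s], i.e. corr[-s]
    corr = np.fft.irfft(np.fft.rfft(ac) * np.conj(np.fft.rfft(bc)), n=n)
    shifts = np.arange(-(n // 2), n - n // 2)
    r_all = corr[(-shifts) % n] / denom
    best = int(np.argmax(r_all))
    shift_samples = int(shifts[best])
    shift_percent = shift_samples * 100.0 / n
    return float(r_all[best]), shift_percent


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean square error between two equal-length arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if a.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def weighting_similarity(
    west: np.ndarray, wexp: np.ndarray
) -> list[tuple[float, float]]:
    """Per-component (Pearson r, RMSE) between two muscles x k matrices.

    Each component's weightings are compared as plain vectors over muscles.
    Components with a constant vector in either matrix get ``r = nan``
    (flagged) but still report RMSE.
    """
    west = np.asarray(west, dtype=float)
    wexp = np.asarray(wexp, dtype=float)
    if west.shape != wexp.shape:
        raise ValueError("shape mismatch")
    out = []
    for c in range(west.shape[1]):
        e = rmse(west[:, c], wexp[:, c])
        try:
            r = _pearson(west[:, c], wexp[:, c])
        except ValueError:
            r = float("nan")
        out.append((r, e))
    return out


def summarize(values, bins: int = 20,
              hist_range: tuple[float, float] | None = None) -> SummaryStats:
    """Median, interquartile range and fixed-bin histogram of a collection.

    Quartiles use linear interpolation.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    counts, edges = np.histogram(values, bins=bins, range=hist_range)
    return SummaryStats(
        median=float(med), iqr=float(q3 - q1),
        hist_counts=counts, hist_edges=edges, n=values.size,
    )
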