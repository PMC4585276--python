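"""EMG envelope extraction, amplitude normalization, gait segmentation
and 200-point time normalization.

The processing chain turns raw multi-channel surface EMG plus a heel-marker
trajectory into amplitude-normalized, gait-segmented excitation matrices
(muscles x 200) suitable for non-negative factorization:

1. :func:`compute_envelope` -- zero-phase 30-300 Hz band-pass, full-wave
   rectification, zero-phase 3 Hz low-pass.
2. :func:`normalize_amplitude` -- per-muscle division by the peak of a
   50 ms moving average taken across all trials.
3. :func:`detect_heel_strikes` -- marker-based gait event detection.
4. :func:`segment_and_time_normalize` -- cubic-spline resampling of each
   gait cycle onto 200 equidistant points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

__all__ = [
    "EnvelopeRecording",
    "GaitCycleMatrix",
    "DEFAULT_MUSCLES",
    "compute_envelope",
    "normalize_amplitude",
    "detect_heel_strikes",
    "segment_and_time_normalize",
]

logger = logging.getLogger(__name__)

#: Canonical right-leg muscle set and ordering used throughout.
DEFAULT_MUSCLES = [
    "TA", "Sol", "Per", "VastLat", "VastMed", "RFem", "Sar", "Add",
    "GlutMed", "TFL", "GastLat", "GastMed", "BFem", "Sem", "GlutMax",
]

N_POINTS = 200  # samples per time-normalized gait cycle


@dataclass
class EnvelopeRecording:
    """One trial of multi-muscle signal with sampling rate and condition.

    ``samples`` is a ``muscles x time`` matrix; values are raw EMG before
    :func:`compute_envelope` and non-negative linear envelopes after.
    ``condition`` is ``(speed km/h, elevation %)``.
    """

    muscle_labels: list[str]
    sampling_rate: float
    samples: np.ndarray
    condition: tuple[float, float] = (3.0, 0.0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D muscles x time matrix")
        if self.samples.shape[0] != len(self.muscle_labels):
            raise ValueError(
                f"{len(self.muscle_labels)} labels but "
                f"{self.samples.shape[0]} signal rows"
            )

    @property
    def n_muscles(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class GaitCycleMatrix:
    """Time-normalized excitations of a single gait cycle.

    ``values`` is ``muscles x 200`` with entries in [0, 1].
    """

    values: np.ndarray
    cycle_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_POINTS:
            raise ValueError(f"values must have exactly {N_POINTS} columns")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")


def _zero_phase_filter(sos: np.ndarray, x: np.ndarray, fs: float,
                       pad_s: float = 1.0) -> np.ndarray:
    """Apply a zero-phase SOS filter with reflection padding.

    Pads ``pad_s`` seconds (capped at the signal length minus one) at both
    ends by reflection before ``sosfiltfilt`` to suppress edge transients,
    then trims back to the original length.
    """
    x = np.atleast_2d(x)
    n = x.shape[-1]
    pad = min(int(round(pad_s * fs)), n - 1)
    if pad > 0:
        x = np.concatenate(
            [x[..., pad:0:-1], x, x[..., -2:-pad - 2:-1]], axis=-1
        )
    y = signal.sosfiltfilt(sos, x, axis=-1)
    if pad > 0:
        y = y[..., pad:pad + n]
    return y


def compute_envelope(raw: EnvelopeRecording) -> EnvelopeRecording:
    """Compute linear envelopes from raw EMG.

    Band-pass filters 30-300 Hz (zero-phase, fourth-order Butterworth),
    full-wave rectifies, then low-pass filters at 3 Hz with the same filter
    type. Residual negative ringing from the low-pass stage is clipped to 0.
    """
    fs = raw.sampling_rate
    if fs < 1000:
        raise ValueError(f"sampling rate {fs} Hz too low (need >= 1000 Hz)")
    if not np.isfinite(raw.samples).all():
        raise ValueError("raw samples contain non-finite values")
    min_len = 10 * 4  # 10 x filter order
    if raw.n_samples <= min_len:
        raise ValueError(
            f"signal of {raw.n_samples} samples is too short to filter "
            f"(need > {min_len})"
        )
    sos_bp = signal.butter(4, [30.0, 300.0], btype="bandpass", fs=fs,
                           output="sos")
    sos_lp = signal.butter(4, 3.0, btype="lowpass", fs=fs, output="sos")
    bandpassed = _zero_phase_filter(sos_bp, raw.samples, fs)
    rectified = np.abs(bandpassed)
    envelope = _zero_phase_filter(sos_lp, rectified, fs)
    np.clip(envelope, 0.0, None, out=envelope)
    return replace(raw, samples=envelope)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (brute-force-equivalent).

    At the edges the window shrinks to the available samples so no phantom
    zeros bias the mean.
    """
    n = x.shape[-1]
    if window <= 1:
        return x.astype(float, copy=True)
    kernel = np.ones(window)
    sums = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same"), -1, x
    )
    counts = np.convolve(np.ones(n), kernel, mode="same")
    return sums / counts


def normalize_amplitude(
    envelopes: list[EnvelopeRecording], window_ms: float = 50.0
) -> tuple[list[EnvelopeRecording], np.ndarray]:
    """Normalize each muscle by its cross-trial smoothed peak.

    The peak is the maximum of a centered ``window_ms`` moving average of
    the linear envelope, taken across *all* trials. Normalized values are
    clipped to [0, 1]; the smoothing can otherwise let isolated samples
    slightly exceed 1.

    Returns the normalized trials and the per-muscle peak vector. Muscles
    with an all-zero envelope across every trial keep their raw values and
    get a peak of ``nan`` (logged).
    """
    if not envelopes:
        raise ValueError("need at least one trial")
    first = envelopes[0]
    for tr in envelopes[1:]:
        if tr.muscle_labels != first.muscle_labels:
            raise ValueError("trials disagree on muscle order")
        if tr.sampling_rate != first.sampling_rate:
            raise ValueError("trials disagree on sampling rate")
    window = max(1, int(round(window_ms / 1000.0 * first.sampling_rate)))
    peaks = np.full(first.n_muscles, -np.inf)
    for tr in envelopes:
        smoothed = _moving_average(tr.samples, window)
        peaks = np.maximum(peaks, smoothed.max(axis=1))
    degenerate = peaks <= 0
    if degenerate.any():
        bad = [first.muscle_labels[i] for i in np.flatnonzero(degenerate)]
        logger.warning("all-zero channels left unnormalized: %s", bad)
    divisor = np.where(degenerate, 1.0, peaks)
    out = []
    for tr in envelopes:
        normalized = np.clip(tr.samples / divisor[:, None], 0.0, 1.0)
        out.append(replace(tr, samples=normalized))
    peaks = np.where(degenerate, np.nan, peaks)
    return out, peaks


def detect_heel_strikes(
    marker: np.ndarray,
    sampling_rate: float,
    anterior_axis: int | str = "x",
    prominence_fraction: float = 0.3,
    min_stride_s: float = 0.4,
) -> np.ndarray:
    """Detect heel-strike times from a heel-marker trajectory.

    ``marker`` is ``time x 3`` (columns x, y, z). On a treadmill the heel
    reaches its most anterior position at initial contact, so heel strike
    is taken as a local maximum of the 8 Hz low-pass-filtered anterior
    coordinate with prominence at least ``prominence_fraction`` of the
    coordinate's peak-to-peak range and separation >= ``min_stride_s``.

    Returns strictly increasing event times in seconds.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.ndim != 2 or marker.shape[1] != 3:
        raise ValueError("marker must be a time x 3 array")
    if isinstance(anterior_axis, str):
        try:
            anterior_axis = "xyz".index(anterior_axis.lower())
        except ValueError:
            raise ValueError(
                f"anterior axis {anterior_axis!r} not one of x, y, z"
            ) from None
    coord = marker[:, anterior_axis]
    sos = signal.butter(4, 8.0, btype="lowpass", fs=sampling_rate,
                        output="sos")
    smoothed = _zero_phase_filter(sos, coord, sampling_rate)[0]
    ptp = float(np.ptp(smoothed))
    if ptp <= 1e-10 * max(1.0, float(np.abs(smoothed).max())):
        raise ValueError("constant marker trajectory: no gait events")
    peaks, _ = signal.find_peaks(
        smoothed,
        prominence=prominence_fraction * ptp,
        distance=max(1, int(round(min_stride_s * sampling_rate))),
    )
    if len(peaks) < 2:
        raise ValueError(
            f"only {len(peaks)} heel strikes detected; need >= 2"
        )
    return peaks / sampling_rate


def segment_and_time_normalize(
    trial: EnvelopeRecording,
    events: np.ndarray,
    cycle_gate_s: tuple[float, float] = (0.4, 3.0),
    clip: bool = True,
) -> list[GaitCycleMatrix]:
    """Cut a trial into gait cycles and resample each onto 200 points.

    Each inter-event interval ``[e_i, e_{i+1})`` is resampled with a cubic
    spline onto 200 equidistant points. Cycles whose duration falls outside
    ``cycle_gate_s`` are dropped and logged. Values are clipped to [0, 1]
    when ``clip`` is set (spline overshoot is possible).
    """
    events = np.asarray(events, dtype=float)
    if len(events) < 2:
        raise ValueError("need at least two gait events")
    if np.any(np.diff(events) <= 0):
        raise ValueError("events must be strictly increasing")
    if events[0] < 0 or events[-1] > trial.duration:
        raise ValueError("events fall outside the trial time span")
    t = trial.times()
    splines = [CubicSpline(t, row) for row in trial.samples]
    lo, hi = cycle_gate_s
    cycles = []
    for i, (start, stop) in enumerate(zip(events[:-1], events[1:])):
        duration = stop - start
        if not (lo <= duration <= hi):
            logger.info(
                "dropping cycle %d: duration %.3f s outside gate [%s, %s]",
                i, duration, lo, hi,
            )
            continue
        grid = start + duration * np.arange(N_POINTS) / N_POINTS
        values = np.vstack([sp(grid) for sp in splines])
        if clip:
            values = np.clip(values, 0.0, 1.0)
        cycles.append(GaitCycleMatrix(values=values, cycle_index=len(cycles)))
    return cycles
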