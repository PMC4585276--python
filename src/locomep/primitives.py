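"""Gaussian excitation primitives (XPs).

An XP is a Gaussian parameterization of a component's time-normalized
non-negative factor as a function of % gait cycle:

    xp(t) = exp(-(t - mu)^2 / (2 sigma^2))

An optional second lobe (mu2, sigma2, amp2) handles bimodal components;
the summed profile is renormalized to peak at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import least_squares

from .emg_processing import N_POINTS

__all__ = [
    "XPComponent",
    "XPParamSet",
    "cycle_grid",
    "evaluate_xp",
    "fit_xp",
    "build_generic_xp",
    "circular_mean",
]

logger = logging.getLogger(__name__)

CYCLE_PERIOD = 100.0  # gait cycle expressed in percent


@dataclass
class XPComponent:
    """Parameters of one excitation primitive.

    ``mu`` is the peak location in % gait cycle, ``sigma`` the width.
    ``lobe2`` is an optional ``(mu2, sigma2, amp2)`` second Gaussian with
    relative amplitude ``amp2`` in (0, 1].
    """

    mu: float
    sigma: float
    lobe2: tuple[float, float, float] | None = None
    fit_rms: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lobe2 is not None:
            mu2, sigma2, amp2 = self.lobe2
            if sigma2 <= 0 or not (0 < amp2 <= 1):
                raise ValueError("invalid second lobe parameters")

    @property
    def n_lobes(self) -> int:
        return 1 if self.lobe2 is None else 2


@dataclass
class XPParamSet:
    """Ordered collection of XP components (one per motor component)."""

    components: list[XPComponent]

    def __len__(self) -> int:
        return len(self.components)

    def profile_matrix(self, t_grid: np.ndarray | None = None) -> np.ndarray:
        """k x len(t_grid) matrix of evaluated primitives."""
        if t_grid is None:
            t_grid = cycle_grid()
        return np.vstack([evaluate_xp(c, t_grid) for c in self.components])


def cycle_grid(n: int = N_POINTS) -> np.ndarray:
    """The canonical % gait-cycle grid: 0, 0.5, ..., 99.5 for n=200."""
    return np.arange(n) * (CYCLE_PERIOD / n)


def _raw_profile(comp: XPComponent, t: np.ndarray) -> np.ndarray:
    y = np.exp(-((t - comp.mu) ** 2) / (2.0 * comp.sigma ** 2))
    if comp.lobe2 is not None:
        mu2, sigma2, amp2 = comp.lobe2
        y = y + amp2 * np.exp(-((t - mu2) ** 2) / (2.0 * sigma2 ** 2))
    return y


def evaluate_xp(comp: XPComponent, t_grid: np.ndarray) -> np.ndarray:
    """Evaluate one primitive on a % gait-cycle grid, renormalized to max 1.

    Uses plain (non-circular) distance. For a single lobe the analytic
    maximum is 1 at mu; for two lobes the peak of the summed profile is
    located on a fine internal grid before renormalizing.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    y = _raw_profile(comp, t_grid)
    if comp.lobe2 is None:
        return y
    fine = np.linspace(0.0, CYCLE_PERIOD, 20001)
    peak = _raw_profile(comp, fine).max()
    return y / peak


def fit_xp(
    factor: np.ndarray,
    t_grid: np.ndarray | None = None,
    bimodal_gate: float = 0.08,
    prominence: float = 0.3,
) -> XPComponent:
    """Least-squares Gaussian fit of a normalized factor profile.

    Starts from (argmax, half-width at half maximum). If the single-lobe
    residual RMS exceeds ``bimodal_gate`` and a second local maximum with
    at least ``prominence`` exists, a two-lobe fit is attempted and kept if
    it improves the residual. Bounds: mu in [0, 100), sigma in [1, 50].
    """
    factor = np.asarray(factor, dtype=float)
    if t_grid is None:
        t_grid = cycle_grid(len(factor))
    if np.any(factor < 0):
        raise ValueError("factor must be non-negative")

    single = _fit_single(factor, t_grid)
    if single.fit_rms <= bimodal_gate:
        return single
    # peaks near the cycle boundary keep their full prominence only when
    # the periodic continuation is taken into account: detect on a tiled
    # copy and keep the peaks of the middle period
    n = len(factor)
    tiled_peaks, tiled_props = signal.find_peaks(np.tile(factor, 3),
                                                 prominence=prominence)
    keep = (tiled_peaks >= n) & (tiled_peaks < 2 * n)
    peaks = tiled_peaks[keep] - n
    props = {"prominences": tiled_props["prominences"][keep]}
    if len(peaks) < 2:
        return single
    double = _fit_double(factor, t_grid, peaks, props)
    if double is not None and double.fit_rms < single.fit_rms:
        return double
    return single


def _init_width(factor: np.ndarray, t_grid: np.ndarray, i_peak: int) -> float:
    """Half-width at half maximum around a peak, converted to sigma."""
    half = factor[i_peak] / 2.0
    right = i_peak
    while right < len(factor) - 1 and factor[right] > half:
        right += 1
    left = i_peak
    while left > 0 and factor[left] > half:
        left -= 1
    hwhm = max((t_grid[right] - t_grid[left]) / 2.0, t_grid[1] - t_grid[0])
    return float(np.clip(hwhm / np.sqrt(2.0 * np.log(2.0)), 1.0, 50.0))


def _fit_single(factor: np.ndarray, t_grid: np.ndarray) -> XPComponent:
    i_peak = int(np.argmax(factor))
    x0 = [float(t_grid[i_peak]), _init_width(factor, t_grid, i_peak)]

    def residual(p):
        mu, sigma = p
        return np.exp(-((t_grid - mu) ** 2) / (2 * sigma ** 2)) - factor

    try:
        res = least_squares(residual, x0, bounds=([0.0, 1.0], [100.0, 50.0]))
        mu, sigma = res.x
        rms = float(np.sqrt(np.mean(res.fun ** 2)))
        return XPComponent(mu=float(mu) % CYCLE_PERIOD, sigma=float(sigma),
                           fit_rms=rms, converged=bool(res.success))
    except Exception:  # pragma: no cover - defensive
        logger.warning("single-lobe fit failed; returning initialization")
        rms = float(np.sqrt(np.mean(residual(x0) ** 2)))
        return XPComponent(mu=x0[0], sigma=x0[1], fit_rms=rms,
                           converged=False)


def _fit_double(factor, t_grid, peaks, props) -> XPComponent | None:
    # two most prominent local maxima seed the two lobes
    top = peaks[np.argsort(props["prominences"])[-2:]]
    i1, i2 = sorted(top, key=lambda i: -factor[i])
    x0 = [
        float(t_grid[i1]), _init_width(factor, t_grid, i1),
        float(t_grid[i2]), _init_width(factor, t_grid, i2),
        float(np.clip(factor[i2] / max(factor[i1], 1e-9), 0.05, 1.0)),
    ]

    def residual(p):
        mu1, s1, mu2, s2, a2 = p
        y = (np.exp(-((t_grid - mu1) ** 2) / (2 * s1 ** 2))
             + a2 * np.exp(-((t_grid - mu2) ** 2) / (2 * s2 ** 2)))
        return y - factor

    try:
        res = least_squares(
            residual, x0,
            bounds=([0.0, 1.0, 0.0, 1.0, 0.01], [100.0, 50.0, 100.0, 50.0, 1.0]),
        )
    except Exception:  # pragma: no cover - defensive
        return None
    mu1, s1, mu2, s2, a2 = res.x
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    return XPComponent(
        mu=float(mu1) % CYCLE_PERIOD, sigma=float(s1),
        lobe2=(float(mu2) % CYCLE_PERIOD, float(s2), float(a2)),
        fit_rms=rms, converged=bool(res.success),
    )


def circular_mean(values: np.ndarray, period: float = CYCLE_PERIOD) -> float:
    """Circular mean of periodic quantities (e.g., peak % gait cycle)."""
    angles = np.asarray(values, dtype=float) * (2.0 * np.pi / period)
    mean_angle = np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles)))
    return float((mean_angle * period / (2.0 * np.pi)) % period)


def build_generic_xp(fits: list[XPParamSet]) -> XPParamSet:
    """Average per-component fits across subjects and conditions.

    Peak locations are combined with a circular mean (period 100% gait
    cycle); widths and amplitudes with ordinary means. When fits disagree
    on the lobe count of a component, the majority wins and only
    majority-conforming fits enter the average.
    """
    if not fits:
        raise ValueError("need at least one fit")
    k = len(fits[0])
    if any(len(f) != k for f in fits):
        raise ValueError("all fits must share the component count")
    generic = []
    for c in range(k):
        comps = [f.components[c] for f in fits]
        two_lobed = sum(comp.n_lobes == 2 for comp in comps)
        want_lobes = 2 if two_lobed > len(comps) / 2 else 1
        conforming = [comp for comp in comps if comp.n_lobes == want_lobes]
        if len(conforming) < len(comps):
            logger.info(
                "component %d: %d/%d fits disagree on lobe count; "
                "averaging the majority", c, len(comps) - len(conforming),
                len(comps),
            )
        mu = circular_mean([comp.mu for comp in conforming])
        sigma = float(np.mean([comp.sigma for comp in conforming]))
        lobe2 = None
        if want_lobes == 2:
            lobe2 = (
                circular_mean([comp.lobe2[0] for comp in conforming]),
                float(np.mean([comp.lobe2[1] for comp in conforming])),
                float(np.mean([comp.lobe2[2] for comp in conforming])),
            )
        generic.append(XPComponent(mu=mu, sigma=sigma, lobe2=lobe2))
    return XPParamSet(components=generic)
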