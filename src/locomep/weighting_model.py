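"""Additive speed/elevation regression on muscle weightings.

The weighting of muscle m in component c at speed v (km/h) and elevation
theta (%) is modeled as

    W[m,c](v, theta) = dv(v)[m,c] + dtheta(theta)[m,c] + W_BL[m,c]

where W_BL are the weightings at the baseline condition (3 km/h, 0%) and
the increments dv, dtheta are per-(m, c) polynomials through the origin
(degree 1 or 2, chosen by adjusted R^2) in (v - 3) and theta respectively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConditionKey",
    "WeightingModel",
    "BASELINE_SPEED",
    "BASELINE_ELEVATION",
    "build_delta_targets",
    "fit_regression",
    "predict_weightings",
]

logger = logging.getLogger(__name__)

BASELINE_SPEED = 3.0       # km/h
BASELINE_ELEVATION = 0.0   # %
SPEED_RANGE = (1.0, 5.0)
ELEVATION_RANGE = (-20.0, 20.0)


@dataclass(frozen=True, order=True)
class ConditionKey:
    """A locomotion condition: speed in km/h and ground elevation in %."""

    speed: float
    elevation: float

    @property
    def is_baseline(self) -> bool:
        return (self.speed == BASELINE_SPEED
                and self.elevation == BASELINE_ELEVATION)

    def in_trained_hull(self) -> bool:
        return (SPEED_RANGE[0] <= self.speed <= SPEED_RANGE[1]
                and ELEVATION_RANGE[0] <= self.elevation <= ELEVATION_RANGE[1])


@dataclass
class WeightingModel:
    """Fitted regression: baseline weightings plus per-axis increments.

    ``speed_coeffs`` and ``elev_coeffs`` have shape ``muscles x k x 2``
    holding the linear and quadratic coefficients of the zero-intercept
    polynomial in ``(v - 3)`` and ``theta``; a zero quadratic coefficient
    means degree 1 was selected.
    """

    baseline: np.ndarray
    speed_coeffs: np.ndarray
    elev_coeffs: np.ndarray
    muscle_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.speed_coeffs = np.asarray(self.speed_coeffs, dtype=float)
        self.elev_coeffs = np.asarray(self.elev_coeffs, dtype=float)
        shape = self.baseline.shape + (2,)
        if self.speed_coeffs.shape != shape or self.elev_coeffs.shape != shape:
            raise ValueError("coefficient arrays must be muscles x k x 2")
        if np.any(self.baseline < 0):
            raise ValueError("baseline weightings must be non-negative")

    @property
    def rank(self) -> int:
        return self.baseline.shape[1]

    def speed_delta(self, speed: float) -> np.ndarray:
        x = speed - BASELINE_SPEED
        return self.speed_coeffs[..., 0] * x + self.speed_coeffs[..., 1] * x * x

    def elevation_delta(self, elevation: float) -> np.ndarray:
        x = elevation - BASELINE_ELEVATION
        return self.elev_coeffs[..., 0] * x + self.elev_coeffs[..., 1] * x * x


def build_delta_targets(
    weightings: dict[ConditionKey, np.ndarray],
) -> tuple[dict[float, np.ndarray], dict[float, np.ndarray]]:
    """Marginal baseline-relative weighting changes per speed and elevation.

    The speed-delta target at speed v is the mean over elevations theta of
    ``W(v, theta) - W(v_BL, theta)``; the elevation-delta target at theta
    is the mean over speeds of ``W(v, theta) - W(v, 0)``. Missing grid
    cells are skipped (the mean runs over the available cells).
    """
    conditions = list(weightings)
    speeds = sorted({c.speed for c in conditions})
    elevations = sorted({c.elevation for c in conditions})
    if BASELINE_SPEED not in speeds or BASELINE_ELEVATION not in elevations:
        raise ValueError("baseline condition missing from the grid")

    def cell(v, th):
        return weightings.get(ConditionKey(v, th))

    speed_targets: dict[float, np.ndarray] = {}
    for v in speeds:
        diffs = [
            cell(v, th) - cell(BASELINE_SPEED, th)
            for th in elevations
            if cell(v, th) is not None and cell(BASELINE_SPEED, th) is not None
        ]
        if diffs:
            speed_targets[v] = np.mean(diffs, axis=0)
    elev_targets: dict[float, np.ndarray] = {}
    for th in elevations:
        diffs = [
            cell(v, th) - cell(v, BASELINE_ELEVATION)
            for v in speeds
            if cell(v, th) is not None
            and cell(v, BASELINE_ELEVATION) is not None
        ]
        if diffs:
            elev_targets[th] = np.mean(diffs, axis=0)
    return speed_targets, elev_targets


def _fit_origin_poly(x: np.ndarray, Y: np.ndarray, degree_max: int) -> np.ndarray:
    """Per-cell zero-intercept polynomial fit, degree chosen by adjusted R^2.

    ``x`` has length p (grid levels, baseline included as an exact zero);
    ``Y`` is ``p x muscles x k``. Returns ``muscles x k x 2`` coefficients.
    """
    n = len(x)
    degree_max = min(degree_max, max(n - 1, 1))
    flat = Y.reshape(n, -1)
    tss = np.sum(flat ** 2, axis=0)  # uncentered: model is through origin
    best_coeffs = np.zeros((2, flat.shape[1]))
    best_adj = np.full(flat.shape[1], -np.inf)
    for deg in range(1, degree_max + 1):
        design = np.vander(x, deg + 1, increasing=True)[:, 1:]  # drop const
        if np.linalg.matrix_rank(design) < deg:
            continue  # rank-deficient (e.g., single off-baseline level)
        coeffs, _, _, _ = np.linalg.lstsq(design, flat, rcond=None)
        resid = flat - design @ coeffs
        sse = np.sum(resid ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(tss > 0, 1.0 - sse / tss, 1.0)
            adj = np.where(
                n > deg, 1.0 - (1.0 - r2) * n / max(n - deg, 1), -np.inf
            )
        better = adj > best_adj + 1e-12
        best_adj = np.where(better, adj, best_adj)
        padded = np.zeros((2, flat.shape[1]))
        padded[:deg] = coeffs
        best_coeffs = np.where(better[None, :], padded, best_coeffs)
    out = best_coeffs.T.reshape(Y.shape[1], Y.shape[2], 2)
    # exact-zero targets get exact-zero coefficients
    out[(tss == 0).reshape(Y.shape[1], Y.shape[2])] = 0.0
    return out


def fit_regression(
    speed_targets: dict[float, np.ndarray],
    elev_targets: dict[float, np.ndarray],
    baseline: np.ndarray,
    degree_max: int = 2,
    muscle_labels: list[str] | None = None,
) -> WeightingModel:
    """Fit the per-(muscle, component) increment polynomials.

    Requires at least two distinct speeds and elevations. Each axis is fit
    independently by least squares through the origin on the delta targets
    from :func:`build_delta_targets`.
    """
    if len(speed_targets) < 2 or len(elev_targets) < 2:
        raise ValueError("need >= 2 distinct speeds and elevations")
    baseline = np.asarray(baseline, dtype=float)

    speeds = np.array(sorted(speed_targets))
    Ys = np.stack([speed_targets[v] for v in speeds])
    speed_coeffs = _fit_origin_poly(speeds - BASELINE_SPEED, Ys, degree_max)

    elevs = np.array(sorted(elev_targets))
    Ye = np.stack([elev_targets[th] for th in elevs])
    elev_coeffs = _fit_origin_poly(elevs - BASELINE_ELEVATION, Ye, degree_max)

    return WeightingModel(
        baseline=baseline,
        speed_coeffs=speed_coeffs,
        elev_coeffs=elev_coeffs,
        muscle_labels=muscle_labels,
    )


def predict_weightings(
    model: WeightingModel,
    cond: ConditionKey,
    baseline_override: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate the additive model at a condition.

    At the baseline condition both increments are structurally zero, so the
    baseline weightings are returned bit-exactly. Negative predictions are
    clipped to 0 (logged). Conditions outside the trained speed/elevation
    hull are predicted with an extrapolation warning.
    """
    baseline = model.baseline
    if baseline_override is not None:
        baseline = np.asarray(baseline_override, dtype=float)
        if baseline.shape != model.baseline.shape:
            raise ValueError("baseline_override shape mismatch")
    if not cond.in_trained_hull():
        logger.warning("condition %s outside trained hull; extrapolating",
                       cond)
    if cond.is_baseline:
        return baseline.copy()
    W = model.speed_delta(cond.speed) + model.elevation_delta(cond.elevation)
    W = W + baseline
    n_clipped = int(np.sum(W < 0))
    if n_clipped:
        logger.info("clipped %d negative weighting predictions at %s",
                    n_clipped, cond)
    return np.clip(W, 0.0, None)
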