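"""Motor-component extraction by non-negative matrix factorization.

A motor component is a pair of a non-negative temporal factor (a row of H)
and the associated per-muscle weightings (a column of W), so that the
muscles x samples excitation matrix X is approximated by W @ H.

The extraction protocol is multiplicative-update NNMF restarted from many
random initializations, keeping the solution with the highest VAF, with the
rank increased incrementally until VAF reaches a threshold (default 85%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .emg_processing import N_POINTS

__all__ = [
    "MotorComponentSet",
    "compute_vaf",
    "nnmf",
    "nnmf_best_of_restarts",
    "select_dimensionality",
    "normalize_and_scale",
    "match_components_by_peak",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class MotorComponentSet:
    """Output of one subject/condition factorization.

    ``factors`` is the raw ``k x n`` factor matrix over concatenated
    cycles; ``weightings`` is ``muscles x k``. After
    :func:`normalize_and_scale`, ``factors_avg`` holds the cycle-averaged,
    max-normalized ``k x 200`` factors and ``weightings`` carries the
    compensating scale so that ``weightings @ factors_avg`` equals the
    product of the unscaled quantities.
    """

    rank: int
    factors: np.ndarray
    weightings: np.ndarray
    vaf: float
    factors_avg: np.ndarray | None = None
    component_order: np.ndarray | None = None
    muscle_labels: list[str] | None = None
    converged: bool = True
    threshold_reached: bool = True
    degenerate: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        self.weightings = np.asarray(self.weightings, dtype=float)
        if self.factors.shape[0] != self.rank:
            raise ValueError("factors row count disagrees with rank")
        if self.weightings.shape[1] != self.rank:
            raise ValueError("weightings column count disagrees with rank")

    @property
    def n_muscles(self) -> int:
        return self.weightings.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.weightings @ self.factors


def compute_vaf(X: np.ndarray, Xhat: np.ndarray) -> float:
    """Variance accounted for: ``1 - SSE / TSS`` with uncentered TSS.

    SSE is the sum of squared differences and TSS the total sum of squares
    of ``X`` (sum of squared entries, no mean removal). May be negative for
    reconstructions worse than the zero matrix.
    """
    X = np.asarray(X, dtype=float)
    Xhat = np.asarray(Xhat, dtype=float)
    if X.shape != Xhat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xhat.shape}")
    tss = float(np.sum(X * X))
    if tss == 0.0:
        raise ValueError("VAF undefined for an all-zero matrix")
    sse = float(np.sum((X - Xhat) ** 2))
    return 1.0 - sse / tss


def nnmf(
    X: np.ndarray,
    W0: np.ndarray,
    H0: np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Lee-Seung multiplicative updates minimizing ||X - W H||_F^2.

    Runs from the given initialization until the relative change of the
    reconstruction error drops below ``tol`` (checked every 10 iterations)
    or ``max_iter`` is reached. Returns ``(W, H, converged)``.
    """
    X = np.asarray(X, dtype=float)
    W = np.array(W0, dtype=float)
    H = np.array(H0, dtype=float)
    err_prev = np.inf
    converged = False
    for it in range(1, max_iter + 1):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        if it % 10 == 0 or it == max_iter:
            err = float(np.linalg.norm(X - W @ H))
            if err_prev < np.inf and abs(err_prev - err) <= tol * max(err_prev, _EPS):
                converged = True
                break
            err_prev = err
    return W, H, converged


def _restart_rng(seed: int, k: int, restart: int) -> np.random.Generator:
    """Counter-based substream: independent of call order and restart count."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(k, restart))
    )


def nnmf_best_of_restarts(
    X: np.ndarray,
    k: int,
    restarts: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> MotorComponentSet:
    """Best-of-``restarts`` NNMF at a fixed rank ``k``.

    Each restart draws W and H entries from Uniform(0.1, 1) using a
    counter-based substream of ``seed``, so results are deterministic for a
    given seed regardless of execution order. The factorization with the
    highest VAF wins.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    m, n = X.shape
    if not 1 <= k <= m:
        raise ValueError(f"rank {k} outside [1, {m}]")
    best: MotorComponentSet | None = None
    any_nonconverged = False
    for r in range(restarts):
        rng = _restart_rng(seed, k, r)
        W0 = rng.uniform(0.1, 1.0, size=(m, k))
        H0 = rng.uniform(0.1, 1.0, size=(k, n))
        W, H, conv = nnmf(X, W0, H0, max_iter=max_iter, tol=tol)
        any_nonconverged |= not conv
        vaf = compute_vaf(X, W @ H)
        if best is None or vaf > best.vaf:
            best = MotorComponentSet(
                rank=k, factors=H, weightings=W, vaf=vaf, converged=conv
            )
    if any_nonconverged:
        logger.warning(
            "NNMF (k=%d): some restarts hit max_iter=%d before tolerance",
            k, max_iter,
        )
    assert best is not None
    return best


def select_dimensionality(
    X: np.ndarray,
    vaf_threshold: float = 0.85,
    restarts: int = 50,
    seed: int = 0,
    max_rank: int | None = None,
    **nnmf_kwargs,
) -> MotorComponentSet:
    """Incrementally increase the rank until VAF reaches the threshold.

    Evaluates k = 1, 2, ... via :func:`nnmf_best_of_restarts` and returns
    the first factorization whose VAF >= ``vaf_threshold``. If even the
    full rank misses the threshold, that result is returned with
    ``threshold_reached=False`` and a warning.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[0]
    max_rank = m if max_rank is None else min(max_rank, m)
    cs = None
    for k in range(1, max_rank + 1):
        cs = nnmf_best_of_restarts(X, k, restarts=restarts, seed=seed,
                                   **nnmf_kwargs)
        if cs.vaf >= vaf_threshold:
            return cs
    logger.warning(
        "VAF threshold %.2f not reached at rank %d (VAF=%.3f)",
        vaf_threshold, max_rank, cs.vaf,
    )
    return replace(cs, threshold_reached=False)


def normalize_and_scale(cs: MotorComponentSet,
                        cycle_count: int) -> MotorComponentSet:
    """Average factors across cycles, normalize to max 1, rescale weightings.

    Each factor row (length ``200 * cycle_count``) is reshaped to
    ``cycles x 200`` and averaged over cycles. The averaged factor is
    divided by its maximum and the corresponding weighting column is
    multiplied by that maximum, so the product W @ H_avg is preserved
    exactly. Components whose averaged factor is identically zero are
    flagged degenerate and left unnormalized.
    """
    k, n = cs.factors.shape
    if n != N_POINTS * cycle_count:
        raise ValueError(
            f"factor length {n} is not 200 x cycle_count ({cycle_count})"
        )
    avg = cs.factors.reshape(k, cycle_count, N_POINTS).mean(axis=1)
    maxima = avg.max(axis=1)
    degenerate = [int(i) for i in np.flatnonzero(maxima <= 0)]
    if degenerate:
        logger.warning("degenerate (all-zero) components: %s", degenerate)
    scale = np.where(maxima > 0, maxima, 1.0)
    return replace(
        cs,
        factors_avg=avg / scale[:, None],
        weightings=cs.weightings * scale[None, :],
        degenerate=degenerate,
    )


def _circular_xcorr_max(a: np.ndarray, b: np.ndarray) -> float:
    """Maximum circular cross-correlation (Pearson) over all shifts."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    corr = np.fft.irfft(np.fft.rfft(a) * np.conj(np.fft.rfft(b)), n=len(a))
    return float(corr.max() / denom)


def match_components_by_peak(
    cs: MotorComponentSet,
    reference: MotorComponentSet | None = None,
) -> MotorComponentSet:
    """Order components by peak time, or align them to a reference set.

    Without a reference, components are sorted by the location of the
    maximum of their averaged normalized factor (ascending % gait cycle).
    With a reference, a greedy assignment maximizes summed circular
    cross-correlation against the reference factors; if two components
    claim the same reference slot the method falls back to peak-time order.
    The applied permutation is stored in ``component_order``.
    """
    if cs.factors_avg is None:
        raise ValueError("call normalize_and_scale before matching")
    peak_order = np.argsort(np.argmax(cs.factors_avg, axis=1), kind="stable")
    if reference is None:
        order = peak_order
    else:
        if reference.factors_avg is None or reference.rank != cs.rank:
            raise ValueError("reference must be normalized and of equal rank")
        k = cs.rank
        sim = np.empty((k, k))
        for i in range(k):
            for j in range(k):
                sim[i, j] = _circular_xcorr_max(
                    reference.factors_avg[i], cs.factors_avg[j]
                )
        order = np.full(k, -1)
        taken = set()
        # greedy: best remaining (reference, component) pair first
        for i, j in zip(*np.unravel_index(np.argsort(-sim, axis=None),
                                          sim.shape)):
            if order[i] == -1 and j not in taken:
                order[i] = j
                taken.add(j)
        if len(taken) != k:  # ambiguous assignment
            logger.warning("ambiguous component match; using peak-time order")
            order = peak_order
    order = np.asarray(order)
    return replace(
        cs,
        factors=cs.factors[order],
        factors_avg=cs.factors_avg[order],
        weightings=cs.weightings[:, order],
        component_order=order,
    )
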