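"""End-to-end predictive model: generic primitives + weighting regression.

Assembles the fitted excitation primitives and the speed/elevation
weighting regression into muscle excitation profile (MEP) prediction,

    mep[m](t) = sum_c W[m,c](speed, elevation, W_BL) * xp[c](t)

in two modes: subject-generic (SGM, group-average baseline weightings) and
subject-specific (SSM, individually measured baseline weightings).
:func:`run_scenario` replicates the two train/test protocols: scenario 1
trains on a 3 x 3 condition subset and tests on the 16 remaining
conditions, scenario 2 trains on the full 5 x 5 grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation, factorization
from .primitives import XPParamSet, build_generic_xp, cycle_grid, fit_xp
from .synthetic_data import SyntheticDataset
from .weighting_model import (
    BASELINE_ELEVATION,
    BASELINE_SPEED,
    ConditionKey,
    WeightingModel,
    build_delta_targets,
    fit_regression,
    predict_weightings,
)

__all__ = [
    "PredictionResult",
    "ScenarioResult",
    "FittedModel",
    "SCENARIO1_SPEEDS",
    "SCENARIO1_ELEVATIONS",
    "build_generic_baseline",
    "predict_mep",
    "extract_components",
    "fit_predictive_model",
    "run_scenario",
]

logger = logging.getLogger(__name__)

SCENARIO1_SPEEDS = (1.0, 3.0, 5.0)
SCENARIO1_ELEVATIONS = (-20.0, 0.0, 20.0)


@dataclass
class ScenarioResult:
    """Fitted model plus the three long-format evaluation tables.

    ``xp_table`` compares the generic primitives against the extracted
    factors per (group, mode-independent) test case; ``weighting_table``
    and ``mep_table`` compare predictions per mode against the selected
    reference.
    """

    model: "FittedModel"
    xp_table: pd.DataFrame
    weighting_table: pd.DataFrame
    mep_table: pd.DataFrame

    def __iter__(self):
        # backwards-friendly unpacking: model, weighting, mep
        return iter((self.model, self.weighting_table, self.mep_table))


@dataclass
class PredictionResult:
    condition: ConditionKey
    mode: str  # "sgm" | "ssm"
    weightings: np.ndarray
    mep: np.ndarray
    n_clipped: int = 0


@dataclass
class FittedModel:
    """Trained predictive model: primitives, regression, generic baseline."""

    xp_params: XPParamSet
    weighting_model: WeightingModel
    generic_baseline: np.ndarray
    muscle_labels: list[str]
    training_metadata: dict = field(default_factory=dict)

    @property
    def rank(self) -> int:
        return len(self.xp_params)


def build_generic_baseline(
    subject_baselines: list[np.ndarray],
) -> np.ndarray:
    """Element-wise mean of per-subject baseline weighting matrices."""
    if not subject_baselines:
        raise ValueError("need at least one subject baseline")
    shapes = {b.shape for b in map(np.asarray, subject_baselines)}
    if len(shapes) != 1:
        raise ValueError(f"mismatched baseline shapes/ranks: {shapes}")
    return np.mean(subject_baselines, axis=0)


def predict_mep(
    model: FittedModel,
    cond: ConditionKey,
    mode: str = "sgm",
    subject_baseline: np.ndarray | None = None,
) -> PredictionResult:
    """Predict the muscles x 200 excitation matrix at a condition.

    SGM uses the model's group-average baseline; SSM requires the
    subject's experimentally obtained baseline weightings.
    """
    mode = mode.lower()
    if mode not in ("sgm", "ssm"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "ssm":
        if subject_baseline is None:
            raise ValueError("SSM requires a subject baseline")
        baseline = np.asarray(subject_baseline, dtype=float)
    else:
        baseline = None
    W = predict_weightings(model.weighting_model, cond,
                           baseline_override=baseline)
    xp = model.xp_params.profile_matrix(cycle_grid())
    return PredictionResult(
        condition=cond, mode=mode, weightings=W, mep=W @ xp,
    )


def extract_components(
    dataset: SyntheticDataset,
    restarts: int = 50,
    vaf_threshold: float = 0.85,
    seed: int = 0,
    rank: int | None = None,
    max_rank: int | None = None,
    **nnmf_kwargs,
) -> dict[tuple[int, ConditionKey], factorization.MotorComponentSet]:
    """Descriptive analysis of every subject-condition cell.

    Concatenates the cell's cycles, runs best-of-restarts NNMF (with
    incremental rank selection unless ``rank`` is fixed), averages and
    normalizes the factors, rescales the weightings, and orders the
    components by peak time so they are comparable across cells.
    """
    out = {}
    for s in dataset.subjects:
        for cond in dataset.config.conditions():
            X = dataset.concatenated(s, cond)
            cell_seed = _cell_seed(seed, s, cond)
            if rank is None:
                cs = factorization.select_dimensionality(
                    X, vaf_threshold=vaf_threshold, restarts=restarts,
                    seed=cell_seed, max_rank=max_rank, **nnmf_kwargs,
                )
            else:
                cs = factorization.nnmf_best_of_restarts(
                    X, rank, restarts=restarts, seed=cell_seed, **nnmf_kwargs,
                )
            n_cycles = len(dataset.cycles[(s, cond)])
            cs = factorization.normalize_and_scale(cs, n_cycles)
            cs = factorization.match_components_by_peak(cs)
            cs.muscle_labels = list(dataset.config.muscle_labels)
            out[(s, cond)] = cs
    return out


def _cell_seed(seed: int, subject: int, cond: ConditionKey) -> int:
    return int(np.random.SeedSequence(
        entropy=seed,
        spawn_key=(subject, int(cond.speed * 10), int(cond.elevation + 100)),
    ).generate_state(1)[0])


def fit_predictive_model(
    components: dict[tuple[int, ConditionKey], factorization.MotorComponentSet],
    train_subjects: list[int],
    train_conditions: list[ConditionKey],
    muscle_labels: list[str],
) -> FittedModel:
    """Train generic XPs, the weighting regression and the group baseline.

    Per training cell, each normalized averaged factor is fitted with a
    Gaussian; fits are averaged into generic primitives. Per-subject delta
    targets over the training grid are averaged across subjects and fitted
    with the additive polynomial regression anchored at the group baseline.
    """
    ranks = {components[(s, c)].rank
             for s in train_subjects for c in train_conditions}
    if len(ranks) != 1:
        raise ValueError(f"training cells disagree on rank: {sorted(ranks)}")

    fits = []
    for s in train_subjects:
        for cond in train_conditions:
            cs = components[(s, cond)]
            fits.append(XPParamSet(components=[
                fit_xp(f) for f in cs.factors_avg
            ]))
    xp_params = build_generic_xp(fits)

    baseline_cond = ConditionKey(BASELINE_SPEED, BASELINE_ELEVATION)
    if baseline_cond not in train_conditions:
        raise ValueError("training grid must include the baseline condition")
    subject_baselines = [components[(s, baseline_cond)].weightings
                         for s in train_subjects]
    generic_baseline = build_generic_baseline(subject_baselines)

    speed_targets_acc: dict[float, list[np.ndarray]] = {}
    elev_targets_acc: dict[float, list[np.ndarray]] = {}
    for s in train_subjects:
        wmap = {c: components[(s, c)].weightings for c in train_conditions}
        st, et = build_delta_targets(wmap)
        for v, d in st.items():
            speed_targets_acc.setdefault(v, []).append(d)
        for th, d in et.items():
            elev_targets_acc.setdefault(th, []).append(d)
    speed_targets = {v: np.mean(ds, axis=0)
                     for v, ds in speed_targets_acc.items()}
    elev_targets = {th: np.mean(ds, axis=0)
                    for th, ds in elev_targets_acc.items()}
    wmodel = fit_regression(speed_targets, elev_targets, generic_baseline,
                            muscle_labels=muscle_labels)
    return FittedModel(
        xp_params=xp_params,
        weighting_model=wmodel,
        generic_baseline=generic_baseline,
        muscle_labels=muscle_labels,
        training_metadata={
            "train_subjects": list(train_subjects),
            "train_conditions": [(c.speed, c.elevation)
                                 for c in train_conditions],
        },
    )


def _scenario_splits(
    dataset: SyntheticDataset, scenario: int
) -> tuple[list[ConditionKey], list[ConditionKey]]:
    all_conditions = dataset.config.conditions()
    if scenario == 1:
        train = [c for c in all_conditions
                 if c.speed in SCENARIO1_SPEEDS
                 and c.elevation in SCENARIO1_ELEVATIONS]
        test = [c for c in all_conditions if c not in train]
    elif scenario == 2:
        train = list(all_conditions)
        test = list(all_conditions)
    else:
        raise ValueError("scenario must be 1 or 2")
    return train, test


def run_scenario(
    dataset: SyntheticDataset,
    scenario: int = 1,
    components: dict | None = None,
    restarts: int = 50,
    seed: int = 0,
    rank: int | None = None,
    modes: tuple[str, ...] = ("sgm", "ssm"),
    against: str = "ground_truth",
) -> ScenarioResult:
    """Train on a scenario split and evaluate all held-out cases.

    Returns a :class:`ScenarioResult` with three long-format tables. The
    XP table has one row per (group, subject, condition, component) with
    the shift-compensated r, time shift (% gait cycle) and RMSE between
    the generic primitive and the cell's extracted factor. The weighting
    table has one row per (group, mode, subject, condition, component)
    with Pearson r and RMSE of the 15-muscle weighting vector; the MEP
    table one row per (group, mode, subject, condition, muscle) with the
    shift-compensated r, the time shift in % gait cycle, and the RMSE of
    the 200-sample profile.

    ``against`` selects the comparison reference: the generator's
    ``ground_truth`` registry or the ``extracted`` (NNMF) quantities.
    Known subjects are the training subjects evaluated on the held-out
    conditions; unknown subjects are never seen in training and are
    evaluated on the same held-out set (scenario 1) or the full grid
    (scenario 2).
    """
    train_conditions, test_conditions = _scenario_splits(dataset, scenario)
    if components is None:
        components = extract_components(
            dataset, restarts=restarts, seed=seed, rank=rank,
        )
    ranks = {cs.rank for cs in components.values()}
    if len(ranks) != 1:
        raise ValueError(f"non-uniform rank across cells: {sorted(ranks)}")

    model = fit_predictive_model(
        components, dataset.train_subjects, train_conditions,
        list(dataset.config.muscle_labels),
    )
    baseline_cond = ConditionKey(BASELINE_SPEED, BASELINE_ELEVATION)
    xp_profiles = model.xp_params.profile_matrix(cycle_grid())

    xp_rows = []
    w_rows = []
    mep_rows = []
    cases = (
        [("known", s, c) for s in dataset.train_subjects
         for c in test_conditions]
        + [("unknown", s, c) for s in dataset.test_subjects
           for c in test_conditions]
    )
    for group, s, cond in cases:
        for comp, factor in enumerate(components[(s, cond)].factors_avg):
            try:
                r, shift = evaluation.xcorr_with_shift(
                    xp_profiles[comp], factor
                )
            except ValueError:
                r, shift = float("nan"), float("nan")
            xp_rows.append({
                "group": group, "subject": s, "speed": cond.speed,
                "elevation": cond.elevation, "component": comp,
                "r": r, "shift": shift,
                "rmse": evaluation.rmse(xp_profiles[comp], factor),
            })
        if against == "ground_truth":
            w_ref = dataset.true_weightings[(s, cond)]
            mep_ref = dataset.true_mep[(s, cond)]
        elif against == "extracted":
            cs = components[(s, cond)]
            w_ref = cs.weightings
            mep_ref = cs.weightings @ cs.factors_avg
        else:
            raise ValueError(f"unknown reference {against!r}")
        subject_baseline = components[(s, baseline_cond)].weightings
        for mode in modes:
            pred = predict_mep(
                model, cond, mode=mode,
                subject_baseline=subject_baseline if mode == "ssm" else None,
            )
            for comp, (r, e) in enumerate(
                evaluation.weighting_similarity(pred.weightings, w_ref)
            ):
                w_rows.append({
                    "group": group, "mode": mode, "subject": s,
                    "speed": cond.speed, "elevation": cond.elevation,
                    "component": comp, "r": r, "rmse": e,
                })
            for mi, label in enumerate(model.muscle_labels):
                try:
                    r, shift = evaluation.xcorr_with_shift(
                        pred.mep[mi], mep_ref[mi]
                    )
                except ValueError:
                    r, shift = float("nan"), float("nan")
                mep_rows.append({
                    "group": group, "mode": mode, "subject": s,
                    "speed": cond.speed, "elevation": cond.elevation,
                    "muscle": label, "r": r, "shift": shift,
                    "rmse": evaluation.rmse(pred.mep[mi], mep_ref[mi]),
                })
    return ScenarioResult(
        model=model,
        xp_table=pd.DataFrame(xp_rows),
        weighting_table=pd.DataFrame(w_rows),
        mep_table=pd.DataFrame(mep_rows),
    )
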