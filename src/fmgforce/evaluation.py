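"""Cross-trial evaluation: R^2 per axis per held-out trial, and the full
band-combination x algorithm x case sweep.

Evaluation is leave-one-trial-out within a subject: for each trial, the
model (normalization, tuning, both stages) is refit on the remaining
trials and scored on the held-out one.  R^2 = 1 - SSE/SST is computed per
axis on the final (stage-2) predictions, retained unclamped (negative
values count), then averaged over axes ("3-DoF R^2" / "6-DoF R^2") and
over trials.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import BandCombination, SubjectDataset, select_bands
from .errors import DataError
from .preprocessing import FilterSpec
from .regression import TuningPlan
from .two_stage import CaseConfig, TwoStageModel


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SSE/SST; may be negative."""
    y = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != p.shape:
        raise DataError(f"length mismatch: {y.shape} vs {p.shape}")
    if y.size < 2:
        raise DataError("r_squared requires at least 2 samples")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise DataError("y_true is constant; R^2 undefined")
    sse = np.sum((p - y) ** 2)
    return float(1.0 - sse / sst)


def cross_trial_evaluate(
    ds: SubjectDataset,
    case: CaseConfig,
    combo: BandCombination | None = None,
    plan: TuningPlan | None = None,
    filter_spec: FilterSpec | None = None,
    seed: int = 0,
    holdout_trials: Iterable[int] | None = None,
    cross_fit_stage1: bool = False,
) -> pd.DataFrame:
    """Leave-one-trial-out evaluation for one subject and configuration.

    Returns a tidy frame with one row per (held-out trial, axis, stage);
    stage 1 rows are the single-stage baseline, stage 2 rows the final
    stacked predictions.  ``holdout_trials`` restricts which folds run
    (all trials by default).
    """
    ds = ds.apply_mask()
    if combo is not None:
        ds = select_bands(ds, combo)
    trials = [int(t) for t in ds.trials]
    if len(trials) < 2:
        raise DataError("cross-trial evaluation requires at least 2 trials")
    folds = trials if holdout_trials is None else [int(t) for t in holdout_trials]
    rows = []
    for held_out in folds:
        train = [t for t in trials if t != held_out]
        model = TwoStageModel(
            case, plan, filter_spec, seed=seed, cross_fit_stage1=cross_fit_stage1
        )
        model.fit(ds, train)
        pred = model.predict(ds, [held_out])
        for j, axis in enumerate(case.outputs):
            for stage, p in ((1, pred.stage1), (2, pred.stage2)):
                rows.append(
                    {
                        "trial": held_out,
                        "axis": axis,
                        "stage": stage,
                        "r2": r_squared(pred.y_true[:, j], p[:, j]),
                    }
                )
    return pd.DataFrame(rows)


def mean_r2(fold_df: pd.DataFrame, stage: int = 2) -> float:
    """Mean R^2 over axes and held-out trials for one stage."""
    sub = fold_df[fold_df["stage"] == stage]
    return float(sub.groupby("trial")["r2"].mean().mean())


def sweep(
    subjects: Sequence[SubjectDataset],
    cases: Sequence[CaseConfig],
    combos: Sequence[BandCombination],
    algorithms: Sequence[str],
    plan: TuningPlan | None = None,
    filter_spec: FilterSpec | None = None,
    seed: int = 0,
    holdout_trials: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Full factorial evaluation table across subjects/cases/combos/algorithms.

    Returns fold-level rows (subject, case, combo, algorithm, trial, axis,
    stage, r2); aggregate with :func:`aggregate_sweep`.
    """
    if not subjects:
        raise DataError("sweep requires at least one subject")
    rows = []
    for si, ds in enumerate(subjects):
        sid = ds.meta.get("seed", si)
        for case in cases:
            for algorithm in algorithms:
                cfg = CaseConfig(case.case, case.outputs, case.sessions, algorithm)
                for combo in combos:
                    fold_df = cross_trial_evaluate(
                        ds,
                        cfg,
                        combo,
                        plan,
                        filter_spec,
                        seed=seed,
                        holdout_trials=holdout_trials,
                    )
                    fold_df["subject"] = sid
                    fold_df["case"] = case.case
                    fold_df["outputs"] = "+".join(case.outputs)
                    fold_df["combo"] = str(combo)
                    fold_df["algorithm"] = algorithm
                    rows.append(fold_df)
    return pd.concat(rows, ignore_index=True)


def aggregate_sweep(fold_df: pd.DataFrame, stage: int = 2) -> pd.DataFrame:
    """Per-subject mean R^2 per cell, then mean +- SD across subjects."""
    sub = fold_df[fold_df["stage"] == stage]
    keys = [k for k in ("case", "outputs", "combo", "algorithm") if k in sub.columns]
    per_subject = (
        sub.groupby(keys + ["subject"], observed=True)["r2"].mean().reset_index()
    )
    agg = (
        per_subject.groupby(keys, observed=True)["r2"]
        .agg(mean_r2="mean", sd_r2="std", n_subjects="count")
        .reset_index()
    )
    return agg


def per_subject_means(fold_df: pd.DataFrame, stage: int = 2) -> pd.DataFrame:
    """One observation per subject x combo x algorithm (ANOVA response)."""
    sub = fold_df[fold_df["stage"] == stage]
    keys = [k for k in ("combo", "algorithm", "subject") if k in sub.columns]
    return sub.groupby(keys, observed=True)["r2"].mean().reset_index()
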