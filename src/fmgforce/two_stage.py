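"""The stacked two-stage regression pipeline.

Stage 1 maps preprocessed FMG features (normalized channels + first
differences) to the force/torque axes — one model per axis for SVR and RF,
one shared-spread multi-output GRNN (mathematically identical to per-axis
GRNNs with the same sigma).  Stage 2 is always a GRNN; it is trained on
the stage-1 *training* predictions assembled with the raw features (raw |
d(raw) | pred | d(pred) | spherical(pred)) against the same true labels,
so cross-axis structure in the loads — which is always present, since a
subject cannot isolate one axis perfectly — can be exploited.

Two case configurations exist: Case 1 fits separate 3-DoF force and 3-DoF
torque models, each restricted to its own focused sessions; Case 2 fits a
single 6-DoF model on all sessions including the free-exertion one.

Leakage rules enforced here: normalization statistics, tuned
hyperparameters, and stage-2 training features all derive from the
training trials only; test data only ever flows through ``predict``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dataset import AXES, SESSIONS, SubjectDataset
from .errors import ConfigError, DataError
from .features import FeatureRecipe, assemble_features
from .preprocessing import (
    FilterSpec,
    NormalizationRef,
    apply_normalizer,
    filter_by_trial,
    fit_normalizer,
)
from .regression import GRNN, TuningPlan, fold_indices, make_regressor, tune

FORCE_AXES = ("Fx", "Fy", "Fz")
TORQUE_AXES = ("Tx", "Ty", "Tz")


@dataclass(frozen=True)
class CaseConfig:
    """Outputs, sessions and stage-1 algorithm for one model case."""

    case: int
    outputs: tuple[str, ...]
    sessions: tuple[str, ...]
    stage1_algorithm: str = "grnn"

    def __post_init__(self) -> None:
        if self.case not in (1, 2):
            raise ConfigError("case must be 1 or 2")
        unknown = set(self.outputs) - set(AXES)
        if unknown:
            raise ConfigError(f"unknown output axes {sorted(unknown)}")
        if set(self.sessions) - set(SESSIONS):
            raise ConfigError("unknown session labels in case config")

    @classmethod
    def case1_force(cls, algorithm: str = "grnn") -> "CaseConfig":
        return cls(1, FORCE_AXES, FORCE_AXES, algorithm)

    @classmethod
    def case1_torque(cls, algorithm: str = "grnn") -> "CaseConfig":
        return cls(1, TORQUE_AXES, TORQUE_AXES, algorithm)

    @classmethod
    def case2(cls, algorithm: str = "grnn") -> "CaseConfig":
        return cls(2, AXES, SESSIONS, algorithm)

    @property
    def output_indices(self) -> np.ndarray:
        return np.array([AXES.index(a) for a in self.outputs])


@dataclass
class TwoStagePrediction:
    """Stage-1 and final (stage-2) predictions for one data slice."""

    stage1: np.ndarray
    stage2: np.ndarray
    y_true: np.ndarray  # preprocessed (low-passed) labels, case outputs only
    trial_id: np.ndarray
    session_id: np.ndarray


class TwoStageModel:
    """Fit/predict wrapper holding both stages and their references."""

    def __init__(
        self,
        case: CaseConfig,
        plan: TuningPlan | None = None,
        filter_spec: FilterSpec | None = None,
        seed: int = 0,
        cross_fit_stage1: bool = False,
        cross_fit_folds: int = 5,
    ):
        self.case = case
        self.plan = plan or TuningPlan()
        self.filter_spec = filter_spec or FilterSpec()
        self.seed = int(seed)
        self.cross_fit_stage1 = cross_fit_stage1
        self.cross_fit_folds = cross_fit_folds
        self.norm_ref: NormalizationRef | None = None
        self.stage2_norm_ref: NormalizationRef | None = None
        self.stage1_params: dict | None = None
        self.stage2_params: dict | None = None
        self.stage1_model = None
        self.stage2_model: GRNN | None = None
        self.n_channels_: int | None = None

    # -- preprocessing ----------------------------------------------------

    def _preprocess(self, ds: SubjectDataset, trials: Iterable[int]):
        """Filter per trial, restrict to the case's sessions."""
        sub = ds.select_trials(trials)
        missing = set(self.case.sessions) - set(np.unique(sub.session_id))
        if missing:
            raise DataError(f"dataset lacks sessions {sorted(missing)} required by case")
        fmg = filter_by_trial(sub.fmg, sub.trial_id, self.filter_spec, high=True)
        labels = filter_by_trial(sub.labels, sub.trial_id, self.filter_spec, high=False)
        keep = np.array([s in self.case.sessions for s in sub.session_id])
        return (
            fmg[keep],
            labels[keep][:, self.case.output_indices],
            sub.trial_id[keep],
            sub.session_id[keep],
        )

    def _stage1_features(self, fmg_norm: np.ndarray, trial_id: np.ndarray) -> np.ndarray:
        return assemble_features(FeatureRecipe.stage1(), fmg_norm, trial_id=trial_id)

    def _stage2_features(
        self, fmg_norm: np.ndarray, stage1_pred: np.ndarray, trial_id: np.ndarray
    ) -> np.ndarray:
        return assemble_features(
            FeatureRecipe.stage2(), fmg_norm, stage1_pred=stage1_pred, trial_id=trial_id
        )

    # -- fitting ----------------------------------------------------------

    def fit(self, ds: SubjectDataset, train_trials: Sequence[int]) -> "TwoStageModel":
        train_trials = sorted(int(t) for t in train_trials)
        if len(train_trials) < 1:
            raise DataError("two-stage fitting needs at least 1 training trial")
        fmg, y, trial_id, _ = self._preprocess(ds, train_trials)
        self.n_channels_ = fmg.shape[1]
        self.norm_ref = fit_normalizer(fmg)
        fmg_n = apply_normalizer(self.norm_ref, fmg)

        f1 = self._stage1_features(fmg_n, trial_id)
        self.stage1_params = tune(self.plan, self.case.stage1_algorithm, f1, y, seed=self.seed)
        self.stage1_model = make_regressor(
            self.case.stage1_algorithm, self.stage1_params, seed=self.seed
        )
        self.stage1_model.fit(f1, y)

        if self.cross_fit_stage1:
            train_pred = self._cross_fit_predictions(f1, y)
        else:
            # plain in-sample stage-1 predictions feed stage 2
            train_pred = np.asarray(self.stage1_model.predict(f1), dtype=float)

        f2 = self._stage2_features(fmg_n, train_pred, trial_id)
        self.stage2_norm_ref = fit_normalizer(f2)
        f2n = apply_normalizer(self.stage2_norm_ref, f2)
        self.stage2_params = tune(self.plan, "grnn", f2n, y, seed=self.seed)
        self.stage2_model = GRNN(self.stage2_params["sigma"]).fit(f2n, y)
        return self

    def _cross_fit_predictions(self, f1: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Optional out-of-fold stage-1 training predictions."""
        n = f1.shape[0]
        pred = np.empty((n, y.shape[1]))
        for val in fold_indices(n, self.cross_fit_folds, self.seed):
            train = np.setdiff1d(np.arange(n), val)
            m = make_regressor(self.case.stage1_algorithm, self.stage1_params, seed=self.seed)
            m.fit(f1[train], y[train])
            pred[val] = m.predict(f1[val])
        return pred

    # -- prediction -------------------------------------------------------

    def predict(self, ds: SubjectDataset, trials: Sequence[int]) -> TwoStagePrediction:
        if self.stage2_model is None:
            raise DataError("model is not fitted")
        fmg, y, trial_id, session_id = self._preprocess(ds, trials)
        if fmg.shape[1] != self.n_channels_:
            raise DataError(
                f"channel mismatch: model was trained on {self.n_channels_} channels, "
                f"got {fmg.shape[1]}"
            )
        fmg_n = apply_normalizer(self.norm_ref, fmg)
        f1 = self._stage1_features(fmg_n, trial_id)
        p1 = np.asarray(self.stage1_model.predict(f1), dtype=float)
        f2 = self._stage2_features(fmg_n, p1, trial_id)
        f2n = apply_normalizer(self.stage2_norm_ref, f2)
        p2 = self.stage2_model.predict(f2n)
        return TwoStagePrediction(
            stage1=p1, stage2=p2, y_true=y, trial_id=trial_id, session_id=session_id
        )


def fit_two_stage(
    ds: SubjectDataset,
    train_trials: Sequence[int],
    case: CaseConfig,
    plan: TuningPlan | None = None,
    **kwargs,
) -> TwoStageModel:
    """Convenience wrapper mirroring the functional interface."""
    return TwoStageModel(case, plan, **kwargs).fit(ds, train_trials)


def predict_two_stage(
    model: TwoStageModel, ds: SubjectDataset, trials: Sequence[int]
) -> TwoStagePrediction:
    return model.predict(ds, trials)
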