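"""Naive positive-unlabeled training loop for the federated booster.

The loop alternates boosting and relabeling stages. Stage 0 treats every
unlabeled sample as negative (working label = PU flag). Each Boost stage trains
a fresh federated ensemble on the current working labels; each Relabel stage
scores all training samples with the preceding model, promotes the top
``proportion`` fraction (plus every observed positive) to positive, and resets
the rest to negative. The default schedule is

    Boost(10) → Relabel(0.3) → Boost(20) → Relabel(0.5) → Boost(30)

with depth-3 trees, the configuration found best on balanced data: the second
relabel proportion of 0.5 drives the working labels toward the balanced split.

The theoretical justification is the selected-completely-at-random (SCAR)
constant-factor argument: when positives are labeled with constant probability
c = p(s=1|y=1), the nontraditional score g(x) = p(s=1|x) equals c·p(y=1|x), so
g ranks samples exactly as the true posterior does, and c is estimable as the
mean score over labeled positives (:func:`estimate_c`). The loop itself is
ranking-based and never uses the estimate; it is provided as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .boosting import BoostConfig
from .data import (
    DataError,
    ParameterError,
    SampleTable,
    VerticalPartition,
    WorkingLabels,
    vertical_split,
)
from .federation import (
    FederatedBoostedModel,
    InProcessTransport,
    MessageLog,
    federated_predict,
    run_federated_training,
)


class ScheduleError(ValueError):
    """Schedule does not alternate Boost/Relabel stages starting and ending with Boost."""


@dataclass(frozen=True)
class Stage:
    kind: str  # "boost" | "relabel"
    n_trees: int = 0
    proportion: float = 0.0

    @classmethod
    def boost(cls, n_trees: int) -> "Stage":
        return cls(kind="boost", n_trees=int(n_trees))

    @classmethod
    def relabel(cls, proportion: float) -> "Stage":
        return cls(kind="relabel", proportion=float(proportion))


@dataclass
class PUSchedule:
    """Alternating Boost/Relabel stages; must start and end with Boost."""

    stages: list[Stage] = field(
        default_factory=lambda: [
            Stage.boost(10),
            Stage.relabel(0.3),
            Stage.boost(20),
            Stage.relabel(0.5),
            Stage.boost(30),
        ]
    )

    def __post_init__(self) -> None:
        if not self.stages:
            raise ScheduleError("schedule must contain at least one Boost stage")
        if self.stages[0].kind != "boost" or self.stages[-1].kind != "boost":
            raise ScheduleError("schedule must start and end with a Boost stage")
        for a, b in zip(self.stages, self.stages[1:]):
            if a.kind == b.kind:
                raise ScheduleError("schedule must alternate Boost and Relabel stages")
        for st in self.stages:
            if st.kind == "boost" and st.n_trees < 0:
                raise ScheduleError("Boost stage needs n_trees >= 0")
            if st.kind == "relabel" and not 0.0 < st.proportion <= 1.0:
                raise ScheduleError("Relabel proportion must be in (0,1]")

    @classmethod
    def from_entries(cls, entries: list[dict]) -> "PUSchedule":
        """Parse [{"boost": 10}, {"relabel": 0.3}, ...] config entries."""
        stages = []
        for e in entries:
            if set(e) == {"boost"}:
                stages.append(Stage.boost(e["boost"]))
            elif set(e) == {"relabel"}:
                stages.append(Stage.relabel(e["relabel"]))
            else:
                raise ScheduleError(f"unknown schedule entry: {e!r}")
        return cls(stages=stages)


@dataclass
class PUCalibration:
    """Elkan–Noto labeling-frequency estimate ĉ = mean g(x) over labeled positives."""

    c: float

    def adjusted_posterior(self, scores: np.ndarray) -> np.ndarray:
        return np.minimum(1.0, np.asarray(scores) / self.c)


@dataclass
class StageSnapshot:
    stage_index: int
    kind: str
    detail: float
    labels: WorkingLabels
    n_positive: int


@dataclass
class LabelTrajectory:
    snapshots: list[StageSnapshot] = field(default_factory=list)
    models: list[FederatedBoostedModel] = field(default_factory=list)  # one per Boost stage

    def positive_counts(self) -> list[int]:
        return [s.n_positive for s in self.snapshots]

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "index": s.stage_index,
                    "kind": s.kind,
                    "detail": s.detail,
                    "n_positive": s.n_positive,
                    "labels": s.labels.y_tilde.tolist(),
                }
                for s in self.snapshots
            ]
        }


def pu_relabel(
    scores: np.ndarray, s: np.ndarray, proportion: float
) -> WorkingLabels:
    """Promote the top-scored fraction (plus every observed positive) to positive.

    quota = round(proportion × n) over *all* samples; ranking is by descending
    score with ties broken by ascending sample index; the observed positives
    (s=1) are kept positive by union regardless of rank.
    """
    scores = np.asarray(scores, dtype=np.float64)
    s = np.asarray(s)
    if scores.shape != s.shape:
        raise DataError("scores and flags must be aligned")
    if not 0.0 < proportion <= 1.0:
        raise ParameterError(f"proportion must be in (0,1], got {proportion}")
    n = scores.size
    quota = int(round(proportion * n))
    order = np.argsort(-scores, kind="stable")  # ties → ascending index
    y_tilde = np.zeros(n, dtype=np.int8)
    y_tilde[order[:quota]] = 1
    y_tilde[s == 1] = 1
    return WorkingLabels(y_tilde=y_tilde, observed=s == 1)


def run_schedule(
    partition: VerticalPartition,
    schedule: PUSchedule | None = None,
    config: BoostConfig | None = None,
    seed: int = 0,
) -> tuple[FederatedBoostedModel, LabelTrajectory, MessageLog]:
    """Execute the full train/relabel/retrain loop on one training partition.

    Each Boost stage trains a *fresh* model (no carryover margins) with the
    stage's tree count; the loop is deterministic given its inputs — ``seed``
    is recorded for provenance but the stages themselves draw no randomness.
    """
    schedule = schedule or PUSchedule()
    config = config or BoostConfig()
    s = partition.guest.s
    if s is None:
        raise DataError("guest view must carry PU flags s")
    transport = InProcessTransport()
    labels = WorkingLabels.from_flags(s)
    trajectory = LabelTrajectory()
    trajectory.snapshots.append(
        StageSnapshot(0, "init", 0.0, labels, labels.n_positive)
    )
    model: FederatedBoostedModel | None = None
    for i, stage in enumerate(schedule.stages, start=1):
        if stage.kind == "boost":
            stage_config = BoostConfig(
                n_trees=stage.n_trees,
                max_depth=config.max_depth,
                learning_rate=config.learning_rate,
                reg_lambda=config.reg_lambda,
                gamma=config.gamma,
                n_bins=config.n_bins,
                min_child_samples=config.min_child_samples,
                base_margin=config.base_margin,
            )
            model, _ = run_federated_training(
                partition, labels, stage_config, transport=transport
            )
            trajectory.models.append(model)
            trajectory.snapshots.append(
                StageSnapshot(i, "boost", stage.n_trees, labels, labels.n_positive)
            )
        else:
            scores = federated_predict(model, partition, transport=transport)
            labels = pu_relabel(scores, s, stage.proportion)
            trajectory.snapshots.append(
                StageSnapshot(i, "relabel", stage.proportion, labels, labels.n_positive)
            )
    return model, trajectory, transport.log


def estimate_c(scores: np.ndarray, s: np.ndarray) -> PUCalibration:
    """ĉ = mean nontraditional score over labeled positives, clipped to (0,1]."""
    scores = np.asarray(scores, dtype=np.float64)
    s = np.asarray(s)
    labeled = scores[s == 1]
    if labeled.size == 0:
        raise DataError("estimating c requires at least one labeled positive")
    c = float(np.clip(labeled.mean(), np.finfo(float).tiny, 1.0))
    return PUCalibration(c=c)


class PUVerticalFederatedClassifier(BaseEstimator, ClassifierMixin):
    """The full semisupervised pipeline as an estimator: ``fit(X, s)``.

    The training target ``s`` is the PU flag vector (1 = labeled positive,
    0 = unlabeled); true labels are never an input. ``predict_proba`` scores
    new samples with the final-stage federated model.
    """

    def __init__(
        self,
        schedule: PUSchedule | list | None = None,
        assignment: dict[str, int] | None = None,
        max_depth: int = 3,
        learning_rate: float = 0.3,
        reg_lambda: float = 1.0,
        gamma: float = 0.0,
        n_bins: int = 32,
        min_child_samples: int = 1,
    ):
        self.schedule = schedule
        self.assignment = assignment
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.reg_lambda = reg_lambda
        self.gamma = gamma
        self.n_bins = n_bins
        self.min_child_samples = min_child_samples

    def _schedule(self) -> PUSchedule:
        if self.schedule is None:
            return PUSchedule()
        if isinstance(self.schedule, PUSchedule):
            return self.schedule
        return PUSchedule.from_entries(list(self.schedule))

    def _config(self) -> BoostConfig:
        return BoostConfig(
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            reg_lambda=self.reg_lambda,
            gamma=self.gamma,
            n_bins=self.n_bins,
            min_child_samples=self.min_child_samples,
        )

    def _partition(self, X, s) -> VerticalPartition:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(
                np.asarray(X, dtype=np.float64),
                columns=[f"f{i}" for i in range(np.asarray(X).shape[1])],
            )
        table = SampleTable(features=X, s=np.asarray(s, dtype=np.int8))
        assignment = self.assignment or {str(c): 0 for c in X.columns}
        return vertical_split(table, assignment)

    def fit(self, X, s):
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        partition = self._partition(X, s)
        self.model_, self.trajectory_, self.log_ = run_schedule(
            partition, self._schedule(), self._config()
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        partition = self._partition(X, np.zeros(len(X), dtype=np.int8))
        p1 = federated_predict(self.model_, partition)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def transduced_labels_(self) -> np.ndarray:
        """Final working labels on the training set (transductive output)."""
        check_is_fitted(self, "trajectory_")
        return self.trajectory_.snapshots[-1].labels.y_tilde.copy()
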