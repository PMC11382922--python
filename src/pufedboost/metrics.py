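"""Confusion-based metrics (Acc, UAR, UF1) and the repeated-experiment harness.

UAR (unweighted average recall) is the mean of per-class recalls; UF1 is the
unweighted (macro) mean of per-class F1 = 2TP/(2TP+FP+FN). Both give every
class the same weight regardless of support, which matters for the imbalanced
multi-institution corpora the method targets. On an exactly balanced test set,
Acc equals UAR.

:func:`repeat_experiment` re-runs the full pipeline — synthetic draw, SCAR
masking, class balancing, vertical partitioning, the PU schedule, held-out
scoring — once per repetition with a seed derived from the master seed, and
reports per-repetition and mean±sd metrics in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .boosting import BoostConfig
from .data import (
    DataError,
    ParameterError,
    split_parties_evenly,
    undersample_balance,
    vertical_split,
)
from .federation import federated_predict, run_federated_training
from .pu import PUSchedule, run_schedule
from .synthetic import SynthSpec, gen_pu_dataset


class MetricError(ValueError):
    """Metric undefined for the given counts (e.g. an empty class)."""


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN per class."""

    per_class: dict[int, tuple[int, int, int, int]]  # class -> (TP, FP, FN, TN)
    n_total: int


def confusion_counts(y_true, y_pred, classes=(0, 1)) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise MetricError("prediction and truth vectors must be aligned")
    per_class = {}
    n = y_true.size
    for c in classes:
        tp = int(((y_true == c) & (y_pred == c)).sum())
        fp = int(((y_true != c) & (y_pred == c)).sum())
        fn = int(((y_true == c) & (y_pred != c)).sum())
        tn = n - tp - fp - fn
        per_class[int(c)] = (tp, fp, fn, tn)
    return ConfusionCounts(per_class=per_class, n_total=n)


def accuracy(counts: ConfusionCounts) -> float:
    correct = sum(tp for tp, _, _, _ in counts.per_class.values())
    return correct / counts.n_total


def uar(counts: ConfusionCounts) -> float:
    """Unweighted average recall: mean over classes of TP/(TP+FN)."""
    recalls = []
    for c, (tp, fp, fn, tn) in counts.per_class.items():
        if tp + fn == 0:
            raise MetricError(f"class {c} has no true samples; UAR undefined")
        recalls.append(tp / (tp + fn))
    return float(np.mean(recalls))


def uf1(counts: ConfusionCounts) -> float:
    """Unweighted (macro) F1: mean over classes of 2TP/(2TP+FP+FN)."""
    f1s = []
    for c, (tp, fp, fn, tn) in counts.per_class.items():
        if 2 * tp + fp + fn == 0:
            raise MetricError(f"class {c} has TP=FP=FN=0; F1 undefined")
        f1s.append(2 * tp / (2 * tp + fp + fn))
    return float(np.mean(f1s))


def evaluate_predictions(y_true, y_pred) -> dict[str, float]:
    """Acc/UAR/UF1 in percent, 3-decimal convention of the result tables."""
    counts = confusion_counts(y_true, y_pred)
    return {
        "acc": round(100.0 * accuracy(counts), 3),
        "uar": round(100.0 * uar(counts), 3),
        "uf1": round(100.0 * uf1(counts), 3),
    }


# ---------------------------------------------------------------------------
# Repetition harness


@dataclass
class MetricsReport:
    per_repetition: pd.DataFrame
    mean: pd.Series = field(init=False)
    sd: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        numeric = self.per_repetition.drop(columns=["seed"], errors="ignore")
        self.mean = numeric.mean()
        self.sd = numeric.std(ddof=1) if len(numeric) > 1 else numeric.std(ddof=0)


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-repetition seeds below 2^31."""
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=n)


def _test_size(n_train: int) -> int:
    # 7:3 train:test split ratio of the corpus protocol
    return int(round(n_train * 3 / 7))


def run_single_repetition(
    spec: SynthSpec,
    schedule: PUSchedule,
    config: BoostConfig,
    seed: int,
    n_parties: int = 2,
    include_supervised: bool = False,
) -> dict[str, float]:
    """One pipeline run: draw, balance, partition, PU schedule, held-out scoring.

    Returns test-set acc/uar/uf1 (percent), the transductive accuracy of the
    final working labels against the hidden training labels, and (optionally)
    the fully supervised reference trained on the true labels.
    """
    rng = np.random.default_rng(seed)
    train_seed, test_seed, balance_seed = (
        int(x) for x in rng.integers(0, 2**31 - 1, size=3)
    )
    train = gen_pu_dataset(spec.with_seed(train_seed))
    train = undersample_balance(train, seed=balance_seed)
    test_spec = replace(spec, n_samples=_test_size(train.n_samples), seed=test_seed)
    test = gen_pu_dataset(test_spec)

    assignment = split_parties_evenly(train.feature_names, n_parties)
    train_part = vertical_split(train, assignment)
    test_part = vertical_split(test, assignment)

    model, trajectory, _ = run_schedule(train_part, schedule, config)
    p_test = federated_predict(model, test_part)
    y_pred = (p_test >= 0.5).astype(int)
    out = evaluate_predictions(test.y, y_pred)
    final_labels = trajectory.snapshots[-1].labels.y_tilde
    out["acc_transductive"] = round(100.0 * float((final_labels == train.y).mean()), 3)

    if include_supervised:
        sup_trees = max(
            (st.n_trees for st in schedule.stages if st.kind == "boost"), default=30
        )
        sup_config = replace(config, n_trees=sup_trees)
        sup_model, _ = run_federated_training(train_part, train.y, sup_config)
        sup_pred = (federated_predict(sup_model, test_part) >= 0.5).astype(int)
        sup = evaluate_predictions(test.y, sup_pred)
        out.update({f"sup_{k}": v for k, v in sup.items()})
    return out


def repeat_experiment(
    spec: SynthSpec | None = None,
    schedule: PUSchedule | None = None,
    config: BoostConfig | None = None,
    n_reps: int = 50,
    master_seed: int = 0,
    n_parties: int = 2,
    include_supervised: bool = False,
) -> MetricsReport:
    """Mean testing performance over repeated randomized pipeline runs."""
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    spec = spec or SynthSpec()
    schedule = schedule or PUSchedule()
    config = config or BoostConfig()
    rows = []
    for rep_seed in derive_seeds(master_seed, n_reps):
        row = run_single_repetition(
            spec, schedule, config, int(rep_seed),
            n_parties=n_parties, include_supervised=include_supervised,
        )
        row["seed"] = int(rep_seed)
        rows.append(row)
    return MetricsReport(per_repetition=pd.DataFrame(rows))
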