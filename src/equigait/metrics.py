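"""Accuracy metrics and leave-one-horse-out cross-validation.

Conventions: confusion-matrix rows are truth, columns are prediction, in
gait-code order. Micro accuracy is trace over total; per-gait accuracy is
one-vs-all (true positives plus true negatives over total); macro averages
are unweighted means over *present* entries only — a gait for which a horse
contributed no data is marked missing and excluded from its macro column.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .dataset import Segment
from .gaits import Gait
from .models import (
    ModelConfig,
    TrainConfig,
    build_model,
    predict_proba,
    segments_to_arrays,
    train_model,
)

N = 5


class UndefinedMetricError(ValueError):
    """A metric requested on an empty confusion matrix or all-missing values."""


def confusion_matrix(
    truth: Sequence[int], pred: Sequence[int], n_classes: int = N
) -> np.ndarray:
    """Counts matrix with rows = truth, columns = prediction."""
    truth = np.asarray(truth, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must have equal length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (truth, pred), 1)
    return cm


def micro_accuracy(cm: np.ndarray) -> float:
    """Diagonal sum over total — the fraction classified correctly."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return float(np.trace(cm) / total)


def ova_accuracy(cm: np.ndarray, gait: Gait | int) -> float:
    """One-vs-all accuracy: (TP + TN) / total for the binarised problem."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    g = int(gait)
    tp = cm[g, g]
    fn = cm[g].sum() - tp
    fp = cm[:, g].sum() - tp
    tn = total - tp - fn - fp
    return float((tp + tn) / total)


def macro_average(
    values: Sequence[float], present: Sequence[bool] | None = None
) -> float:
    """Unweighted mean over present values only."""
    values = np.asarray(values, dtype=float)
    mask = (
        np.ones(len(values), dtype=bool)
        if present is None
        else np.asarray(present, dtype=bool)
    )
    if not mask.any():
        raise UndefinedMetricError("macro average of all-missing values")
    return float(values[mask].mean())


@dataclasses.dataclass
class AccuracyReport:
    """Micro, per-gait one-vs-all and macro accuracy for one evaluation."""

    micro: float
    per_gait: dict[Gait, float]  # only gaits present in the truth
    macro: float
    cm: np.ndarray

    @classmethod
    def from_predictions(
        cls, truth: Sequence[int], pred: Sequence[int]
    ) -> "AccuracyReport":
        cm = confusion_matrix(truth, pred)
        present = cm.sum(axis=1) > 0
        per_gait = {
            Gait(g): ova_accuracy(cm, g) for g in range(N) if present[g]
        }
        macro = macro_average(
            [ova_accuracy(cm, g) for g in range(N)], present
        )
        return cls(micro=micro_accuracy(cm), per_gait=per_gait, macro=macro, cm=cm)


@dataclasses.dataclass
class CvResult:
    """Leave-one-horse-out cross-validation output.

    ``per_horse`` maps horse id to its repeat-averaged report values:
    per-gait one-vs-all accuracies (only for gaits the horse showed) and
    micro accuracy. ``gait_macro`` averages each gait column over the
    horses that have it; ``overall_macro_of_gaits`` is the mean of the
    per-gait macro values; ``mean_micro`` averages the per-horse micro
    accuracies (the model-comparison number).
    """

    per_horse: dict[int, dict]
    gait_macro: dict[Gait, float]
    overall_macro_of_gaits: float
    mean_micro: float


def loho_cv(
    segments: Sequence[Segment],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    repeats: int = 5,
    val_fraction: float = 0.15,
    progress: Callable[[str], None] | None = None,
) -> CvResult:
    """Leave-one-horse-out cross-validation, repeated with fresh seeds.

    For each horse, a model is trained on all other horses (with an 85/15
    train/validation split of their segments) and evaluated on the held-out
    horse; repeats use seeds ``seed, seed+1, …`` and their confusion
    matrices are pooled before computing accuracies.
    """
    horses = sorted({s.horse_id for s in segments})
    if len(horses) < 2:
        raise ValueError("need at least 2 horses for cross-validation")
    per_horse: dict[int, dict] = {}
    for horse in horses:
        held = [s for s in segments if s.horse_id == horse]
        rest = [s for s in segments if s.horse_id != horse]
        X_ho, y_ho = segments_to_arrays(held)
        cm = np.zeros((N, N), dtype=np.int64)
        for r in range(repeats):
            seed = train_cfg.seed + r
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(rest))
            n_val = max(1, int(round(val_fraction * len(rest))))
            val = [rest[i] for i in order[:n_val]]
            train = [rest[i] for i in order[n_val:]]
            model = build_model(model_cfg, seed=seed)
            cfg_r = dataclasses.replace(train_cfg, seed=seed)
            train_model(model, train, val, cfg_r)
            pred = predict_proba(model, X_ho).argmax(axis=1)
            cm += confusion_matrix(y_ho, pred)
            if progress:
                progress(f"horse {horse} repeat {r}: cm trace {np.trace(cm)}")
        present = cm.sum(axis=1) > 0
        per_horse[horse] = {
            "micro": micro_accuracy(cm),
            "per_gait": {
                Gait(g): ova_accuracy(cm, g) for g in range(N) if present[g]
            },
            "cm": cm,
        }
    gait_macro: dict[Gait, float] = {}
    for g in range(N):
        vals = [
            rep["per_gait"][Gait(g)]
            for rep in per_horse.values()
            if Gait(g) in rep["per_gait"]
        ]
        if vals:
            gait_macro[Gait(g)] = float(np.mean(vals))
    overall = macro_average(list(gait_macro.values()))
    mean_micro = float(np.mean([rep["micro"] for rep in per_horse.values()]))
    return CvResult(
        per_horse=per_horse,
        gait_macro=gait_macro,
        overall_macro_of_gaits=overall,
        mean_micro=mean_micro,
    )
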