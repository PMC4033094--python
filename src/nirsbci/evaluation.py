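"""Evaluation protocol: per-participant cross-validation, group statistics
against chance, mobility comparison, and realistic-paradigm testing.

Each participant's nine task and nine rest trials are scored by nine-fold
leave-one-trial-per-class-out cross-validation; group-level inference is a
one-tailed one-sample t-test of the per-participant accuracies against
chance (0.5), and per-participant significance is an exact one-tailed
binomial test on trial-level (majority-vote) outcomes — timepoint-level
counts would be anticonservative under temporal autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import (
    LabeledSamples,
    PredictionSeries,
    PointwiseSvmModel,
    ThresholdModel,
    WindowSvmModel,
    detect_onset,
    featurize_pointwise,
    featurize_window,
    fit_svm,
    fit_threshold,
    predict_svm,
    predict_threshold,
)
from .recording import HemoRecording, Trial, TrialTable

MODEL_KINDS = ("threshold", "svm-point", "svm-window")


# ---------------------------------------------------------------------------
# model fitting/prediction dispatch (uniform contract over the three kinds)

def fit_model(
    kind: str,
    rec: HemoRecording,
    trials: TrialTable,
    window_duration: float | None = None,
):
    if kind == "threshold":
        return fit_threshold(rec, trials)
    if kind == "svm-point":
        return fit_svm(featurize_pointwise(rec, trials), "pointwise",
                       rec.channels)
    if kind == "svm-window":
        if window_duration is None:
            window_duration = min(
                t.duration for t in trials.non_fixation
            )
        samples = featurize_window(rec, trials, window_duration)
        return fit_svm(samples, "window", rec.channels, rate=rec.rate,
                       window_duration=window_duration)
    raise ValueError(f"unknown model kind {kind!r}; use {MODEL_KINDS}")


def predict_model(model, rec: HemoRecording,
                  trials: TrialTable | None = None,
                  stride: float = 1.0) -> PredictionSeries:
    if isinstance(model, ThresholdModel):
        return predict_threshold(model, rec)
    return predict_svm(model, rec, trials, stride=stride)


# ---------------------------------------------------------------------------
# scoring helpers

def _trial_votes(pred: PredictionSeries, trials: TrialTable) -> list[bool]:
    """Majority-vote correctness per task/rest trial (ties count wrong)."""
    votes = []
    for trial in trials.non_fixation:
        mask = ((pred.times >= trial.onset - 1e-9)
                & (pred.times < trial.end - 1e-9))
        labels = pred.labels[mask]
        if len(labels) == 0:
            votes.append(False)
            continue
        n_task = int(np.sum(labels == "task"))
        majority = "task" if n_task * 2 > len(labels) else "rest"
        votes.append(majority == trial.condition)
    return votes


def _timepoint_score(pred: PredictionSeries,
                     trials: TrialTable) -> tuple[int, int]:
    """(n_correct, n_total) over every prediction inside a task/rest trial."""
    correct = total = 0
    for trial in trials.non_fixation:
        mask = ((pred.times >= trial.onset - 1e-9)
                & (pred.times < trial.end - 1e-9))
        labels = pred.labels[mask]
        correct += int(np.sum(labels == trial.condition))
        total += len(labels)
    return correct, total


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVResult:
    """One participant's cross-validated performance for one model."""

    accuracy: float
    n_correct: int
    n_total: int
    trial_outcomes: list[bool]
    latencies: list[float | None]
    predictions: list[PredictionSeries] = field(default_factory=list)

    @property
    def n_trials_correct(self) -> int:
        return int(sum(self.trial_outcomes))


def _subset_table(trials: list[Trial]) -> TrialTable:
    return TrialTable(sorted(trials, key=lambda t: t.onset))


def crossvalidate(
    rec: HemoRecording,
    trials: TrialTable,
    model_kind: str,
    k: int = 9,
    window_duration: float | None = None,
) -> CVResult:
    """k-fold leave-trials-out CV on one (preprocessed) block recording.

    Each fold holds out an equal share of task and of rest trials (one of
    each for the canonical 9+9 design with k = 9); the model is refitted
    on the remainder and scored on the held-out trials.  Accuracy pools
    timepoint labels (window model: one label per trial) over all folds.
    """
    tasks = [t for t in trials.non_fixation if t.condition == "task"]
    rests = [t for t in trials.non_fixation if t.condition == "rest"]
    if not tasks or not rests:
        raise ValueError("cross-validation needs both task and rest trials")
    if len(tasks) % k or len(rests) % k:
        valid = sorted(
            kk for kk in range(1, min(len(tasks), len(rests)) + 1)
            if len(tasks) % kk == 0 and len(rests) % kk == 0
        )
        raise ValueError(
            f"k={k} does not divide {len(tasks)} task and {len(rests)} "
            f"rest trials; valid k: {valid}"
        )
    per_task, per_rest = len(tasks) // k, len(rests) // k
    n_correct = n_total = 0
    outcomes: list[bool] = []
    latencies: list[float | None] = []
    preds: list[PredictionSeries] = []
    for j in range(k):
        held = (tasks[j * per_task:(j + 1) * per_task]
                + rests[j * per_rest:(j + 1) * per_rest])
        held_set = {(t.onset, t.condition) for t in held}
        train = [t for t in trials.non_fixation
                 if (t.onset, t.condition) not in held_set]
        train_table = _subset_table(train)
        held_table = _subset_table(held)
        model = fit_model(model_kind, rec, train_table, window_duration)
        pred = predict_model(model, rec, held_table)
        c, n = _timepoint_score(pred, held_table)
        n_correct += c
        n_total += n
        outcomes.extend(_trial_votes(pred, held_table))
        for trial in held_table.non_fixation:
            if trial.condition == "task":
                latencies.append(detect_onset(pred, trial))
        preds.append(pred)
    return CVResult(
        accuracy=n_correct / n_total if n_total else float("nan"),
        n_correct=n_correct,
        n_total=n_total,
        trial_outcomes=outcomes,
        latencies=latencies,
        predictions=preds,
    )


# ---------------------------------------------------------------------------
# statistics

@dataclass
class GroupStats:
    mean: float
    sd: float
    t: float
    df: int
    p: float
    n: int
    chance: float


def group_stats(accuracies, chance: float = 0.5) -> GroupStats:
    """One-sample, one-tailed (greater) t-test of accuracies vs. chance."""
    acc = np.asarray(list(accuracies), float)
    n = len(acc)
    if n < 2:
        raise ValueError("group statistics need at least two participants")
    mean = float(acc.mean())
    sd = float(acc.std(ddof=1))
    if sd == 0:
        # zero-variance edge: the t statistic diverges; report the limit
        if mean > chance:
            t_obs, p = float("inf"), 0.0
        elif mean < chance:
            t_obs, p = float("-inf"), 1.0
        else:
            t_obs, p = 0.0, 0.5
    else:
        res = stats.ttest_1samp(acc, chance, alternative="greater")
        t_obs, p = float(res.statistic), float(res.pvalue)
    return GroupStats(mean=mean, sd=sd, t=t_obs, df=n - 1, p=p, n=n,
                      chance=chance)


def t_critical(df: int, alpha: float = 0.05) -> float:
    """One-tailed critical t value (e.g. 1.68 at df = 39, α = 0.05)."""
    return float(stats.t.ppf(1 - alpha, df))


def per_participant_significance(
    n_correct: int, n_total: int, chance: float = 0.5, alpha: float = 0.05
) -> bool:
    """Exact one-tailed binomial test of trial-level outcomes vs. chance."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_correct > n_total:
        raise ValueError("n_correct cannot exceed n_total")
    p = stats.binomtest(n_correct, n_total, chance,
                        alternative="greater").pvalue
    return bool(p < alpha)


@dataclass
class PairedComparison:
    t: float
    df: int
    p: float
    mean_diff: float


def compare_models(acc_a, acc_b) -> PairedComparison:
    """Paired two-tailed t-test on per-participant accuracy differences."""
    a = np.asarray(list(acc_a), float)
    b = np.asarray(list(acc_b), float)
    if a.shape != b.shape:
        raise ValueError("paired comparison needs equal-length accuracy lists")
    diff = a - b
    n = len(diff)
    if n < 2:
        raise ValueError("paired comparison needs at least two participants")
    if diff.std(ddof=1) == 0:
        if np.allclose(diff, 0):
            t_obs, p = 0.0, 1.0
        else:
            t_obs = float("inf") if diff.mean() > 0 else float("-inf")
            p = 0.0
    else:
        res = stats.ttest_rel(a, b)
        t_obs, p = float(res.statistic), float(res.pvalue)
    return PairedComparison(t=t_obs, df=n - 1, p=p,
                            mean_diff=float(diff.mean()))


# ---------------------------------------------------------------------------
# realistic-paradigm testing

@dataclass
class RealisticResult:
    accuracy: float
    n_correct: int
    n_total: int
    latency: float | None
    segment_outcomes: list[bool]
    majority_baseline: float


def evaluate_realistic(
    model, rec: HemoRecording, trials: TrialTable, stride: float = 1.0
) -> RealisticResult:
    """Score a restricted-trained model on the continuous realistic block.

    Every prediction timestamp is labeled with the condition of its
    containing segment; latency is the delay from the task segment's onset
    to the first task-labeled output within it.
    """
    if isinstance(model, (ThresholdModel, PointwiseSvmModel)):
        pred = predict_model(model, rec, trials)
    else:
        pred = predict_model(model, rec, None, stride=stride)
    n_correct, n_total = _timepoint_score(pred, trials)
    task_segments = trials.of_condition("task")
    latency = None
    if task_segments:
        latency = detect_onset(pred, task_segments[0])
    durations = [t.duration for t in trials.non_fixation]
    rest_time = sum(t.duration for t in trials.of_condition("rest"))
    return RealisticResult(
        accuracy=n_correct / n_total if n_total else float("nan"),
        n_correct=n_correct,
        n_total=n_total,
        latency=latency,
        segment_outcomes=_trial_votes(pred, trials),
        majority_baseline=rest_time / sum(durations),
    )


# ---------------------------------------------------------------------------
# latency summaries

@dataclass
class LatencySummary:
    mean: float
    sd: float
    min: float
    max: float
    n: int
    n_missing: int


def latency_stats(per_participant_means) -> LatencySummary:
    """Summary over per-participant mean latencies; None entries (no
    detection) are excluded and counted separately."""
    vals = [v for v in per_participant_means if v is not None]
    n_missing = len(per_participant_means) - len(vals)
    if not vals:
        raise ValueError("no detections: all latencies are None")
    arr = np.asarray(vals, float)
    return LatencySummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        min=float(arr.min()),
        max=float(arr.max()),
        n=len(arr),
        n_missing=n_missing,
    )
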