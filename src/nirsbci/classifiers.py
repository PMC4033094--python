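"""The three compared workload models under one fit/predict contract.

1. Reference-channel thresholding: classify each timepoint of the
   left−right ΔHbO difference against a baseline learned from rest trials.
2. Pointwise SVM: linear SVM over the four instantaneous amplitudes
   (left HbO, left Hb, right HbO, right Hb), one decision per timepoint.
3. Window SVM: linear SVM over the flattened full-trial timecourse of
   every chromophore on every channel (e.g. 40 s × 6.25 Hz × 16 signals
   = 4000 features for an eight-channel montage).

All three emit a :class:`PredictionSeries` of timestamped task/rest
labels, so the same evaluation code scores them.  SVMs are fitted with an
SMO-type solver (libsvm via scikit-learn), linear kernel, C = 1, on
per-feature standardized inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .recording import CHROMOPHORES, HemoRecording, Trial, TrialTable

LABELS = ("rest", "task")
_EPS = 1e-9


def n_samples_in(duration: float, rate: float) -> int:
    """Samples spanned by ``duration`` seconds: floor(duration·rate).

    Trial spans are half-open ``[onset, onset + duration)`` at sample
    resolution; a 30 s trial at 6.25 Hz contributes 187 samples.
    """
    return int(math.floor(duration * rate + _EPS))


def _trial_slice(trial, rate: float) -> tuple[int, int]:
    onset, duration = trial.onset, trial.duration
    start = int(math.ceil(onset * rate - _EPS))
    return start, start + n_samples_in(duration, rate)


@dataclass
class PredictionSeries:
    """Timestamped task/rest labels (per timepoint or per window)."""

    times: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.labels = np.asarray(self.labels, object)
        if len(self.times) != len(self.labels):
            raise ValueError("times and labels must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class LabeledSamples:
    """Design matrix + labels + per-row metadata for classifier fitting."""

    design: np.ndarray
    labels: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.design.shape[0] != len(self.labels):
            raise ValueError("design rows must match labels")

    @property
    def n(self) -> int:
        return self.design.shape[0]


# ---------------------------------------------------------------------------
# reference-channel thresholding

def diff_series(rec: HemoRecording, target: str = "L",
                reference: str = "R") -> np.ndarray:
    """Elementwise target − reference ΔHbO (µM); cancels global activity."""
    return rec.get(target, "HbO") - rec.get(reference, "HbO")


@dataclass
class ThresholdModel:
    """Single-baseline detector on the bilateral ΔHbO difference."""

    baseline: float
    target_channel: str = "L"
    reference_channel: str = "R"

    def __post_init__(self) -> None:
        if self.target_channel == self.reference_channel:
            raise ValueError("target and reference channels must differ")


def fit_threshold(
    rec: HemoRecording,
    trials: TrialTable,
    target: str = "L",
    reference: str = "R",
    baseline_mode: str = "mean_of_trial_maxima",
) -> ThresholdModel:
    """Learn the decision baseline from the rest trials.

    ``mean_of_trial_maxima`` (default): mean over rest trials of the
    within-trial maximum of the difference series.  ``block_max``: the
    maximum over all rest samples — the stricter alternative reading.
    """
    d = diff_series(rec, target, reference)
    rests = trials.of_condition("rest")
    if not rests:
        raise ValueError("thresholding requires at least one rest trial")
    maxima = []
    for trial in rests:
        i0, i1 = _trial_slice(trial, rec.rate)
        if i1 > len(d):
            raise ValueError(
                f"rest trial [{trial.onset}, {trial.end}) s exceeds the "
                f"recording ({len(d) / rec.rate:.1f} s)"
            )
        maxima.append(d[i0:i1].max())
    if baseline_mode == "mean_of_trial_maxima":
        baseline = float(np.mean(maxima))
    elif baseline_mode == "block_max":
        baseline = float(np.max(maxima))
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    return ThresholdModel(baseline=baseline, target_channel=target,
                          reference_channel=reference)


def predict_threshold(model: ThresholdModel,
                      rec: HemoRecording) -> PredictionSeries:
    """Label every timepoint: task iff the difference strictly exceeds the
    baseline (ties are rest)."""
    d = diff_series(rec, model.target_channel, model.reference_channel)
    labels = np.where(d > model.baseline, "task", "rest").astype(object)
    return PredictionSeries(times=rec.times, labels=labels)


def detect_onset(pred: PredictionSeries, trial, rate: float | None = None,
                 persistence: int = 1) -> float | None:
    """Latency (s) from trial onset to the first task-labeled sample
    within the trial, requiring ``persistence`` consecutive task labels;
    None if the trial is never flagged."""
    if isinstance(trial, Trial):
        onset, duration = trial.onset, trial.duration
    else:
        onset, duration = trial
    if duration <= 0:
        raise ValueError("trial duration must be positive")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    mask = (pred.times >= onset - _EPS) & (pred.times < onset + duration - _EPS)
    idx = np.nonzero(mask)[0]
    is_task = pred.labels[idx] == "task"
    run = 0
    for k, flag in enumerate(is_task):
        run = run + 1 if flag else 0
        if run >= persistence:
            first = idx[k - persistence + 1]
            return float(pred.times[first] - onset)
    return None


# ---------------------------------------------------------------------------
# featurization

def featurize_pointwise(rec: HemoRecording,
                        trials: TrialTable) -> LabeledSamples:
    """One row per in-trial sample; features are the instantaneous
    amplitudes [ch1 HbO, ch1 Hb, ch2 HbO, ch2 Hb, ...] in channel order.
    Fixation samples are excluded."""
    mat = rec.to_matrix()
    rows, labels, meta = [], [], []
    for ti, trial in enumerate(trials.non_fixation):
        i0, i1 = _trial_slice(trial, rec.rate)
        if i1 > rec.n_samples:
            raise ValueError(
                f"trial [{trial.onset}, {trial.end}) s exceeds the "
                f"recording ({rec.duration:.1f} s)"
            )
        rows.append(mat[i0:i1])
        labels.extend([trial.condition] * (i1 - i0))
        meta.extend(
            {"trial": ti, "time": i / rec.rate} for i in range(i0, i1)
        )
    design = (np.vstack(rows) if rows
              else np.empty((0, mat.shape[1])))
    return LabeledSamples(
        design=design,
        labels=np.asarray(labels, object),
        meta=pd.DataFrame(meta, columns=["trial", "time"]),
    )


def featurize_window(
    rec: HemoRecording,
    trials: TrialTable,
    window_duration: float,
    truncate: bool = False,
) -> LabeledSamples:
    """One row per trial: every chromophore series on every channel over
    the first ``window_duration`` seconds of the trial, concatenated
    channel-major then chromophore then time.

    Trials shorter than the window are an error unless ``truncate`` is
    set, in which case the window shrinks to the shortest trial.
    """
    if window_duration <= 0:
        raise ValueError("window_duration must be positive")
    nf = trials.non_fixation
    if truncate and nf:
        window_duration = min(window_duration, min(t.duration for t in nf))
    n_w = n_samples_in(window_duration, rec.rate)
    if n_w == 0:
        raise ValueError("window shorter than one sample")
    rows, labels, meta = [], [], []
    for ti, trial in enumerate(nf):
        if trial.duration < window_duration - _EPS:
            raise ValueError(
                f"trial of {trial.duration} s is shorter than the "
                f"{window_duration} s window; pass truncate=True to use "
                "the shortest trial as the window"
            )
        i0 = int(math.ceil(trial.onset * rec.rate - _EPS))
        if i0 + n_w > rec.n_samples:
            raise ValueError("trial window exceeds the recording")
        row = np.concatenate([
            rec.get(ch, chromo)[i0:i0 + n_w]
            for ch in rec.channels
            for chromo in CHROMOPHORES
        ])
        rows.append(row)
        labels.append(trial.condition)
        # stamp at the window's final sample so the label falls inside
        # the half-open trial span
        meta.append({"trial": ti, "onset": trial.onset,
                     "end": (i0 + n_w - 1) / rec.rate})
    n_feat = n_w * 2 * len(rec.channels)
    design = np.vstack(rows) if rows else np.empty((0, n_feat))
    return LabeledSamples(
        design=design,
        labels=np.asarray(labels, object),
        meta=pd.DataFrame(meta, columns=["trial", "onset", "end"]),
    )


# ---------------------------------------------------------------------------
# SVMs

@dataclass
class _LinearSvm:
    """Fitted linear decision function over standardized features."""

    weights: np.ndarray
    intercept: float
    mean: np.ndarray
    sd: np.ndarray

    def decision(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.mean) / self.sd
        return Xs @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        # classes_ order is ('rest', 'task'); positive margin => task
        return np.where(self.decision(X) > 0, "task", "rest").astype(object)


@dataclass
class PointwiseSvmModel:
    """Linear SVM over the four instantaneous amplitude features."""

    svm: _LinearSvm
    channels: list[str]

    @property
    def n_features(self) -> int:
        return len(self.svm.weights)


@dataclass
class WindowSvmModel:
    """Linear SVM over flattened full-trial timecourse vectors."""

    svm: _LinearSvm
    channels: list[str]
    window_duration: float
    rate: float

    @property
    def expected_dim(self) -> int:
        return n_samples_in(self.window_duration, self.rate) * 2 * len(self.channels)


def _fit_linear_svm(samples: LabeledSamples, C: float = 1.0,
                    standardize: bool = True) -> _LinearSvm:
    classes = set(samples.labels)
    if samples.n < 2 or len(classes) < 2:
        raise ValueError(
            "SVM fitting needs at least two rows spanning both classes; "
            f"got {samples.n} rows with classes {sorted(classes)}"
        )
    X = samples.design
    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Xs = (X - mean) / sd
    y = (samples.labels == "task").astype(int)
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xs, y)
    return _LinearSvm(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        mean=mean,
        sd=sd,
    )


def fit_svm(
    samples: LabeledSamples,
    kind: str,
    channels: list[str],
    rate: float | None = None,
    window_duration: float | None = None,
    C: float = 1.0,
    standardize: bool = True,
) -> PointwiseSvmModel | WindowSvmModel:
    """Fit the pointwise or window linear SVM on labeled samples."""
    svm = _fit_linear_svm(samples, C=C, standardize=standardize)
    if kind == "pointwise":
        return PointwiseSvmModel(svm=svm, channels=list(channels))
    if kind == "window":
        if rate is None or window_duration is None:
            raise ValueError("window SVM needs rate and window_duration")
        model = WindowSvmModel(svm=svm, channels=list(channels),
                               window_duration=window_duration, rate=rate)
        if model.expected_dim != len(svm.weights):
            raise ValueError(
                f"training rows have {len(svm.weights)} features but the "
                f"{window_duration} s window implies {model.expected_dim}"
            )
        return model
    raise ValueError(f"unknown SVM kind {kind!r}")


def _check_geometry(model, rec: HemoRecording) -> None:
    if list(rec.channels) != list(model.channels):
        raise ValueError(
            f"recording channels {rec.channels} do not match the model's "
            f"training channels {model.channels}"
        )


def predict_svm(
    model: PointwiseSvmModel | WindowSvmModel,
    rec: HemoRecording,
    trials: TrialTable | None = None,
    stride: float = 1.0,
) -> PredictionSeries:
    """Predict task/rest labels.

    Pointwise model: one label per in-trial sample (or per sample of the
    whole recording when ``trials`` is None).  Window model: one label per
    trial; on continuous data (``trials`` None) causal sliding windows of
    the trained duration advance by ``stride`` seconds and each label is
    stamped at the window's final timestamp.
    """
    _check_geometry(model, rec)
    if isinstance(model, PointwiseSvmModel):
        if trials is None:
            X = rec.to_matrix()
            times = rec.times
        else:
            samples = featurize_pointwise(rec, trials)
            X = samples.design
            times = samples.meta["time"].to_numpy()
        if X.shape[1] != model.n_features:
            raise ValueError(
                f"expected {model.n_features} features, got {X.shape[1]}"
            )
        return PredictionSeries(times=times, labels=model.svm.predict(X))

    n_w = n_samples_in(model.window_duration, rec.rate)
    if trials is not None:
        samples = featurize_window(rec, trials, model.window_duration)
        if samples.n and samples.design.shape[1] != model.expected_dim:
            raise ValueError(
                f"expected {model.expected_dim} features, got "
                f"{samples.design.shape[1]}"
            )
        if samples.n == 0:
            return PredictionSeries(times=np.empty(0), labels=np.empty(0, object))
        times = samples.meta["end"].to_numpy()
        return PredictionSeries(times=times,
                                labels=model.svm.predict(samples.design))
    step = max(1, int(round(stride * rec.rate)))
    starts = np.arange(0, rec.n_samples - n_w + 1, step)
    if len(starts) == 0:
        raise ValueError(
            f"recording shorter than the {model.window_duration} s window"
        )
    rows = np.empty((len(starts), model.expected_dim))
    for r, i0 in enumerate(starts):
        rows[r] = np.concatenate([
            rec.get(ch, chromo)[i0:i0 + n_w]
            for ch in rec.channels
            for chromo in CHROMOPHORES
        ])
    times = (starts + n_w - 1) / rec.rate
    return PredictionSeries(times=times, labels=model.svm.predict(rows))
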