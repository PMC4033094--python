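"""Core in-memory containers for fNIRS timeseries and trial annotations.

The pipeline's central currency is the :class:`HemoRecording` — per-channel
ΔHbO/ΔHb concentration-change timeseries (µM) at a fixed sampling rate —
plus the :class:`TrialTable` of task/rest/fixation annotations that defines
training examples and evaluation labels.  :class:`OpticalRecording` holds
two-wavelength optical-density changes, the input to the modified
Beer-Lambert inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

CONDITIONS = ("task", "rest", "fixation")
CHROMOPHORES = ("HbO", "Hb")

#: default bilateral prefrontal channel labels (left / right PFC)
DEFAULT_CHANNELS = ("L", "R")


@dataclass(frozen=True)
class Trial:
    """One annotated interval: ``[onset, onset + duration)`` seconds."""

    onset: float
    duration: float
    condition: str
    block: str = "restricted"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.condition in ("task", "rest") and self.duration <= 0:
            raise ValueError(
                f"{self.condition} trial at {self.onset} s has non-positive "
                f"duration {self.duration}"
            )

    @property
    def end(self) -> float:
        return self.onset + self.duration


class TrialTable:
    """Ordered, non-overlapping trial annotations for one recording block."""

    def __init__(self, trials: Iterable[Trial]):
        trials = list(trials)
        for a, b in zip(trials, trials[1:]):
            if b.onset < a.onset:
                raise ValueError("trials must be sorted by onset")
            if b.onset < a.end - 1e-9:
                raise ValueError(
                    f"trials overlap: [{a.onset}, {a.end}) and "
                    f"[{b.onset}, {b.end})"
                )
        self.trials: list[Trial] = trials

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i: int) -> Trial:
        return self.trials[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, TrialTable) and self.trials == other.trials

    def of_condition(self, *conditions: str) -> list[Trial]:
        return [t for t in self.trials if t.condition in conditions]

    @property
    def non_fixation(self) -> list[Trial]:
        return self.of_condition("task", "rest")

    @property
    def span(self) -> float:
        """Total extent in seconds (end of last trial)."""
        return max((t.end for t in self.trials), default=0.0)

    def relabeled(self, conditions: Sequence[str]) -> "TrialTable":
        """Copy with the task/rest trials' conditions replaced in order.

        Fixation entries are untouched.  Used for permutation-null studies.
        """
        nf = self.non_fixation
        if len(conditions) != len(nf):
            raise ValueError(
                f"need {len(nf)} conditions, got {len(conditions)}"
            )
        it = iter(conditions)
        out = [
            t if t.condition == "fixation" else replace(t, condition=next(it))
            for t in self.trials
        ]
        return TrialTable(out)


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("each series must be one-dimensional")
    return arr


@dataclass
class HemoRecording:
    """Multichannel ΔHbO/ΔHb timeseries in µM.

    ``series`` maps channel label → {"HbO": array, "Hb": array}; all series
    share one length and sampling rate.  ``provenance`` is an append-only
    log of processing steps.
    """

    rate: float
    series: dict[str, dict[str, np.ndarray]]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        lengths = set()
        for ch, by_chromo in self.series.items():
            for chromo in CHROMOPHORES:
                if chromo not in by_chromo:
                    raise ValueError(f"channel {ch!r} missing {chromo} series")
                by_chromo[chromo] = _as_series(by_chromo[chromo])
                lengths.add(len(by_chromo[chromo]))
        if len(lengths) > 1:
            raise ValueError(f"series lengths differ: {sorted(lengths)}")

    @property
    def channels(self) -> list[str]:
        return list(self.series)

    @property
    def n_samples(self) -> int:
        first = next(iter(self.series.values()))
        return len(first["HbO"])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def get(self, channel: str, chromophore: str) -> np.ndarray:
        try:
            by_chromo = self.series[channel]
        except KeyError:
            raise KeyError(
                f"channel {channel!r} not in recording "
                f"(have {self.channels})"
            ) from None
        return by_chromo[chromophore]

    def copy(self) -> "HemoRecording":
        return HemoRecording(
            rate=self.rate,
            series={
                ch: {c: arr.copy() for c, arr in by.items()}
                for ch, by in self.series.items()
            },
            provenance=[dict(p) for p in self.provenance],
        )

    def log(self, step: str, **params) -> None:
        """Append a provenance entry for a processing step."""
        self.provenance.append({"step": step, "params": params})

    def column_names(self) -> list[str]:
        return [f"{ch}_{c}" for ch in self.channels for c in CHROMOPHORES]

    def to_matrix(self) -> np.ndarray:
        """(n_samples, n_channels×2) matrix in ``column_names`` order."""
        return np.column_stack(
            [self.series[ch][c] for ch in self.channels for c in CHROMOPHORES]
        )


@dataclass
class OpticalRecording:
    """Two-wavelength ΔOD (unitless) per channel, pre-MBLL.

    ``od`` maps channel label → array of shape (n_samples, 2), column i
    being the optical-density change at ``optics.wavelengths[i]``.
    """

    rate: float
    od: dict[str, np.ndarray]
    optics: "OpticsParams"  # noqa: F821 — forward ref, defined in params
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        lengths = set()
        for ch, arr in self.od.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(
                    f"channel {ch!r}: ΔOD must have shape (n, 2), "
                    f"got {arr.shape}"
                )
            self.od[ch] = arr
            lengths.add(arr.shape[0])
        if len(lengths) > 1:
            raise ValueError(f"series lengths differ: {sorted(lengths)}")

    @property
    def channels(self) -> list[str]:
        return list(self.od)

    @property
    def n_samples(self) -> int:
        return next(iter(self.od.values())).shape[0]
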