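"""Synthetic participant generator for bilateral prefrontal fNIRS.

Emulates the block-design workload experiment the classifiers target:
6.25 Hz sampling over two channels (left/right PFC) × two chromophores,
a task-evoked hemodynamic response (onset lag 1–2 s, peak 4–8 s after
onset) convolved with the task boxcar, anticorrelated Hb, sinusoidal
physiological noise (cardiac / respiration / Mayer waves), random-walk
drift, white noise, and common-mode motion artifacts.  Everything is
driven by a single integer seed; identical seeds give bit-identical
datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.stats import gamma as gamma_dist

from .params import DEFAULT_RATE, HdrParams, MotionParams, NoiseParams, OpticsParams
from .recording import (
    DEFAULT_CHANNELS,
    HemoRecording,
    OpticalRecording,
    Trial,
    TrialTable,
)

#: duration (s) of each segment of the realistic paradigm: 3.5 min rest,
#: 3.5 min task, 3.5 min post-task rest
REALISTIC_SEGMENT = 210.0

_GAMMA_SHAPE = 6.0  # main lobe
_UNDERSHOOT_SHAPE = 12.0  # delayed lobe, mode at 2× time_to_peak
_SPIKE_TAU = 0.5  # s, exponential decay of motion spikes


def generate_paradigm(
    kind: str,
    n_task: int = 9,
    n_rest: int = 9,
    trial_dur: float = 30.0,
    fixation_dur: float = 30.0,
    seed: int = 0,
    block: str = "restricted",
) -> TrialTable:
    """Build a trial table for a training block or the realistic sample.

    ``training_block``: ``n_task`` task and ``n_rest`` rest trials of
    ``trial_dur`` s in seeded-shuffled order, consecutive trials separated
    by a ``fixation_dur`` s fixation cross (no trailing fixation).
    ``realistic``: three 210 s segments — rest, task, rest — with no
    fixation (counts and durations are ignored).
    """
    if kind == "realistic":
        entries = [
            Trial(0.0, REALISTIC_SEGMENT, "rest", block="realistic"),
            Trial(REALISTIC_SEGMENT, REALISTIC_SEGMENT, "task", block="realistic"),
            Trial(2 * REALISTIC_SEGMENT, REALISTIC_SEGMENT, "rest", block="realistic"),
        ]
        return TrialTable(entries)
    if kind != "training_block":
        raise ValueError(f"unknown paradigm kind {kind!r}")
    if n_task < 0 or n_rest < 0 or n_task + n_rest == 0:
        raise ValueError("training block needs at least one trial")
    if trial_dur <= 0 or fixation_dur <= 0:
        raise ValueError("trial and fixation durations must be positive")
    conditions = ["task"] * n_task + ["rest"] * n_rest
    rng = np.random.default_rng(seed)
    rng.shuffle(conditions)
    entries: list[Trial] = []
    t = 0.0
    for i, cond in enumerate(conditions):
        entries.append(Trial(t, trial_dur, cond, block=block))
        t += trial_dur
        if i < len(conditions) - 1:
            entries.append(Trial(t, fixation_dur, "fixation", block=block))
            t += fixation_dur
    return TrialTable(entries)


def hdr_kernel(params: HdrParams, rate: float = DEFAULT_RATE) -> np.ndarray:
    """Unit-peak hemodynamic response kernel sampled at ``rate``.

    Single-gamma main lobe (mode at ``time_to_peak`` after the response
    starts) minus a smaller, later gamma undershoot, the whole shifted by
    ``onset_lag`` and normalized to peak 1.  Zero before the onset lag;
    decays below 5% of peak by the kernel end.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    tp = params.time_to_peak
    lag = params.onset_lag
    t_end = lag + 5.0 * tp
    n = int(round(t_end * rate)) + 1
    t = np.arange(n) / rate
    s = t - lag
    main = np.zeros(n)
    pos = s > 0
    main[pos] = gamma_dist.pdf(
        s[pos], a=_GAMMA_SHAPE, scale=tp / (_GAMMA_SHAPE - 1)
    )
    main /= main.max()
    kernel = main
    if params.undershoot_fraction > 0:
        # the undershoot lobe starts at the main peak (so it cannot move
        # the peak sample) and bottoms out at 2× time_to_peak
        su = s - tp
        under = np.zeros(n)
        upos = su > 0
        under[upos] = gamma_dist.pdf(
            su[upos], a=_UNDERSHOOT_SHAPE,
            scale=tp / (_UNDERSHOOT_SHAPE - 1),
        )
        under /= under.max()
        kernel = main - params.undershoot_fraction * under
    kernel = kernel / kernel.max()
    # compact support: zero the asymptotic tail (below 1e-4 of peak) so a
    # trial's response dies out completely before the next trial begins
    significant = np.nonzero(np.abs(kernel) >= 1e-4)[0]
    if len(significant):
        kernel[significant[-1] + 1:] = 0.0
    return kernel


def _task_boxcar(trials: TrialTable, n: int, rate: float) -> np.ndarray:
    box = np.zeros(n)
    t = np.arange(n) / rate
    for trial in trials.of_condition("task"):
        box[(t >= trial.onset) & (t < trial.end)] = 1.0
    return box


def _clean_response(
    trials: TrialTable, n: int, rate: float, hdr: HdrParams
) -> np.ndarray:
    """Noise-free ΔHbO (µM, unit channel gain): boxcar ⊛ kernel, scaled so
    sustained activation plateaus at ``hbo_amplitude``."""
    kernel = hdr_kernel(hdr, rate)
    box = _task_boxcar(trials, n, rate)
    resp = np.convolve(box, kernel)[:n]
    ksum = kernel.sum()
    if ksum > 0:
        resp = resp / ksum
    return hdr.hbo_amplitude * resp


def _drift(rng: np.random.Generator, n: int, rate: float,
           cutoff: float, sd: float) -> np.ndarray:
    """Gaussian random walk low-passed below ``cutoff``, rescaled to ``sd``."""
    if sd == 0 or n < 30:
        return np.zeros(n)
    walk = np.cumsum(rng.standard_normal(n))
    ny = rate / 2
    b, a = sps.butter(2, cutoff / ny)
    low = sps.filtfilt(b, a, walk)
    s = low.std()
    if s == 0:
        return np.zeros(n)
    return sd * (low - low.mean()) / s


def _sinusoid(rng: np.random.Generator, n: int, rate: float,
              freq: float, amp: float) -> np.ndarray:
    if amp == 0:
        return np.zeros(n)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / rate
    return amp * np.sin(2 * np.pi * freq * t + phase)


def _motion_series(rng: np.random.Generator, n: int, rate: float,
                   motion: MotionParams) -> np.ndarray:
    """One channel's motion-artifact trace (spikes + baseline shifts)."""
    out = np.zeros(n)
    minutes = n / rate / 60.0
    t = np.arange(n) / rate
    n_spikes = rng.poisson(motion.spike_rate * minutes)
    for _ in range(n_spikes):
        t0 = rng.uniform(0, n / rate)
        sign = rng.choice([-1.0, 1.0])
        mask = t >= t0
        out[mask] += (
            sign * motion.spike_amplitude
            * np.exp(-(t[mask] - t0) / _SPIKE_TAU)
        )
    n_shifts = rng.poisson(motion.shift_rate * minutes)
    for _ in range(n_shifts):
        t0 = rng.uniform(0, n / rate)
        sign = rng.choice([-1.0, 1.0])
        out[t >= t0] += sign * motion.shift_amplitude
    return out


@dataclass
class ParticipantDataset:
    """All blocks of one synthetic participant.

    ``truth`` holds the noise-free, motion-free ΔHbO/ΔHb per block — the
    ground truth against which motion correction is scored.
    """

    recordings: dict[str, HemoRecording]
    trials: dict[str, TrialTable]
    truth: dict[str, HemoRecording]
    seed: int
    optical: dict[str, OpticalRecording] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rates = {rec.rate for rec in self.recordings.values()}
        if len(rates) > 1:
            raise ValueError(f"blocks have mismatched rates: {sorted(rates)}")
        for block, rec in self.recordings.items():
            if rec.duration < self.trials[block].span - 1e-9:
                raise ValueError(
                    f"block {block!r}: recording ({rec.duration:.1f} s) "
                    f"shorter than its trial table "
                    f"({self.trials[block].span:.1f} s)"
                )

    @property
    def blocks(self) -> list[str]:
        return list(self.recordings)


def generate_participant(
    paradigms: dict[str, TrialTable],
    hdr: HdrParams = HdrParams(),
    noise: NoiseParams = NoiseParams(),
    motion_by_block: dict[str, MotionParams] | None = None,
    rate: float = DEFAULT_RATE,
    seed: int = 0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> ParticipantDataset:
    """Simulate one participant's recordings for the given blocks.

    Per block and channel, ΔHbO is the task boxcar convolved with the HDR
    kernel (left gain 1, right gain 1 − lateralization), ΔHb its negative
    scalar multiple, plus seeded sinusoidal physiological noise, low-passed
    random-walk drift, white noise, and per-block motion artifacts (added
    common-mode to HbO and Hb).  Blocks without an entry in
    ``motion_by_block`` get no motion — the restricted-mobility default.
    """
    if not paradigms:
        raise ValueError("paradigms must be non-empty")
    motion_by_block = motion_by_block or {}
    gains = {ch: 1.0 for ch in channels}
    if len(channels) >= 2:
        for ch in channels[1:]:
            gains[ch] = 1.0 - hdr.lateralization
    root = np.random.SeedSequence(seed)
    block_seeds = root.spawn(len(paradigms))
    recordings: dict[str, HemoRecording] = {}
    truths: dict[str, HemoRecording] = {}
    for (block, table), ss in zip(paradigms.items(), block_seeds):
        n = int(math.ceil(table.span * rate))
        resp = _clean_response(table, n, rate, hdr)
        motion = motion_by_block.get(block, MotionParams.none())
        series: dict[str, dict[str, np.ndarray]] = {}
        clean: dict[str, dict[str, np.ndarray]] = {}
        ch_seeds = ss.spawn(len(channels))
        for ch, ch_ss in zip(channels, ch_seeds):
            rng = np.random.default_rng(ch_ss)
            hbo_clean = gains[ch] * resp
            hb_clean = hdr.hb_to_hbo_ratio * hbo_clean
            clean[ch] = {"HbO": hbo_clean.copy(), "Hb": hb_clean.copy()}
            hbo = hbo_clean.copy()
            hb = hb_clean.copy()
            for chromo_series in (hbo, hb):
                for freq, amp in (noise.cardiac, noise.respiration,
                                  noise.mayer):
                    chromo_series += _sinusoid(rng, n, rate, freq, amp)
                chromo_series += _drift(rng, n, rate, *noise.drift)
                if noise.white_sd > 0:
                    chromo_series += noise.white_sd * rng.standard_normal(n)
            if motion.common_mode:
                art = _motion_series(rng, n, rate, motion)
                hbo += art
                hb += art
            else:
                hbo += _motion_series(rng, n, rate, motion)
                hb += _motion_series(rng, n, rate, motion)
            series[ch] = {"HbO": hbo, "Hb": hb}
        rec = HemoRecording(rate=rate, series=series)
        rec.log("simulate", block=block, seed=seed)
        recordings[block] = rec
        truths[block] = HemoRecording(rate=rate, series=clean)
    return ParticipantDataset(
        recordings=recordings,
        trials=dict(paradigms),
        truth=truths,
        seed=seed,
    )


def forward_optics(
    hemo: HemoRecording, optics: OpticsParams = OpticsParams()
) -> OpticalRecording:
    """Map ΔHbO/ΔHb (µM) to two-wavelength ΔOD — the MBLL forward model.

    ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_Hb(λ)·ΔHb] · L · DPF(λ), concentrations
    converted to mol/L.  Exact inverse of :func:`nirsbci.mbll.mbll_invert`.
    """
    E = optics.extinction_array
    scale = optics.separation * np.asarray(optics.dpf)
    od: dict[str, np.ndarray] = {}
    for ch in hemo.channels:
        conc = np.column_stack(
            [hemo.get(ch, "HbO"), hemo.get(ch, "Hb")]
        ) * 1e-6  # µM -> M
        od[ch] = (conc @ E.T) * scale
    return OpticalRecording(
        rate=hemo.rate,
        od=od,
        optics=optics,
        provenance=[dict(p) for p in hemo.provenance]
        + [{"step": "forward_optics",
            "params": {"wavelengths": list(optics.wavelengths)}}],
    )


def sample_participant_hdr(
    base: HdrParams, rng: np.random.Generator
) -> HdrParams:
    """Draw one participant's HDR variant from the population model:
    lognormal(0, 0.25) amplitude gain and onset lag uniform in [1, 2] s."""
    gain = float(rng.lognormal(mean=0.0, sigma=0.25))
    lag = float(rng.uniform(1.0, 2.0))
    return replace(
        base,
        hbo_amplitude=base.hbo_amplitude * gain,
        onset_lag=lag,
    )
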