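"""Deterministic miniature datasets for tests and documentation.

``tiny_clean``: two noise-free participants (restricted block only).
``tiny_motion``: the same geometry with strong common-mode motion spikes.
``realistic_demo``: one continuous 10.5-minute rest/task/rest block.
"""

from __future__ import annotations

from pathlib import Path

from .params import HdrParams, MotionParams, NoiseParams
from .io import write_recording, write_trials
from .simulate import ParticipantDataset, generate_paradigm, generate_participant

FIXTURE_NAMES = ("tiny_clean", "tiny_motion", "realistic_demo")


def _tiny(seed: int, motion: MotionParams,
          n_participants: int = 2) -> list[ParticipantDataset]:
    table = generate_paradigm("training_block", n_task=3, n_rest=3,
                              trial_dur=30.0, fixation_dur=30.0, seed=seed)
    return [
        generate_participant(
            {"restricted": table},
            hdr=HdrParams(),
            noise=NoiseParams.silent(),
            motion_by_block={"restricted": motion},
            seed=seed + i,
        )
        for i in range(n_participants)
    ]


def build_fixture(name: str, seed: int = 0) -> list[ParticipantDataset]:
    """Generate a named fixture in memory."""
    if name == "tiny_clean":
        return _tiny(seed, MotionParams.none())
    if name == "tiny_motion":
        return _tiny(seed, MotionParams(spike_rate=6.0, spike_amplitude=8.0,
                                        shift_rate=1.0, shift_amplitude=4.0))
    if name == "realistic_demo":
        table = generate_paradigm("realistic")
        return [
            generate_participant(
                {"realistic": table},
                hdr=HdrParams(),
                noise=NoiseParams(),
                seed=seed,
            )
        ]
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def make_fixture(name: str, out_dir, seed: int = 0,
                 force: bool = False) -> list[Path]:
    """Write a named fixture's recordings and trial tables to ``out_dir``."""
    datasets = build_fixture(name, seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for i, ds in enumerate(datasets):
        for block, rec in ds.recordings.items():
            rec_path = out_dir / f"{name}_p{i}_{block}.tsv"
            trial_path = out_dir / f"{name}_p{i}_{block}_trials.tsv"
            write_recording(rec, rec_path, force=force)
            write_trials(ds.trials[block], trial_path, force=force)
            written.extend([rec_path, trial_path])
    return written
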