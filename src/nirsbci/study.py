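"""End-to-end synthetic study: simulate a cohort, run the three
experiments (restricted CV, unrestricted CV, restricted-trained realistic
test) for the three models, and aggregate group statistics.

The report table mirrors the usual comparative layout: one row per
(experiment, model) with mean/SD accuracy, the one-tailed t against
chance, the number of participants individually significant, and — for
the thresholding detector — onset-latency summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StudyConfig
from .evaluation import (
    MODEL_KINDS,
    LatencySummary,
    compare_models,
    crossvalidate,
    evaluate_realistic,
    fit_model,
    group_stats,
    latency_stats,
    per_participant_significance,
)
from .preprocess import preprocess_pipeline
from .recording import HemoRecording, TrialTable
from .simulate import (
    ParticipantDataset,
    generate_paradigm,
    generate_participant,
    sample_participant_hdr,
)

EXPERIMENTS = ("restricted", "unrestricted", "realistic")


@dataclass
class ParticipantRun:
    """One simulated participant, preprocessed and ready to evaluate."""

    dataset: ParticipantDataset
    processed: dict[str, HemoRecording]
    trials: dict[str, TrialTable]


def simulate_participant(config: StudyConfig,
                         seed_seq: np.random.SeedSequence) -> ParticipantRun:
    """Simulate and preprocess one participant's three blocks."""
    rng = np.random.default_rng(seed_seq)
    hdr = (sample_participant_hdr(config.hdr, rng)
           if config.participant_variability else config.hdr)
    seeds = rng.integers(0, 2**31, size=3)
    tables = {
        "restricted": generate_paradigm(
            "training_block", config.n_task, config.n_rest,
            config.trial_dur, config.fixation_dur,
            seed=int(seeds[0]), block="restricted"),
        "unrestricted": generate_paradigm(
            "training_block", config.n_task, config.n_rest,
            config.trial_dur, config.fixation_dur,
            seed=int(seeds[1]), block="unrestricted"),
        "realistic": generate_paradigm("realistic"),
    }
    dataset = generate_participant(
        tables,
        hdr=hdr,
        noise=config.noise,
        motion_by_block={
            "restricted": config.motion_restricted,
            "unrestricted": config.motion_unrestricted,
        },
        rate=config.rate,
        seed=int(seeds[2]),
    )
    processed = {
        block: preprocess_pipeline(rec, config.filters)
        for block, rec in dataset.recordings.items()
    }
    if config.permute_labels:
        for block in ("restricted", "unrestricted"):
            conds = [t.condition for t in tables[block].non_fixation]
            rng.shuffle(conds)
            tables[block] = tables[block].relabeled(conds)
    return ParticipantRun(dataset=dataset, processed=processed,
                          trials=tables)


@dataclass
class StudyReport:
    table: pd.DataFrame
    per_participant: pd.DataFrame
    latency: dict[str, LatencySummary]
    comparisons: pd.DataFrame
    config: StudyConfig

    def mean_accuracy(self, experiment: str, model: str) -> float:
        row = self.table[(self.table.experiment == experiment)
                         & (self.table.model == model)]
        return float(row["mean_acc"].iloc[0])


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full three-model × three-experiment synthetic study."""
    root = np.random.SeedSequence(config.seed)
    rows = []
    for pid, ss in enumerate(root.spawn(config.n_participants)):
        run = simulate_participant(config, ss)
        for block in ("restricted", "unrestricted"):
            for kind in MODEL_KINDS:
                cv = crossvalidate(
                    run.processed[block], run.trials[block], kind,
                    k=config.k, window_duration=config.window_duration,
                )
                lat = [v for v in cv.latencies if v is not None]
                rows.append({
                    "participant": pid,
                    "experiment": block,
                    "model": kind,
                    "accuracy": cv.accuracy,
                    "n_trials_correct": cv.n_trials_correct,
                    "n_trials": len(cv.trial_outcomes),
                    "significant": per_participant_significance(
                        cv.n_trials_correct, len(cv.trial_outcomes),
                        config.chance, config.alpha),
                    "mean_latency": float(np.mean(lat)) if lat else None,
                })
        for kind in MODEL_KINDS:
            model = fit_model(kind, run.processed["restricted"],
                              run.trials["restricted"],
                              config.window_duration)
            rr = evaluate_realistic(model, run.processed["realistic"],
                                    run.trials["realistic"],
                                    stride=config.stride)
            rows.append({
                "participant": pid,
                "experiment": "realistic",
                "model": kind,
                "accuracy": rr.accuracy,
                "n_trials_correct": int(sum(rr.segment_outcomes)),
                "n_trials": len(rr.segment_outcomes),
                "significant": per_participant_significance(
                    int(sum(rr.segment_outcomes)),
                    len(rr.segment_outcomes),
                    config.chance, config.alpha),
                "mean_latency": rr.latency,
            })
    per_participant = pd.DataFrame(rows)

    group_rows = []
    latency: dict[str, LatencySummary] = {}
    for experiment in EXPERIMENTS:
        for kind in MODEL_KINDS:
            sub = per_participant[
                (per_participant.experiment == experiment)
                & (per_participant.model == kind)
            ]
            gs = group_stats(sub["accuracy"], config.chance)
            group_rows.append({
                "experiment": experiment,
                "model": kind,
                "mean_acc": gs.mean,
                "sd_acc": gs.sd,
                "t": gs.t,
                "df": gs.df,
                "p": gs.p,
                "n_significant": int(sub["significant"].sum()),
                "N": gs.n,
            })
            if kind == "threshold":
                lat = list(sub["mean_latency"])
                if any(v is not None for v in lat):
                    latency[experiment] = latency_stats(lat)

    comp_rows = []
    for experiment in EXPERIMENTS:
        for a in MODEL_KINDS:
            for b in MODEL_KINDS:
                if a >= b:
                    continue
                sub = per_participant[per_participant.experiment == experiment]
                acc_a = sub[sub.model == a].sort_values("participant")["accuracy"]
                acc_b = sub[sub.model == b].sort_values("participant")["accuracy"]
                if len(acc_a) < 2:
                    continue
                cmp = compare_models(acc_a.to_numpy(), acc_b.to_numpy())
                comp_rows.append({
                    "experiment": experiment, "model_a": a, "model_b": b,
                    "t": cmp.t, "df": cmp.df, "p": cmp.p,
                    "mean_diff": cmp.mean_diff,
                })

    return StudyReport(
        table=pd.DataFrame(group_rows),
        per_participant=per_participant,
        latency=latency,
        comparisons=pd.DataFrame(comp_rows),
        config=config,
    )
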