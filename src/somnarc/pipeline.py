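"""End-to-end orchestration: simulate -> detect -> QC -> split -> summarize.

The study runner drives the whole chain in memory one participant at a
time (a full-week raw stream is large; per-minute products are not) and
returns tidy DataFrames.  ``RunManifest`` records config hash, seeds and
outputs so a rerun with the same manifest reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import participant_means, summarize_groups, weekday_weekend_contrast
from .config import PipelineConfig
from .detection import (ParticipantDetection, ParticipantUnusable, PowerSeries,
                        detect_sleep, detect_sleep_from_power)
from .qc import qc_recording, split_cohort
from .synthetic import CohortModel, generate_cohort, participants_table, truth_table

__all__ = ["run_synthetic_study", "under60_sex_duration_gap",
           "mean_weekend_contrast", "RunManifest", "run_pipeline"]


def _detection_for(recordings, i, cfg: PipelineConfig, resolution: str) -> ParticipantDetection:
    truth = recordings._truths[i]
    if resolution == "minute":
        values = recordings.minute_power(i)
        power = PowerSeries(start_time=truth.start_time, values=values,
                            participant_id=truth.participant_id)
        return detect_sleep_from_power(power, cfg)
    if resolution == "raw":
        return detect_sleep(recordings[i], cfg)
    raise ValueError("resolution must be 'minute' or 'raw'")


def run_synthetic_study(model: CohortModel, cfg: PipelineConfig | None = None,
                        resolution: str = "minute") -> dict:
    """Generate a cohort and run detection + QC over every participant.

    Returns a dict of DataFrames: ``nights`` (detected adjusted episodes,
    all participants), ``participants`` (demographics, wake activity, QC
    outcome), ``reports`` (self-reports) plus the ``truths`` list.
    """
    cfg = cfg or PipelineConfig()
    recordings, truths, reports = generate_cohort(model)
    night_frames = []
    part_rows = []
    for i, truth in enumerate(truths):
        reasons: tuple = ()
        wake_activity = float("nan")
        n_nights = 0
        try:
            det = _detection_for(recordings, i, cfg, resolution)
        except ParticipantUnusable as exc:
            passed = False
            reasons = ("short_record",) if exc.reason != "structural_anomaly" \
                else ("structural_anomaly",)
        else:
            qc = qc_recording(det, cfg)
            passed, reasons = qc.passed, qc.reason_codes
            wake_activity = det.wake_activity
            n_nights = len(det.episodes)
            frame = det.nights_frame()
            if len(frame):
                night_frames.append(frame)
        part_rows.append({
            "participant_id": truth.participant_id, "age": truth.age,
            "sex": truth.sex, "age_bin": truth.age_bin,
            "wake_activity": wake_activity, "n_nights": n_nights,
            "qc_pass": passed, "qc_reasons": ";".join(reasons),
        })
    nights = pd.concat(night_frames, ignore_index=True) if night_frames \
        else pd.DataFrame(columns=["participant_id", "night_index", "date", "dow",
                                   "onset_min", "wake_min", "duration_min", "qc_flags"])
    participants = pd.DataFrame(part_rows)
    return {"nights": nights, "participants": participants,
            "reports": reports, "truths": truths}


def _passing(study: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    participants = study["participants"]
    ok = participants[participants["qc_pass"]]
    nights = study["nights"]
    nights = nights[nights["participant_id"].isin(ok["participant_id"])]
    return nights, ok


def under60_sex_duration_gap(study: dict) -> tuple[float, int]:
    """XX-minus-XY mean adjusted sleep duration among under-60, minutes.

    Participant-level means over QC-passed participants.  Returns
    (gap, n participants contributing).
    """
    nights, participants = _passing(study)
    under60 = participants[participants["age"] < 60]
    means = participant_means(nights).merge(under60, on="participant_id")
    xx = means.loc[means["sex"] == "XX", "duration"]
    xy = means.loc[means["sex"] == "XY", "duration"]
    return float(xx.mean() - xy.mean()), int(len(means))


def mean_weekend_contrast(study: dict, max_age: int = 59) -> tuple[float, int]:
    """Mean per-participant weekend-minus-weekday duration, minutes."""
    nights, participants = _passing(study)
    young = participants[participants["age"] <= max_age]
    df = nights[nights["participant_id"].isin(young["participant_id"])].copy()
    df["is_weekend"] = df["dow"].isin(("Sat", "Sun"))
    per = df.pivot_table(index="participant_id", columns="is_weekend",
                         values="duration_min", aggfunc="mean")
    per = per.rename(columns={False: "weekday", True: "weekend"}).dropna()
    diffs = per["weekend"] - per["weekday"]
    return float(diffs.mean()), int(diffs.size)


# ---------------------------------------------------------------------------
# manifest-driven pipeline for the CLI

STAGES = ("simulate", "detect", "qc", "split", "summarize")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list
    outputs: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _hash_config(cfg: PipelineConfig, model: CohortModel) -> str:
    blob = repr((sorted(dataclasses.asdict(cfg).items()),
                 sorted((k, str(v)) for k, v in dataclasses.asdict(model).items())))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(model: CohortModel, cfg: PipelineConfig, out_dir,
                 stages: tuple = STAGES, seed: int | None = None,
                 resolution: str = "minute") -> RunManifest:
    """Execute the requested stages in order, writing tidy CSVs.

    Stage outputs: ``participants.csv``, ``truth.csv``,
    ``self_reports.csv``, ``sleep_table.csv``, ``qc.csv``,
    ``splits.csv``, ``group_summaries.csv``, ``contrasts.csv`` and
    ``manifest.json`` under ``out_dir``.  Missing upstream outputs
    raise, naming the stage.
    """
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        model = dataclasses.replace(model, seed=seed)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    manifest = RunManifest(config_hash=_hash_config(cfg, model),
                           seed=model.seed, stages=list(stages))

    study = None
    for stage in stages:
        t0 = time.time()
        if stage == "simulate":
            _, truths, reports = generate_cohort(model)
            participants_table(truths).to_csv(out / "participants.csv", index=False)
            truth_table(truths).to_csv(out / "truth.csv", index=False)
            reports.to_csv(out / "self_reports.csv", index=False)
            manifest.outputs[stage] = ["participants.csv", "truth.csv", "self_reports.csv"]
        elif stage == "detect":
            study = run_synthetic_study(model, cfg, resolution=resolution)
            study["nights"].to_csv(out / "sleep_table.csv", index=False)
            manifest.outputs[stage] = ["sleep_table.csv"]
        elif stage == "qc":
            if study is None:
                raise RuntimeError("stage 'qc' requires stage 'detect' outputs")
            study["participants"].to_csv(out / "qc.csv", index=False)
            manifest.outputs[stage] = ["qc.csv"]
        elif stage == "split":
            if study is None:
                raise RuntimeError("stage 'split' requires stage 'detect' outputs")
            passing = study["participants"][study["participants"]["qc_pass"]].copy()
            passing["split"] = split_cohort(passing, seed=model.seed)
            passing[["participant_id", "sex", "age_bin", "split"]] \
                .to_csv(out / "splits.csv", index=False)
            manifest.outputs[stage] = ["splits.csv"]
        elif stage == "summarize":
            if study is None:
                raise RuntimeError("stage 'summarize' requires stage 'detect' outputs")
            nights, participants = _passing(study)
            summarize_groups(nights, participants) \
                .to_csv(out / "group_summaries.csv", index=False)
            weekday_weekend_contrast(nights, participants) \
                .to_csv(out / "contrasts.csv", index=False)
            manifest.outputs[stage] = ["group_summaries.csv", "contrasts.csv"]
        manifest.timestamps[stage] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
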