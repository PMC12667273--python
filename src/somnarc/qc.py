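"""Cohort quality control and the matched discovery/replication split.

Exclusion rules: duplicate recordings per participant, structural
anomalies (excess data gaps or a flat worn axis), more than four nights
without a detectable sleep episode, off-wrist time outside the
first/last day or clipping the protected nights, and recordings that
span a daylight-saving clock change.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .detection import ParticipantDetection

__all__ = ["QCResult", "ParticipantRecord", "qc_recording", "deduplicate", "split_cohort"]

REASON_CODES = (
    "duplicate", "structural_anomaly", "missing_days_gt4",
    "midweek_wristoff", "dst_overlap", "short_record",
)

MINUTES_PER_DAY = 1440
#: structural-anomaly bound on the fraction of gap-flagged samples
MAX_GAP_FRACTION = 0.20


@dataclass
class QCResult:
    participant_id: str
    passed: bool
    reason_codes: tuple = ()

    def __post_init__(self) -> None:
        self.reason_codes = tuple(sorted(self.reason_codes))
        unknown = set(self.reason_codes) - set(REASON_CODES)
        if unknown:
            raise ValueError(f"unknown QC reason codes: {sorted(unknown)}")
        if self.passed != (len(self.reason_codes) == 0):
            raise ValueError("pass must hold exactly when reason_codes is empty")


@dataclass
class ParticipantRecord:
    """Demographics, detected nights, QC status and self-report."""

    participant_id: str
    age: int
    age_bin: str
    sex: str
    nights: pd.DataFrame | None = None
    qc: QCResult | None = None
    self_report: object = None
    split: str = "unassigned"
    extras: dict = field(default_factory=dict)


def qc_recording(det: ParticipantDetection, cfg: PipelineConfig) -> QCResult:
    """Apply the recording-level exclusion rules to one participant.

    Off-wrist minutes are allowed only on the first and last calendar
    day and must not clip a detected episode; more than four missing
    nights, a DST-spanning recording, a short recording, or structural
    anomalies all fail QC.
    """
    reasons: set[str] = set()
    worn = det.worn
    n = worn.size

    if n < int(7.5 * MINUTES_PER_DAY):
        reasons.add("short_record")

    off_idx = np.flatnonzero(~worn)
    day2_start = MINUTES_PER_DAY
    day7_end = 7 * MINUTES_PER_DAY
    if np.any((off_idx >= day2_start) & (off_idx < min(day7_end, n))):
        reasons.add("midweek_wristoff")
    else:
        # edge-day off-wrist must not clip any detected episode
        for ep in det.episodes:
            if np.any(~worn[max(ep.onset_idx, 0):min(ep.wake_idx, n)]):
                reasons.add("midweek_wristoff")
                break

    if det.n_nights_missing > 4:
        reasons.add("missing_days_gt4")

    end_time = det.start_time + pd.Timedelta(minutes=n)
    if det.start_time.utcoffset() != end_time.utcoffset():
        reasons.add("dst_overlap")

    if det.gap_fraction > MAX_GAP_FRACTION or det.constant_axis_worn:
        reasons.add("structural_anomaly")

    return QCResult(participant_id=det.participant_id,
                    passed=not reasons, reason_codes=tuple(reasons))


def deduplicate(records: list) -> list:
    """At most one record per participant id.

    The record with more detected nights wins; ties go to the earlier
    ``start_time``.  Order of the surviving records follows first
    appearance, so the operation is stable.
    """
    best: dict[str, object] = {}
    order: list[str] = []
    for rec in records:
        pid = rec.participant_id
        n_nights = len(rec.nights) if getattr(rec, "nights", None) is not None \
            else len(getattr(rec, "episodes", []))
        start = getattr(rec, "start_time", None) or rec.extras.get("start_time")
        key = (-n_nights, start)
        if pid not in best:
            best[pid] = (key, rec)
            order.append(pid)
        elif key < best[pid][0]:
            best[pid] = (key, rec)
    return [best[pid][1] for pid in order]


def _stable_hash(text: str) -> int:
    return int(hashlib.md5(text.encode()).hexdigest()[:8], 16)


def split_cohort(participants: pd.DataFrame, seed: int) -> pd.Series:
    """Random half-split stratified by sex and age bin.

    Returns a Series (index-aligned to ``participants``) of
    ``"discovery"``/``"replication"`` labels.  Within each stratum the
    two arms differ in size by at most one; the stratum's odd record
    goes to the globally smaller arm so far, ties broken by a
    deterministic hash of its participant id.  Deterministic given
    ``seed``.
    """
    if len(participants) == 0:
        raise ValueError("cannot split an empty cohort")
    for col in ("participant_id", "sex", "age_bin"):
        if col not in participants.columns:
            raise ValueError(f"participants table lacks column {col!r}")
    rng = np.random.default_rng(seed)
    labels = pd.Series("unassigned", index=participants.index, dtype=object)
    totals = {"discovery": 0, "replication": 0}
    strata = participants.groupby(["sex", "age_bin"], sort=True).groups
    for key in sorted(strata):
        idx = participants.loc[strata[key]].sort_values("participant_id").index.to_numpy()
        perm = idx[rng.permutation(idx.size)]
        half = idx.size // 2
        labels[perm[:half]] = "discovery"
        labels[perm[half: 2 * half]] = "replication"
        totals["discovery"] += half
        totals["replication"] += half
        if idx.size % 2:
            extra = perm[-1]
            if totals["discovery"] < totals["replication"]:
                arm = "discovery"
            elif totals["replication"] < totals["discovery"]:
                arm = "replication"
            else:
                pid = str(participants.loc[extra, "participant_id"])
                arm = "discovery" if _stable_hash(pid) % 2 == 0 else "replication"
            labels[extra] = arm
            totals[arm] += 1
    return labels
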