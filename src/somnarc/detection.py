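"""Major-sleep-episode detection from raw wrist acceleration.

The pipeline mirrors the published multi-stage design:

1. resample the raw tri-axial signal onto an exact uniform grid
   (default 20 Hz), flagging un-interpolatable gaps;
2. mark off-wrist minutes from forward/backward 150-min averages of the
   per-minute acceleration SD;
3. integrate the per-minute power density spectrum of the mean-removed
   signal across the three axes into a per-minute activity power
   (Parseval-equivalent to the within-minute RMS);
4. rank every worn minute into within-participant percentile categories
   (grid 5..100 by 5);
5. seed candidate sleep at low categories and stabilize it with
   forward/backward moving averages of 100, 60 and 90 minutes;
6. take the longest candidate run per noon-to-noon night window as the
   raw major sleep episode; and
7. refine it with hierarchical merge / trim / extend rules into the
   adjusted episode.

Everything from step 4 on depends only on within-participant activity
ranks, making the detected episodes invariant to rescaling the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import periodogram

from .config import PipelineConfig
from .io import RawRecording

__all__ = [
    "UniformRecording", "WornMask", "PowerSeries", "ScoreSeries", "SleepEpisode",
    "ParticipantDetection", "ParticipantUnusable",
    "resample_to_grid", "detect_wrist_off", "minute_power", "score_percentiles",
    "smooth_low_activity", "extract_major_episode", "refine_and_merge",
    "detect_sleep", "detect_sleep_from_power", "build_activity_map",
]

SENTINEL_CATEGORY = -1


class ParticipantUnusable(ValueError):
    """Raised when a recording cannot support detection; carries a reason code."""

    def __init__(self, reason: str, message: str):
        self.reason = reason
        super().__init__(f"{reason}: {message}")


@dataclass
class UniformRecording:
    participant_id: str
    start_time: pd.Timestamp
    rate: float
    xyz: np.ndarray          # shape (3, n) on the exact grid
    gap_mask: np.ndarray     # True where nearest source sample > 1 s away

    @property
    def n_minutes(self) -> int:
        return int(np.ceil(self.xyz.shape[1] / (60 * self.rate)))


@dataclass
class WornMask:
    start_time: pd.Timestamp
    worn: np.ndarray         # per calendar minute, True = worn


@dataclass
class PowerSeries:
    """Per-minute activity power; NaN marks off-wrist or data-free minutes."""

    start_time: pd.Timestamp
    values: np.ndarray
    participant_id: str = ""


@dataclass
class ScoreSeries:
    start_time: pd.Timestamp
    categories: np.ndarray   # grid percentile per minute, -1 sentinel off-wrist
    thresholds: dict = field(default_factory=dict)


@dataclass
class SleepEpisode:
    night_index: int
    date: str                # label date (wake day by default)
    dow: str
    onset_min: float         # minutes past the window's noon anchor
    wake_min: float
    stage: str               # "raw" | "adjusted"
    flags: tuple = ()
    onset_idx: int = 0       # absolute minute indices [onset_idx, wake_idx)
    wake_idx: int = 0

    @property
    def duration_min(self) -> float:
        return self.wake_min - self.onset_min


@dataclass
class ParticipantDetection:
    """Per-participant detection output used by QC and cohort analysis."""

    participant_id: str
    start_time: pd.Timestamp
    episodes: list           # adjusted SleepEpisodes for detected nights
    n_nights_expected: int
    n_nights_missing: int
    worn: np.ndarray
    wake_activity: float     # mean worn-minute power outside sleep episodes
    gap_fraction: float = 0.0
    constant_axis_worn: bool = False

    def nights_frame(self) -> pd.DataFrame:
        rows = [{
            "participant_id": self.participant_id,
            "night_index": ep.night_index, "date": ep.date, "dow": ep.dow,
            "onset_min": ep.onset_min, "wake_min": ep.wake_min,
            "duration_min": ep.duration_min, "qc_flags": ";".join(ep.flags),
        } for ep in self.episodes]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 1: resampling

def resample_to_grid(raw: RawRecording, cfg: PipelineConfig) -> UniformRecording:
    """Linear interpolation onto the exact ``cfg.resample_rate`` grid.

    Gaps wider than 1 s are flagged in ``gap_mask`` rather than being
    trusted as interpolated data.
    """
    if raw.span_seconds < 60:
        raise ParticipantUnusable("short_record", "recording shorter than one minute")
    rate = cfg.resample_rate
    n = int(np.floor(raw.span_seconds * rate)) + 1
    grid = np.arange(n, dtype=np.float64) / rate + raw.t[0]
    xyz = np.empty((3, n))
    for ax in range(3):
        xyz[ax] = np.interp(grid, raw.t, raw.xyz[ax])
    right = np.searchsorted(raw.t, grid)
    left = np.clip(right - 1, 0, raw.t.size - 1)
    right = np.clip(right, 0, raw.t.size - 1)
    nearest = np.minimum(np.abs(grid - raw.t[left]), np.abs(raw.t[right] - grid))
    return UniformRecording(participant_id=raw.participant_id,
                            start_time=raw.start_time, rate=rate,
                            xyz=xyz, gap_mask=nearest > 1.0)


# ---------------------------------------------------------------------------
# stage 2: non-wear

def _minute_axis_sd(uni: UniformRecording) -> tuple[np.ndarray, np.ndarray]:
    """Axis-mean within-minute SD; NaN where a minute has no usable data."""
    m = int(round(60 * uni.rate))
    n_min = uni.xyz.shape[1] // m
    usable = ~uni.gap_mask[: n_min * m].reshape(n_min, m)
    count = usable.sum(axis=1)
    sds = np.zeros(n_min)
    for ax in range(3):
        x = uni.xyz[ax, : n_min * m].reshape(n_min, m)
        xm = np.where(usable, x, 0.0)
        s = xm.sum(axis=1)
        ss = (xm * xm).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = ss / count - (s / count) ** 2
        sds += np.sqrt(np.maximum(var, 0.0))
    sds /= 3.0
    sds[count < m // 2] = np.nan
    return sds, count


def _directional_means(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """NaN-aware forward/backward rolling means with partial edge windows."""
    s = pd.Series(x)
    bwd = s.rolling(window, min_periods=1).mean().to_numpy()
    fwd = s[::-1].rolling(window, min_periods=1).mean()[::-1].to_numpy()
    return fwd, bwd


def wrist_off_from_minute_sd(sd: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Off-wrist flag per minute.

    A minute reads as off-wrist when its forward OR backward
    ``wristoff_window``-minute mean of the axis-mean SD falls below
    ``wristoff_sd_threshold``; boundary minutes use the available
    partial window.  The one-sided rule lets detected non-wear cover
    the full low-variance span instead of only its core.
    """
    fwd, bwd = _directional_means(sd, cfg.wristoff_window)
    off = (fwd < cfg.wristoff_sd_threshold) | (bwd < cfg.wristoff_sd_threshold)
    return off


def detect_wrist_off(uni: UniformRecording, cfg: PipelineConfig) -> WornMask:
    sd, count = _minute_axis_sd(uni)
    off = wrist_off_from_minute_sd(sd, cfg)
    worn = ~off & ~np.isnan(sd)
    return WornMask(start_time=uni.start_time, worn=worn)


# ---------------------------------------------------------------------------
# stage 3: per-minute power

def minute_power(uni: UniformRecording, worn: WornMask, cfg: PipelineConfig) -> PowerSeries:
    """Integrated power-spectrum activity per minute.

    Per minute and axis the within-minute mean is removed, the
    periodogram computed, and its area integrated; the minute's power is
    the square root of the summed axis integrals, which by Parseval's
    theorem equals the RMS of the mean-removed signal.  Off-wrist and
    data-free minutes carry NaN.
    """
    m = int(round(60 * uni.rate))
    n_min = uni.xyz.shape[1] // m
    usable = ~uni.gap_mask[: n_min * m].reshape(n_min, m)
    count = usable.sum(axis=1)
    total = np.zeros(n_min)
    for ax in range(3):
        x = uni.xyz[ax, : n_min * m].reshape(n_min, m).astype(np.float64)
        with np.errstate(invalid="ignore"):
            mean = np.where(usable, x, 0.0).sum(axis=1) / count
        x = np.where(usable, x, mean[:, None])  # gap samples contribute no variance
        freqs, psd = periodogram(x, fs=uni.rate, detrend="constant", axis=-1)
        df = freqs[1] - freqs[0]
        total += psd.sum(axis=1) * df
    power = np.sqrt(total)
    power[count == 0] = np.nan
    wv = worn.worn[:n_min]
    power[:wv.size][~wv] = np.nan
    return PowerSeries(start_time=uni.start_time, values=power,
                       participant_id=uni.participant_id)


# ---------------------------------------------------------------------------
# stage 4: percentile categories

def score_percentiles(power: PowerSeries, cfg: PipelineConfig) -> ScoreSeries:
    """Within-participant percentile category per worn minute.

    Thresholds use the nearest-rank percentile over worn minutes; each
    minute takes the smallest grid percentile whose threshold is at or
    above its power.  Requires at least 1440 worn minutes.
    """
    vals = power.values
    worn = np.isfinite(vals)
    n = int(worn.sum())
    if n < 1440:
        raise ParticipantUnusable(
            "insufficient_worn_minutes", f"only {n} worn minutes (need 1440)")
    sorted_vals = np.sort(vals[worn])
    grid = np.asarray(cfg.percentile_grid)
    ranks = -(-grid * n // 100) - 1  # exact nearest-rank: ceil(p*n/100) - 1
    thresholds = sorted_vals[np.clip(ranks, 0, n - 1)]
    idx = np.searchsorted(thresholds, vals[worn], side="left")
    cats = np.full(vals.size, SENTINEL_CATEGORY, dtype=np.int16)
    cats[worn] = grid[np.clip(idx, 0, grid.size - 1)]
    return ScoreSeries(start_time=power.start_time, categories=cats,
                       thresholds=dict(zip(grid.tolist(), thresholds.tolist())))


# ---------------------------------------------------------------------------
# stage 5: smoothing

def smooth_low_activity(scores: ScoreSeries, cfg: PipelineConfig) -> np.ndarray:
    """Candidate-sleep indicator after the iterated moving-average passes.

    The seed marks worn minutes at or below ``cfg.seed_percentile``;
    each pass replaces the indicator by the arithmetic mean of its
    forward and backward ``w``-minute moving averages thresholded at
    0.5.  Off-wrist minutes are forced non-sleep throughout.
    """
    cats = scores.categories
    off = cats == SENTINEL_CATEGORY
    ind = ((cats >= 0) & (cats <= cfg.seed_percentile)).astype(float)
    ind[off] = 0.0
    for w in cfg.smoothing_windows:
        fwd, bwd = _directional_means(ind, w)
        ind = ((fwd + bwd) / 2.0 >= 0.5).astype(float)
        ind[off] = 0.0
    return ind.astype(bool)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# stage 6: extraction

def extract_major_episode(
    candidate: np.ndarray,
    scores: ScoreSeries,
    window: tuple[int, int],
    cfg: PipelineConfig,
) -> SleepEpisode | None:
    """Longest candidate run whose midpoint falls in the night window.

    Ties break toward the run with the lower mean percentile category,
    then toward the earlier run.  Returns None (night flagged upstream)
    when no qualifying run reaches ``cfg.min_bout`` minutes.
    """
    lo, hi = window
    cats = scores.categories
    best = None
    for start, end in _runs(candidate):
        mid = (start + end - 1) / 2.0
        if not (lo <= mid < hi):
            continue
        key = (-(end - start), float(np.mean(cats[start:end])), start)
        if best is None or key < best[0]:
            best = (key, start, end)
    if best is None or (best[2] - best[1]) < cfg.min_bout:
        return None
    return SleepEpisode(night_index=0, date="", dow="", stage="raw",
                        onset_min=float(best[1] - lo), wake_min=float(best[2] - lo),
                        onset_idx=best[1], wake_idx=best[2])


# ---------------------------------------------------------------------------
# stage 7: refinement

def refine_and_merge(
    episode: SleepEpisode,
    candidate: np.ndarray,
    scores: ScoreSeries,
    cfg: PipelineConfig,
) -> SleepEpisode:
    """Hierarchical adjustment: merge nearby bouts, trim, then extend.

    (i) any candidate bout of at least ``min_bout`` minutes whose gap to
    the episode is at most ``merge_gap`` minutes with every gap minute
    at or below ``merge_quiet_percentile`` is absorbed (to fixed point);
    (ii) boundary minutes with category above the trim threshold (or
    off-wrist) are trimmed; (iii) boundaries extend across adjacent
    minutes at or below ``extend_percentile``.  If adjustment collapses
    the episode below ``min_bout`` the raw episode is kept, flagged.

    The trim threshold adapts to the participant's sleep depth: it is
    the ``trim_core_quantile`` quantile of the categories in the
    episode's core (the middle 60%), clipped to
    [``trim_floor_percentile``, ``trim_percentile``].  Minutes whose
    rank exceeds every core minute's are boundary contamination (e.g.
    quiet pre-sleep wakefulness) and retract regardless of where the
    participant's sleep fraction places them on the percentile grid.
    """
    cats = scores.categories
    lo_anchor = episode.onset_idx - int(round(episode.onset_min))
    onset, wake = episode.onset_idx, episode.wake_idx

    def quiet_gap(a: int, b: int) -> bool:
        seg = cats[a:b]
        return bool(np.all((seg >= 0) & (seg <= cfg.merge_quiet_percentile)))

    runs = [(s, e) for s, e in _runs(candidate) if e - s >= cfg.min_bout]
    changed = True
    while changed:
        changed = False
        for s, e in runs:
            if e <= onset and onset - e <= cfg.merge_gap and quiet_gap(e, onset) and s < onset:
                onset = min(onset, s)
                changed = True
            elif s >= wake and s - wake <= cfg.merge_gap and quiet_gap(wake, s) and e > wake:
                wake = max(wake, e)
                changed = True

    margin = max(10, (wake - onset) // 5)
    core = cats[onset + margin: wake - margin]
    core = core[core >= 0]
    t_trim = float(np.quantile(core, cfg.trim_core_quantile)) if core.size \
        else float(cfg.trim_percentile)
    t_trim = float(np.clip(t_trim, cfg.trim_floor_percentile, cfg.trim_percentile))

    def keep(i: int, inward: int) -> bool:
        # a boundary minute survives when it and the median of the next
        # few inward minutes sit at or below the trim threshold; the
        # median makes the stop robust to isolated movement bursts
        if cats[i] < 0 or cats[i] > t_trim:
            return False
        look = cats[i: i + 5] if inward > 0 else cats[max(i - 4, 0): i + 1]
        look = look[look >= 0]
        return bool(look.size == 0 or np.median(look) <= t_trim)

    while onset < wake and not keep(onset, +1):
        onset += 1
    while wake > onset and not keep(wake - 1, -1):
        wake -= 1

    while onset > 0 and 0 <= cats[onset - 1] <= cfg.extend_percentile:
        onset -= 1
    while wake < cats.size and 0 <= cats[wake] <= cfg.extend_percentile:
        wake += 1

    if wake - onset < cfg.min_bout:
        return SleepEpisode(
            night_index=episode.night_index, date=episode.date, dow=episode.dow,
            onset_min=episode.onset_min, wake_min=episode.wake_min,
            stage="raw", flags=episode.flags + ("refinement_collapsed",),
            onset_idx=episode.onset_idx, wake_idx=episode.wake_idx)
    return SleepEpisode(
        night_index=episode.night_index, date=episode.date, dow=episode.dow,
        onset_min=float(onset - lo_anchor), wake_min=float(wake - lo_anchor),
        stage="adjusted", flags=episode.flags, onset_idx=onset, wake_idx=wake)


# ---------------------------------------------------------------------------
# orchestration

def _night_windows(n_minutes: int, start_time: pd.Timestamp,
                   cfg: PipelineConfig) -> list[tuple[int, int, int]]:
    """(night_index, lo, hi) for each noon-anchored window fully inside."""
    start_minute_of_day = start_time.hour * 60 + start_time.minute
    first = cfg.sleep_anchor_minutes - start_minute_of_day
    if first < 0:
        first += 1440
    out = []
    k = 0
    lo = first
    while lo + 1440 <= n_minutes:
        out.append((k + 1, lo, lo + 1440))
        k += 1
        lo += 1440
    return out


def detect_sleep_from_power(
    power: PowerSeries,
    cfg: PipelineConfig,
    worn: np.ndarray | None = None,
    gap_fraction: float = 0.0,
    constant_axis_worn: bool = False,
) -> ParticipantDetection:
    """Run stages 2(proxy)-7 from a per-minute power series.

    When ``worn`` is not supplied, off-wrist minutes are inferred from
    the power itself via the axis-mean SD proxy ``power / sqrt(3)``
    (exact for isotropic noise), masked, and then excluded exactly as
    in the raw-sample path.
    """
    values = power.values.astype(float).copy()
    if worn is None:
        sd_proxy = values / np.sqrt(3.0)
        off = wrist_off_from_minute_sd(sd_proxy, cfg)
        worn = ~off & np.isfinite(values)
    values[~worn] = np.nan
    masked = PowerSeries(start_time=power.start_time, values=values,
                         participant_id=power.participant_id)
    scores = score_percentiles(masked, cfg)
    candidate = smooth_low_activity(scores, cfg)

    episodes: list[SleepEpisode] = []
    missing = 0
    windows = _night_windows(values.size, power.start_time, cfg)
    in_sleep = np.zeros(values.size, dtype=bool)
    for night_index, lo, hi in windows:
        raw_ep = extract_major_episode(candidate, scores, (lo, hi), cfg)
        if raw_ep is None:
            missing += 1
            continue
        raw_ep.night_index = night_index
        ep = refine_and_merge(raw_ep, candidate, scores, cfg)
        anchor_time = power.start_time + pd.Timedelta(minutes=lo)
        if cfg.night_attribution == "wake":
            label_time = power.start_time + pd.Timedelta(minutes=int(ep.wake_idx))
        else:
            label_time = power.start_time + pd.Timedelta(minutes=int(ep.onset_idx))
        ep.date = label_time.date().isoformat()
        ep.dow = label_time.day_name()[:3]
        episodes.append(ep)
        in_sleep[ep.onset_idx:ep.wake_idx] = True

    wake_mask = worn & ~in_sleep & np.isfinite(values)
    wake_activity = float(np.mean(values[wake_mask])) if wake_mask.any() else float("nan")
    return ParticipantDetection(
        participant_id=power.participant_id, start_time=power.start_time,
        episodes=episodes, n_nights_expected=len(windows), n_nights_missing=missing,
        worn=worn, wake_activity=wake_activity,
        gap_fraction=gap_fraction, constant_axis_worn=constant_axis_worn)


def _constant_axis_while_worn(uni: UniformRecording, worn: np.ndarray) -> bool:
    """Any axis flat for > 24 h of consecutive worn minutes."""
    sd_by_axis = []
    m = int(round(60 * uni.rate))
    n_min = uni.xyz.shape[1] // m
    for ax in range(3):
        x = uni.xyz[ax, : n_min * m].reshape(n_min, m)
        sd_by_axis.append(x.std(axis=1))
    for sd in sd_by_axis:
        flat = (sd < 1e-6) & worn[:n_min]
        if any(e - s > 1440 for s, e in _runs(flat)):
            return True
    return False


def detect_sleep(raw: RawRecording, cfg: PipelineConfig) -> ParticipantDetection:
    """Full pipeline from a raw recording."""
    uni = resample_to_grid(raw, cfg)
    worn_mask = detect_wrist_off(uni, cfg)
    power = minute_power(uni, worn_mask, cfg)
    gap_fraction = float(uni.gap_mask.mean())
    const_axis = _constant_axis_while_worn(uni, worn_mask.worn)
    return detect_sleep_from_power(
        power, cfg, worn=worn_mask.worn[: power.values.size],
        gap_fraction=gap_fraction, constant_axis_worn=const_axis)


# ---------------------------------------------------------------------------
# daily activity maps

DOW_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")


def build_activity_map(
    power: PowerSeries,
    cfg: PipelineConfig,
    sleep_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean per-minute activity in anchored daily windows by day of week.

    Windows run from ``cfg.day_anchor_activity`` (default 18:00) of the
    previous day to the same time of the current day and are labelled by
    the day they end on.  Only complete windows contribute.  Passing a
    ``sleep_mask`` excludes detected sleep minutes (wake-only map).
    """
    values = power.values
    n = values.size
    start_minute_of_day = power.start_time.hour * 60 + power.start_time.minute
    anchor = cfg.activity_anchor_minutes
    first = anchor - start_minute_of_day
    if first < 0:
        first += 1440
    sums = np.zeros((7, 1440))
    counts = np.zeros((7, 1440))
    lo = first
    while lo + 1440 <= n:
        end_time = power.start_time + pd.Timedelta(minutes=lo + 1440)
        dow = end_time.weekday()
        seg = values[lo:lo + 1440].copy()
        if sleep_mask is not None:
            seg[sleep_mask[lo:lo + 1440]] = np.nan
        ok = np.isfinite(seg)
        sums[dow, ok] += seg[ok]
        counts[dow] += ok
        lo += 1440
    if counts.sum() == 0:
        raise ParticipantUnusable("short_record", "no complete anchored daily window")
    with np.errstate(invalid="ignore", divide="ignore"):
        grid = sums / counts
    return pd.DataFrame(grid, index=list(DOW_NAMES))


def mean_activity_map(maps: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Cohort map = element-wise mean of individual maps (NaN-aware)."""
    stack = np.stack([m.to_numpy() for m in maps])
    with np.errstate(invalid="ignore"):
        return pd.DataFrame(np.nanmean(stack, axis=0), index=list(DOW_NAMES))
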