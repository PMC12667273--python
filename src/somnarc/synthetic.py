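"""Synthetic wrist-accelerometer cohorts with known ground truth.

The generator emulates week-long (8 calendar day) tri-axial wrist
recordings for a middle-aged-to-older cohort: scheduled nightly sleep
episodes with person-level chronotype shifts and night-to-night jitter,
a diurnal wake-activity profile that declines with age, weekday/weekend
schedule shifts in the younger strata, occasional off-wrist segments,
and self-report items statistically linked to the latent schedules.

Two output resolutions share one noise model:

* :func:`generate_recording` - raw samples at >= 20 Hz (gravity plus
  Gaussian movement noise whose per-axis SD follows the minute profile);
* :func:`generate_minute_power` - the per-minute activity power that the
  detection pipeline would integrate from those samples, drawn directly
  from the sampling distribution of the within-minute RMS.  This is the
  practical path for cohorts of thousands of participants.

All randomness is driven by ``numpy.random.Generator`` substreams fanned
out per participant from ``CohortModel.seed`` via ``SeedSequence``, so
cohorts are reproducible element-wise and order-independent.

Time convention: sleep times are minutes relative to the preceding noon
(23:30 onset = 690), which keeps a night's onset and wake on one
monotone axis across midnight.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import RawRecording

__all__ = [
    "CohortModel",
    "ParticipantTruth",
    "SelfReport",
    "SelfReportParams",
    "DEPRESSION_LEVELS",
    "sample_participant_truth",
    "generate_recording",
    "generate_minute_power",
    "generate_self_reports",
    "generate_cohort",
    "load_cohort_model",
    "truth_table",
]

MINUTES_PER_DAY = 1440
N_DAYS = 8
N_MINUTES = N_DAYS * MINUTES_PER_DAY
NOON = 720

#: the published age strata, years (inclusive bounds)
DEFAULT_AGE_BINS: tuple[tuple[int, int], ...] = (
    (44, 49), (50, 54), (55, 59), (60, 64), (65, 69), (70, 74), (75, 82),
)

# Baseline schedules for genetic females (XX), minutes past preceding
# noon, one value per age bin.  Shapes are mildly quadratic in age:
# onset drifts earlier then later, wake drifts later into the 60s then
# reverses, so sleep duration peaks in the late 60s.
_ONSET_XX = (688.0, 686.0, 684.0, 681.0, 679.0, 681.0, 686.0)
_WAKE_XX = (1143.0, 1143.0, 1144.0, 1147.0, 1152.0, 1150.0, 1142.0)

#: per-bin multiplier of the under-60 sex gap and of the weekend shift
_UNDER60_TAPER = (1.0, 1.0, 1.0, 0.5, 0.0, 0.0, 0.0)

#: male sex gap split: onset later by 9/17 of the gap, wake earlier by 8/17
_GAP_ONSET_SHARE = 9.0 / 17.0

#: weekend shift split: onset later by 0.3 s, wake later by 1.3 s
_WEEKEND_ONSET_SHARE = 0.3

#: daytime activity amplitude multiplier per age bin (declines with age)
DEFAULT_ACTIVITY_AMPLITUDE = (1.00, 0.96, 0.92, 0.87, 0.82, 0.76, 0.70)

#: per-axis acceleration noise SD during still sleep, g
SLEEP_SIGMA = 0.005
#: per-axis residual SD of an unworn (constant-signal) device, g
OFF_SIGMA = 1.0e-4
#: probability per sleep minute of a movement burst
BURST_RATE = 0.05
#: per-axis burst noise SD range, g
BURST_SIGMA = (0.05, 0.15)

# Diurnal per-axis noise-SD profile (hour-of-day breakpoints, g) for a
# reference participant (activity scale 1).  Morning peak, evening
# trough, a flat low-variance sedentary block 12:30-17:30 that is the
# quietest waking period of the day, and a flat late-evening/night
# plateau so the context preceding sleep onset does not depend on the
# participant's chronotype.
_DIURNAL_HOURS = (0.0, 5.5, 6.5, 8.0, 10.0, 12.0, 12.5, 17.5, 18.25, 19.0, 21.0, 22.0, 24.0)
_DIURNAL_SIGMA = (0.050, 0.050, 0.075, 0.100, 0.100, 0.080, 0.030, 0.030, 0.085, 0.075, 0.060, 0.050, 0.050)

_GRAVITY = np.array([0.2, -0.3, np.sqrt(1.0 - 0.04 - 0.09)])

DEPRESSION_LEVELS = ("not at all", "several days", "more than half the days", "nearly every day")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SelfReportParams:
    """Links from latent schedules to the questionnaire items.

    ``expansion`` > 1 makes self-reported hours span a wider range than
    the objective durations they derive from, emulating the observed
    compression of objective relative to reported differences.
    The binary/ordinal links are logistic in standardized latent person
    factors: chronotype shift (later = positive), log activity scale,
    and person-level duration offset.  Directions follow the reported
    associations; magnitudes are free parameters.
    """

    expansion: float = 2.0
    bias_hours: float = -8.0
    noise_sd_hours: float = 0.8
    early_intercept: float = -1.8
    early_chrono: float = 0.9
    toomuch_intercept: float = -2.2
    toomuch_chrono: float = 0.8
    toomuch_activity: float = 0.6
    mood_intercept: float = -1.73  # ~15% symptomatic at baseline
    mood_chrono: float = 0.35
    mood_activity: float = 0.40
    mood_duration: float = 0.30
    symptom_level_probs: Sequence[float] = (0.60, 0.25, 0.15)

    def zeroed(self) -> "SelfReportParams":
        """Copy with every schedule link set to zero (null generator)."""
        return dataclasses.replace(
            self, early_chrono=0.0, toomuch_chrono=0.0, toomuch_activity=0.0,
            mood_chrono=0.0, mood_activity=0.0, mood_duration=0.0,
        )


@dataclass
class CohortModel:
    """Population-level generator parameters.

    Schedule tables (``onset_base``/``wake_base``) hold one noon-relative
    minute value per sex per age bin.  When left ``None`` they are built
    from the XX baseline and ``sex_gap_min``: in bins fully under 60 the
    XY schedule starts 9/17 of the gap later and ends 8/17 earlier, i.e.
    male sleep duration is reduced by the full gap; the gap tapers to
    half in the 60-64 bin and to zero from 65.
    """

    n_per_cell: int = 10
    age_bins: Sequence[Sequence[int]] = DEFAULT_AGE_BINS
    onset_base: dict | None = None
    wake_base: dict | None = None
    sex_gap_min: float = 17.0
    weekend_shift_min: float = 50.0
    between_person_sd_min: float = 45.0
    person_duration_sd_min: float = 10.0
    nightly_sd_min: float = 30.0
    activity_amplitude_by_age: Sequence[float] | None = None
    activity_person_sd: float = 0.15
    wristoff_prob_day18: float = 0.10
    wristoff_prob_midweek: float = 0.02
    selfreport_params: SelfReportParams = field(default_factory=SelfReportParams)
    seed: int = 0
    start_date_range: tuple[str, str] = ("2015-06-01", "2015-07-20")
    timezone: str = "Europe/London"

    def __post_init__(self) -> None:
        self.age_bins = tuple((int(lo), int(hi)) for lo, hi in self.age_bins)
        bins = self.age_bins
        if any(b[0] > b[1] for b in bins):
            raise ValueError("age bins must have lo <= hi")
        if any(a[1] >= b[0] for a, b in zip(bins, bins[1:])):
            raise ValueError("age bins must be disjoint and ordered")
        for name in ("between_person_sd_min", "person_duration_sd_min",
                     "nightly_sd_min", "activity_person_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("wristoff_prob_day18", "wristoff_prob_midweek"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if isinstance(self.selfreport_params, dict):
            self.selfreport_params = SelfReportParams(**self.selfreport_params)
        n = len(bins)
        taper = _resize_taper(n)
        if self.onset_base is None or self.wake_base is None:
            onset_xx = np.asarray(_resize_table(_ONSET_XX, n), dtype=float)
            wake_xx = np.asarray(_resize_table(_WAKE_XX, n), dtype=float)
            gap = self.sex_gap_min * taper
            self.onset_base = {
                "XX": onset_xx.tolist(),
                "XY": (onset_xx + gap * _GAP_ONSET_SHARE).tolist(),
            }
            self.wake_base = {
                "XX": wake_xx.tolist(),
                "XY": (wake_xx - gap * (1.0 - _GAP_ONSET_SHARE)).tolist(),
            }
        if self.activity_amplitude_by_age is None:
            self.activity_amplitude_by_age = _resize_table(DEFAULT_ACTIVITY_AMPLITUDE, n)
        self.activity_amplitude_by_age = tuple(float(a) for a in self.activity_amplitude_by_age)
        self.weekend_taper = tuple(taper.tolist())
        for sex in ("XX", "XY"):
            ob, wb = self.onset_base[sex], self.wake_base[sex]
            if len(ob) != n or len(wb) != n:
                raise ValueError("schedule tables must have one entry per age bin")
            if any(o >= w for o, w in zip(ob, wb)):
                raise ValueError(f"onset_base must precede wake_base in every {sex} cell")

    def bin_index(self, age: float) -> int:
        for i, (lo, hi) in enumerate(self.age_bins):
            if lo <= age <= hi:
                return i
        raise ValueError(
            f"age {age} falls outside every configured age bin {list(self.age_bins)}"
        )

    def bin_label(self, age: float) -> str:
        lo, hi = self.age_bins[self.bin_index(age)]
        return f"{lo}-{hi}"


def _resize_table(table: Sequence[float], n: int) -> tuple:
    """Adapt a 7-bin default table to n bins by linear interpolation."""
    if n == len(table):
        return tuple(table)
    x = np.linspace(0.0, 1.0, len(table))
    xi = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.0])
    return tuple(np.interp(xi, x, np.asarray(table, dtype=float)).tolist())


def _resize_taper(n: int) -> np.ndarray:
    if n == len(_UNDER60_TAPER):
        return np.asarray(_UNDER60_TAPER)
    # generic rule: full effect strictly under 60, half in a bin straddling
    # or starting at 60-64, none from 65
    return np.ones(n)


@dataclass
class ParticipantTruth:
    """Latent ground truth for one participant (artifact plumbing)."""

    participant_id: str
    age: int
    sex: str
    age_bin: str
    start_time: pd.Timestamp
    person_onset_offset: float
    person_wake_offset: float
    #: noon-relative onset/wake minutes for nights 0..8 (night i wakes on day i+1)
    onsets: np.ndarray
    wakes: np.ndarray
    activity_scale: float
    latent_mood: str  # "none" | "depressed"
    #: absolute off-wrist segments, minutes since recording start
    off_segments: list
    has_midweek_off: bool

    @property
    def night_indices(self) -> np.ndarray:
        return np.arange(len(self.onsets))

    def wake_date(self, night: int) -> pd.Timestamp:
        return (self.start_time + pd.Timedelta(days=night)).normalize()

    def durations(self) -> np.ndarray:
        return self.wakes - self.onsets

    def valid_nights(self) -> np.ndarray:
        """Nights whose noon window lies fully inside the recording (1..7)."""
        return np.arange(1, N_DAYS)


@dataclass
class SelfReport:
    reported_hours: int
    too_much_sleep: str
    waking_too_early: str
    depression: str
    anhedonia: str

    def __post_init__(self) -> None:
        if not 3 <= self.reported_hours <= 12:
            raise ValueError("reported_hours must lie in [3, 12]")
        for item in (self.depression, self.anhedonia):
            if item not in DEPRESSION_LEVELS:
                raise ValueError(f"unknown symptom level {item!r}")


def sample_participant_truth(
    model: CohortModel,
    age: int,
    sex: str,
    rng: np.random.Generator,
    participant_id: str = "P00000",
    start_date: str | pd.Timestamp | None = None,
) -> ParticipantTruth:
    """Draw one participant's latent schedule, activity level and mood.

    Nightly schedules are cell base + person offsets + nightly noise,
    with the weekend shift added to Friday and Saturday nights (wake on
    Sat/Sun) scaled by the cell's under-60 taper.  Deterministic given
    ``rng`` state.
    """
    if sex not in ("XX", "XY"):
        raise ValueError("sex must be 'XX' or 'XY'")
    b = model.bin_index(age)  # raises for out-of-bin ages

    chrono = rng.normal(0.0, model.between_person_sd_min) if model.between_person_sd_min else 0.0
    dur_off = rng.normal(0.0, model.person_duration_sd_min) if model.person_duration_sd_min else 0.0
    act_z = rng.normal(0.0, 1.0)
    act_scale = model.activity_amplitude_by_age[b] * float(np.exp(model.activity_person_sd * act_z))

    if start_date is None:
        lo = pd.Timestamp(model.start_date_range[0])
        hi = pd.Timestamp(model.start_date_range[1])
        start_date = lo + pd.Timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))
    start_time = pd.Timestamp(start_date).tz_localize(model.timezone) \
        if pd.Timestamp(start_date).tzinfo is None else pd.Timestamp(start_date)
    start_time = start_time.normalize()

    onset_base = model.onset_base[sex][b]
    wake_base = model.wake_base[sex][b]
    taper = model.weekend_taper[b]

    onsets = np.empty(N_DAYS + 1)
    wakes = np.empty(N_DAYS + 1)
    for night in range(N_DAYS + 1):
        wake_day = start_time + pd.Timedelta(days=night)
        weekend = wake_day.weekday() >= 5  # Sat/Sun wake => Fri/Sat night
        shift = model.weekend_shift_min * taper if weekend else 0.0
        for _ in range(100):
            o = onset_base + chrono + shift * _WEEKEND_ONSET_SHARE
            w = wake_base + chrono + dur_off + shift * (1.0 + _WEEKEND_ONSET_SHARE)
            if model.nightly_sd_min:
                o += rng.normal(0.0, model.nightly_sd_min)
                w += rng.normal(0.0, model.nightly_sd_min)
            if o < w and 120.0 < w - o < 960.0:
                break
        else:  # pragma: no cover - unreachable at plausible SDs
            raise RuntimeError("could not draw a valid night schedule")
        onsets[night], wakes[night] = o, w

    # latent mood, linked to later chronotype, lower activity, shorter sleep
    p = model.selfreport_params
    z_c = chrono / model.between_person_sd_min if model.between_person_sd_min else 0.0
    z_d = dur_off / model.person_duration_sd_min if model.person_duration_sd_min else 0.0
    p_mood = _sigmoid(p.mood_intercept + p.mood_chrono * z_c
                      - p.mood_activity * act_z - p.mood_duration * z_d)
    mood = "depressed" if rng.random() < p_mood else "none"

    off_segments: list[tuple[int, int]] = []
    has_midweek = False
    if rng.random() < model.wristoff_prob_day18:
        if rng.random() < 0.5:  # day-1 morning block, after the night-0 wake
            wake0_abs = wakes[0] - NOON  # minutes since midnight day 1
            start = int(max(wake0_abs + 30, 0) + rng.uniform(0, 60))
            end = min(start + int(rng.uniform(60, 180)), 700)
        else:  # day-8 evening block, before the night-8 onset
            onset8_abs = (N_DAYS - 1) * MINUTES_PER_DAY + NOON + onsets[N_DAYS]
            start = (N_DAYS - 1) * MINUTES_PER_DAY + 1080 + int(rng.uniform(0, 60))
            end = min(start + int(rng.uniform(60, 180)), int(onset8_abs - 30))
        if end > start:
            off_segments.append((start, end))
    if rng.random() < model.wristoff_prob_midweek:
        day = int(rng.integers(2, N_DAYS))  # days 2..7
        start = (day - 1) * MINUTES_PER_DAY + int(rng.uniform(540, 900))
        end = min(start + int(rng.uniform(120, 360)), day * MINUTES_PER_DAY - 1)
        off_segments.append((start, end))
        has_midweek = True

    return ParticipantTruth(
        participant_id=participant_id, age=int(age), sex=sex,
        age_bin=model.bin_label(age), start_time=start_time,
        person_onset_offset=chrono, person_wake_offset=chrono + dur_off,
        onsets=onsets, wakes=wakes, activity_scale=act_scale,
        latent_mood=mood, off_segments=off_segments, has_midweek_off=has_midweek,
    )


# ---------------------------------------------------------------------------
# minute-level noise profile shared by both output resolutions

def minute_profile(truth: ParticipantTruth, rng: np.random.Generator | None = None,
                   square_wave: bool = False) -> dict:
    """Per-minute state arrays: per-axis noise SD, sleep and off flags.

    ``square_wave=True`` replaces the diurnal wake profile and burst
    process with two flat levels (wake/sleep), producing a recording
    whose per-minute activity power is a two-level square wave aligned
    to the schedule.
    """
    minute_of_day = np.arange(N_MINUTES) % MINUTES_PER_DAY
    hours = minute_of_day / 60.0
    if square_wave:
        sigma = np.full(N_MINUTES, 0.08)
    else:
        sigma = np.interp(hours, _DIURNAL_HOURS, _DIURNAL_SIGMA) * truth.activity_scale

    asleep = np.zeros(N_MINUTES, dtype=bool)
    for night in range(N_DAYS + 1):
        anchor = (night - 1) * MINUTES_PER_DAY + NOON  # noon preceding the night
        o = int(round(anchor + truth.onsets[night]))
        w = int(round(anchor + truth.wakes[night]))
        lo, hi = max(o, 0), min(w, N_MINUTES)
        if hi > lo:
            asleep[lo:hi] = True
    sigma[asleep] = SLEEP_SIGMA

    if not square_wave and rng is not None and BURST_RATE > 0:
        burst = asleep & (rng.random(N_MINUTES) < BURST_RATE)
        amps = rng.uniform(*BURST_SIGMA, size=int(burst.sum()))
        sigma[burst] = np.sqrt(sigma[burst] ** 2 + amps ** 2)

    off = np.zeros(N_MINUTES, dtype=bool)
    for start, end in truth.off_segments:
        off[max(start, 0):min(end, N_MINUTES)] = True
    sigma[off] = OFF_SIGMA
    return {"sigma": sigma, "asleep": asleep, "off": off}


def generate_recording(
    truth: ParticipantTruth,
    sample_rate: float = 20.0,
    rng: np.random.Generator | None = None,
    square_wave: bool = False,
) -> RawRecording:
    """Synthesize the raw tri-axial stream for one participant.

    The signal is the gravity vector plus white noise whose per-axis SD
    follows the minute profile; off-wrist segments are near-constant.
    In ``square_wave`` mode the movement signal is a deterministic sine
    (equal power on the three axes) at two flat levels plus a 1% jitter
    so that within-participant activity ranks remain well defined.
    """
    if sample_rate < 20.0:
        raise ValueError("sample_rate must be >= 20 Hz")
    rng = np.random.default_rng(0) if rng is None else rng
    n_per_min = int(round(60 * sample_rate))
    n = N_MINUTES * n_per_min
    t = np.arange(n, dtype=np.float64) / sample_rate
    profile = minute_profile(truth, rng=rng, square_wave=square_wave)
    sigma = np.repeat(profile["sigma"], n_per_min)
    if square_wave:
        # per-axis sine with SD sigma: per-minute power sigma*sqrt(3) and
        # axis-mean SD sigma, both matching the noise mode exactly
        xyz = np.empty((3, n), dtype=np.float32)
        for ax, f in enumerate((2.0, 3.0, 5.0)):
            wave = np.sqrt(2.0) * sigma * np.sin(2 * np.pi * f * t)
            jitter = rng.normal(0.0, 1.0, size=n) * (0.01 * sigma)
            xyz[ax] = _GRAVITY[ax] + wave + jitter
    else:
        xyz = (_GRAVITY[:, None] + rng.normal(size=(3, n)) * sigma[None, :]).astype(np.float32)
    return RawRecording(
        participant_id=truth.participant_id,
        start_time=truth.start_time,
        t=t, xyz=xyz, nominal_rate=sample_rate,
    )


def generate_minute_power(
    truth: ParticipantTruth,
    rng: np.random.Generator | None = None,
    sample_rate: float = 20.0,
    square_wave: bool = False,
) -> np.ndarray:
    """Per-minute activity power, drawn from the RMS sampling law.

    For Gaussian noise with per-axis SD sigma, the mean-removed RMS
    integrated across the three axes satisfies
    ``power^2 = sigma^2 * chi2(3m - 3) / m`` with ``m`` samples per
    minute - exactly the statistic :func:`somnarc.detection.minute_power`
    computes from the raw stream.  Off-wrist minutes are included at the
    unworn noise floor; the detector is responsible for masking them.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    profile = minute_profile(truth, rng=rng, square_wave=square_wave)
    sigma = profile["sigma"]
    m = int(round(60 * sample_rate))
    if square_wave:
        # two flat levels with a ~1e-4 relative jitter so ranks stay distinct
        return sigma * np.sqrt(3.0) * (1.0 + 1e-4 * rng.normal(size=N_MINUTES))
    chi = rng.chisquare(3 * m - 3, size=N_MINUTES)
    return sigma * np.sqrt(chi / m)


# ---------------------------------------------------------------------------
# self reports

def generate_self_reports(
    truth: ParticipantTruth, model: CohortModel, rng: np.random.Generator
) -> SelfReport:
    """Draw the questionnaire responses linked to the latent schedule."""
    nights = truth.valid_nights()
    if len(nights) == 0:
        raise ValueError("participant has no valid night")
    p = model.selfreport_params
    true_hours = float(np.mean(truth.durations()[nights])) / 60.0
    noise = rng.normal(0.0, p.noise_sd_hours) if p.noise_sd_hours else 0.0
    reported = int(np.clip(round(p.expansion * true_hours + p.bias_hours + noise), 3, 12))

    z_c = truth.person_onset_offset / model.between_person_sd_min \
        if model.between_person_sd_min else 0.0
    z_d = (truth.person_wake_offset - truth.person_onset_offset) / model.person_duration_sd_min \
        if model.person_duration_sd_min else 0.0
    bin_amp = model.activity_amplitude_by_age[model.bin_index(truth.age)]
    z_a = np.log(truth.activity_scale / bin_amp) / model.activity_person_sd \
        if model.activity_person_sd else 0.0

    p_early = _sigmoid(p.early_intercept + p.early_chrono * (-z_c))
    p_much = _sigmoid(p.toomuch_intercept + p.toomuch_chrono * z_c + p.toomuch_activity * (-z_a))
    early = "Yes" if rng.random() < p_early else "No"
    much = "Yes" if rng.random() < p_much else "No"

    def symptom_level(flagged: bool) -> str:
        if not flagged:
            return DEPRESSION_LEVELS[0]
        probs = np.asarray(p.symptom_level_probs, dtype=float)
        probs = probs / probs.sum()
        return DEPRESSION_LEVELS[1 + int(rng.choice(3, p=probs))]

    depressed = truth.latent_mood == "depressed"
    depression = symptom_level(depressed)
    anhedonia = symptom_level(depressed or rng.random() < 0.05)
    return SelfReport(reported_hours=reported, too_much_sleep=much,
                      waking_too_early=early, depression=depression, anhedonia=anhedonia)


# ---------------------------------------------------------------------------
# cohort assembly

class RecordingSequence:
    """Lazy, order-independent view of the cohort's raw recordings."""

    def __init__(self, truths: Sequence[ParticipantTruth], seeds: Sequence,
                 sample_rate: float = 20.0):
        self._truths = list(truths)
        self._seeds = list(seeds)
        self.sample_rate = sample_rate

    def __len__(self) -> int:
        return len(self._truths)

    def __getitem__(self, i: int) -> RawRecording:
        rng = np.random.default_rng(self._seeds[i])
        return generate_recording(self._truths[i], self.sample_rate, rng)

    def minute_power(self, i: int) -> np.ndarray:
        rng = np.random.default_rng(self._seeds[i])
        return generate_minute_power(self._truths[i], rng, self.sample_rate)


def generate_cohort(model: CohortModel, sample_rate: float = 20.0):
    """Draw the full cohort: ``n_per_cell`` participants per sex per bin.

    Returns ``(recordings, truths, self_reports)`` where ``recordings``
    is a lazy :class:`RecordingSequence` (one full-week raw recording is
    ~300 MB in memory; materialize per participant), ``truths`` is the
    list of :class:`ParticipantTruth` and ``self_reports`` a DataFrame
    with one row per participant.  Fully reproducible from
    ``model.seed``.
    """
    truths: list[ParticipantTruth] = []
    reports: list[dict] = []
    rec_seeds = []
    idx = 0
    for b, (lo, hi) in enumerate(model.age_bins):
        for sex in ("XX", "XY"):
            for _ in range(model.n_per_cell):
                ss = np.random.SeedSequence(entropy=model.seed, spawn_key=(idx,))
                truth_ss, rec_ss, rep_ss = ss.spawn(3)
                rng = np.random.default_rng(truth_ss)
                age = int(rng.integers(lo, hi + 1))
                truth = sample_participant_truth(
                    model, age, sex, rng, participant_id=f"P{idx:05d}")
                truths.append(truth)
                rec_seeds.append(rec_ss)
                report = generate_self_reports(truth, model, np.random.default_rng(rep_ss))
                reports.append({"participant_id": truth.participant_id,
                                **dataclasses.asdict(report)})
                idx += 1
    reports_df = pd.DataFrame(reports)
    return RecordingSequence(truths, rec_seeds, sample_rate), truths, reports_df


def truth_table(truths: Sequence[ParticipantTruth]) -> pd.DataFrame:
    """Tidy per-night ground-truth schedule table (valid nights 1..7)."""
    rows = []
    for truth in truths:
        for night in truth.valid_nights():
            wake_day = truth.wake_date(int(night))
            rows.append({
                "participant_id": truth.participant_id,
                "night_index": int(night),
                "date": wake_day.date().isoformat(),
                "dow": wake_day.day_name()[:3],
                "onset_min": truth.onsets[night],
                "wake_min": truth.wakes[night],
                "duration_min": truth.wakes[night] - truth.onsets[night],
            })
    return pd.DataFrame(rows)


def participants_table(truths: Sequence[ParticipantTruth]) -> pd.DataFrame:
    return pd.DataFrame([
        {"participant_id": t.participant_id, "age": t.age, "sex": t.sex,
         "age_bin": t.age_bin, "start_time": t.start_time.isoformat(),
         "activity_scale": t.activity_scale, "latent_mood": t.latent_mood}
        for t in truths
    ])


def load_cohort_model(path) -> CohortModel:
    """Build a :class:`CohortModel` from YAML mirroring its fields."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(CohortModel)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown cohort model keys: {sorted(unknown)}")
    return CohortModel(**data)
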