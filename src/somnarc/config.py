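"""Pipeline configuration: defaults, YAML loading, provenance.

All tunables of the detection pipeline live in :class:`PipelineConfig`.
Defaults follow the published processing choices (20 Hz resampling,
150-min non-wear windows, percentile grid 5..100 in steps of 5, decision
percentiles 10/25/50/75, smoothing windows 100/60/90 min) with the
remaining free constants documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    #: uniform resampling rate of the raw tri-axial signal, Hz
    resample_rate: float = 20.0
    #: forward/backward averaging span for non-wear detection, minutes
    wristoff_window: int = 150
    #: per-minute axis-mean SD below which a window reads as off-wrist, g
    wristoff_sd_threshold: float = 0.004
    #: within-participant percentile grid for activity categories
    percentile_grid: Sequence[int] = field(default_factory=lambda: list(range(5, 101, 5)))
    #: the four named decision percentiles (extend, merge-quiet, seed/trim bound, high)
    decision_percentiles: Sequence[int] = field(default_factory=lambda: [10, 25, 50, 75])
    #: moving-average window lengths applied in order, minutes
    smoothing_windows: Sequence[int] = field(default_factory=lambda: [100, 60, 90])
    #: maximum gap bridged when absorbing adjacent sleep bouts, minutes
    merge_gap: int = 30
    #: minimum accepted episode/bout length, minutes
    min_bout: int = 30
    #: anchor for night (sleep) windows, local clock "HH:MM"
    day_anchor_sleep: str = "12:00"
    #: anchor for daily activity maps, local clock "HH:MM"
    day_anchor_activity: str = "18:00"
    #: significance level for every reported test
    alpha: float = 0.05
    #: percentile category at or below which a minute seeds candidate sleep
    seed_percentile: int = 50
    #: boundary minutes with category above the trim threshold are
    #: trimmed off; the threshold adapts to the episode core (see
    #: trim_core_quantile) but never exceeds this ceiling
    trim_percentile: int = 50
    #: lower bound of the adaptive trim threshold
    trim_floor_percentile: int = 25
    #: quantile of the episode-core categories defining the trim threshold
    trim_core_quantile: float = 0.9
    #: boundaries extend over adjacent minutes at or below this category
    extend_percentile: int = 10
    #: every minute of a merge gap must be at or below this category
    merge_quiet_percentile: int = 25
    #: label nights by wake day ("wake") or by sleep-onset day ("onset")
    night_attribution: str = "wake"
    #: use Welch's t-test instead of the pooled-variance Student t
    welch: bool = False
    # default vs user provenance, filled by load_config
    provenance: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.percentile_grid = [int(p) for p in self.percentile_grid]
        self.decision_percentiles = [int(p) for p in self.decision_percentiles]
        self.smoothing_windows = [int(w) for w in self.smoothing_windows]
        if self.resample_rate <= 0:
            raise ValueError("resample_rate must be positive")
        for name in ("wristoff_window", "merge_gap", "min_bout"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(w <= 0 for w in self.smoothing_windows):
            raise ValueError("smoothing windows must be positive")
        for lst in (self.percentile_grid, self.decision_percentiles):
            if not lst or any(b <= a for a, b in zip(lst, lst[1:])):
                raise ValueError("percentile lists must be strictly increasing")
            if lst[0] <= 0 or lst[-1] > 100:
                raise ValueError("percentiles must lie in (0, 100]")
        if self.night_attribution not in ("wake", "onset"):
            raise ValueError("night_attribution must be 'wake' or 'onset'")

    @property
    def sleep_anchor_minutes(self) -> int:
        return _parse_clock(self.day_anchor_sleep)

    @property
    def activity_anchor_minutes(self) -> int:
        return _parse_clock(self.day_anchor_activity)


def _parse_clock(text: str) -> int:
    hh, mm = text.split(":")
    minutes = int(hh) * 60 + int(mm)
    if not 0 <= minutes < 1440:
        raise ValueError(f"clock time out of range: {text!r}")
    return minutes


def load_config(path) -> PipelineConfig:
    """Read a YAML file holding a subset of :class:`PipelineConfig` fields.

    Unspecified fields take their defaults; unknown keys raise instead of
    being silently ignored.  ``cfg.provenance`` maps each field name to
    ``"user"`` or ``"default"``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    data = {} if data is None else data
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig) if f.name != "provenance"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    cfg.provenance = {name: ("user" if name in data else "default") for name in sorted(known)}
    return cfg
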