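"""Shared fixtures: pipeline config and reusable simulated studies."""

import dataclasses

import numpy as np
import pytest

from somnarc.config import PipelineConfig
from somnarc.synthetic import CohortModel
from somnarc.pipeline import run_synthetic_study

UNDER60_BINS = [(44, 49), (50, 54), (55, 59)]


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def zero_noise_model() -> CohortModel:
    """Deterministic schedules: every SD zero, no off-wrist segments."""
    return dataclasses.replace(
        CohortModel(), between_person_sd_min=0.0, person_duration_sd_min=0.0,
        nightly_sd_min=0.0, activity_person_sd=0.0,
        wristoff_prob_day18=0.0, wristoff_prob_midweek=0.0)


@pytest.fixture(scope="session")
def study_under60_a():
    """Full end-to-end study, 1002/sex ages 44-59 (effect-recovery cohort A)."""
    model = CohortModel(n_per_cell=334, age_bins=UNDER60_BINS, seed=20250101)
    return run_synthetic_study(model)


@pytest.fixture(scope="session")
def study_under60_b():
    """Same design, independent seed (effect-recovery cohort B)."""
    model = CohortModel(n_per_cell=334, age_bins=UNDER60_BINS, seed=20250102)
    return run_synthetic_study(model)


@pytest.fixture(scope="session")
def study_allages():
    """Small study across all seven age bins for trend/association checks."""
    model = CohortModel(n_per_cell=12, seed=5)
    return run_synthetic_study(model)


@pytest.fixture(scope="session")
def study_noisy_small():
    """~30 participants under default noise (about 200 nights)."""
    model = CohortModel(n_per_cell=5, age_bins=UNDER60_BINS, seed=11)
    return run_synthetic_study(model)


def boundary_errors(study) -> np.ndarray:
    """Absolute detected-vs-truth onset and wake errors over all nights."""
    truths = {t.participant_id: t for t in study["truths"]}
    errs = []
    for _, row in study["nights"].iterrows():
        t = truths[row.participant_id]
        night = int(row.night_index)
        errs.append(abs(row.onset_min - t.onsets[night]))
        errs.append(abs(row.wake_min - t.wakes[night]))
    return np.asarray(errs)
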