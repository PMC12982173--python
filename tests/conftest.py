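import numpy as np
import pytest

from cardiopsych.synth import (BeatSpec, CohortSpec, RhythmSpec,
                               generate_cohort, generate_ecg_record)

PLANTED_BETAS = (1.2, 1.1, 1.0, 0.9, 0.8)


def truth_amplitude(beat: BeatSpec, lead: str, wave: str) -> float:
    """Limb-lead algebra applied to the per-lead template amplitudes."""
    a1, a2 = beat.amplitude("I", wave), beat.amplitude("II", wave)
    return {"I": a1, "II": a2, "III": a2 - a1, "aVR": -(a1 + a2) / 2.0,
            "aVL": a1 - a2 / 2.0, "aVF": a2 - a1 / 2.0}[lead]


def planted_cohort(seed: int, n_subjects: int = 90, n_features: int = 30,
                   r2_true: float = 0.5, target: str = "beck"):
    """Cohort with 5 informative features at exactly the requested R^2."""
    var_signal = sum(b * b for b in PLANTED_BETAS)
    noise_sd = float(np.sqrt(var_signal * (1.0 - r2_true) / r2_true))
    spec = CohortSpec(
        n_subjects=n_subjects, n_features=n_features,
        informative={target: [(i, b) for i, b in enumerate(PLANTED_BETAS)]},
        noise_sd={target: noise_sd}, seed=seed)
    return generate_cohort(spec)


def null_cohort(seed: int, n_subjects: int = 90, n_features: int = 100):
    spec = CohortSpec(n_subjects=n_subjects, n_features=n_features, seed=seed)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_beat() -> BeatSpec:
    return BeatSpec()


@pytest.fixture(scope="session")
def noiseless_record(default_beat):
    """12-beat noiseless 60 bpm record plus ground-truth fiducials."""
    rhythm = RhythmSpec(mean_rr=1000.0, n_beats=12, seed=1)
    record, fiducials = generate_ecg_record(default_beat, rhythm)
    return record, fiducials, default_beat, rhythm
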