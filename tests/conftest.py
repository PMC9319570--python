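"""Shared fixtures.

The two expensive fixtures (full synthetic cohorts run through feature
extraction) are session-scoped so the pipeline-level tests share one
computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from harpipe import (
    ActivityProfile,
    CohortSpec,
    CrossValidationExperiment,
    ExperimentConfig,
    make_cohort,
)


@pytest.fixture(scope="session")
def imbalanced_cohort_experiment():
    """8-subject imbalanced ankle cohort (driving 64%, stairs 4.5% each),
    featurized and cross-validated with the none/undersample arms.

    Returns (features_by_sensor, ExperimentResults).
    """
    spec = CohortSpec(seed=7)
    recordings = make_cohort(spec)
    config = ExperimentConfig(
        balancing_arms=("none", "undersample"),
        n_folds=8,
        undersample_repeats=10,
        seed=3,
    )
    experiment = CrossValidationExperiment.from_recordings(recordings, config)
    return experiment.features_by_sensor, experiment.run()


def y_only_profiles() -> dict[str, ActivityProfile]:
    """Profiles whose x and z axes are statistically identical across classes
    (pure noise at a shared level) while the y axis carries all class signal."""
    def prof(name, f0, y_amps, drift=0.3):
        amps = np.zeros((3, 3))
        amps[1] = y_amps
        return ActivityProfile(
            name,
            fundamental_freq_hz=f0,
            harmonic_amps=amps,
            baseline_offset=np.array([0.0, 1.0, 0.0]),
            noise_sd=0.08,
            lowfreq_drift_hz=drift,
        )

    return {
        "level_walking": prof("level_walking", 1.9, [0.50, 0.15, 0.05]),
        "ascending_stairs": prof("ascending_stairs", 1.7, [0.40, 0.25, 0.08]),
        "descending_stairs": prof("descending_stairs", 2.15, [0.60, 0.08, 0.06]),
        "driving": prof("driving", 0.0, [0.30, 0.0, 0.0]),
    }


@pytest.fixture(scope="session")
def y_signal_features():
    """Features of a small near-balanced cohort where only the y axis is
    informative; used for importance-recovery checks."""
    from harpipe import epoch_stream, extract_features

    spec = CohortSpec(
        n_subjects=4,
        class_share={
            "level_walking": 0.30,
            "ascending_stairs": 0.20,
            "descending_stairs": 0.20,
            "driving": 0.30,
        },
        duration_s=240.0,
        # zero jitter: per-subject parameter noise would re-scale the x/z
        # noise floors per class and leak class signal into those axes
        subject_variability=0.0,
        seed=21,
    )
    recordings = make_cohort(spec, profiles=y_only_profiles())
    epochs = []
    for rec in recordings:
        epochs.extend(epoch_stream(rec))
    return extract_features(epochs)
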