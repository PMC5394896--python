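import numpy as np
import pytest

from anticipy.preprocess import BinnedDataset, TrialEpochs
from anticipy.simulate import ChannelEffect, DesignSpec, GroundTruth, generate_dataset


@pytest.fixture(scope="session")
def small_spec():
    """6 subjects x 54 trials, 6 channels, 100 Hz over 0-240 ms (24 samples)."""
    return DesignSpec(
        n_subjects=6,
        n_trials_per_subject=54,
        n_channels=6,
        sample_rate=100.0,
        epoch_window=(0.0, 240.0),
        p_incorrect=0.0,
    )


@pytest.fixture(scope="session")
def planted_truth():
    """One direct, one indirect, one context channel for mean reward."""
    return GroundTruth(
        effects=(
            ChannelEffect(0, "mean", "direct", amplitude=1.2),
            ChannelEffect(1, "mean", "indirect", source=0, gain=0.8),
            ChannelEffect(2, "mean", "context", source=0, gain=1.0),
        ),
        onset_ms={"mean": 0.0},
        rise_ms=0.0,
        noise_sd=0.4,
        shared_noise_sd=1.0,
    )


@pytest.fixture(scope="session")
def planted_dataset(small_spec, planted_truth):
    epochs, stim, truth = generate_dataset(small_spec, planted_truth, seed=11)
    return epochs, stim, truth


def make_null_binned(rng, n_subjects=4, trials_per_subject=36, n_channels=4, n_bins=12):
    """Pure-noise binned dataset for calibration checks."""
    n = n_subjects * trials_per_subject
    subjects = np.repeat(np.arange(n_subjects), trials_per_subject)
    data = rng.normal(size=(n, n_channels, n_bins))
    centers = (np.arange(n_bins) + 0.5) * 10.0
    return BinnedDataset(
        data=data, bin_width_ms=10.0, bin_centers_ms=centers, subject=subjects
    )


def factorial_y(rng, subjects, levels=(1.0, 2.0, 3.0)):
    """Balanced numeric factor within each subject, shuffled per subject."""
    y = np.empty(len(subjects))
    for s in np.unique(subjects):
        idx = np.flatnonzero(subjects == s)
        vals = np.tile(levels, len(idx) // len(levels))
        y[idx] = rng.permutation(vals)
    return y
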