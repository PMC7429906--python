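"""Shared fixtures: a reduced acquisition profile and small synthetic
cohorts so unit tests stay fast."""

import numpy as np
import pytest

from mrsdyn import AcquisitionProfile, GroundTruth
from mrsdyn.synthetic import simulate_cohort


@pytest.fixture(scope="session")
def mini_profile():
    """32 transients of 1024 points: enough structure, cheap to fit."""
    return AcquisitionProfile("mini", n_transients=32, tr_s=3.0, n_points=1024)


@pytest.fixture(scope="session")
def mini_truth():
    return GroundTruth(
        drift_total={"gaba": -0.10, "glx": 0.054, "tnaa": 0.0, "tcr": 0.0},
        latent_sd=0.0,
        coupling_kappa=0.0,
        glx_innovation_sd=0.0,
        coupling_delay_bins=2,
        noise_sd=0.02,
        freq_jitter_ppm=0.004,
        phase_jitter_deg=1.0,
    )


def _quiet_base():
    return GroundTruth(
        noise_sd=1e-4,
        freq_jitter_ppm=0.0,
        scanner_drift_ppm=0.0,
        phase_jitter_deg=0.0,
        coupling_delay_bins=2,
        baseline_sd={"gaba": 0.0, "glx": 0.0, "tnaa": 0.0, "tcr": 0.0,
                     "naa_edit": 0.0},
    )


@pytest.fixture(scope="session")
def mini_cohort(mini_profile, mini_truth):
    return simulate_cohort(mini_profile, mini_truth, n_subjects=5, seed=42)


@pytest.fixture(scope="session")
def quiet_truth():
    """Nearly noiseless null conditions for deterministic recovery checks."""
    return GroundTruth.null(_quiet_base())


@pytest.fixture
def rng():
    return np.random.default_rng(7)


AMPS = {"tcr": 1.0, "tnaa": 1.4, "gaba": 0.12, "glx": 1.0, "naa_edit": 0.4}


@pytest.fixture(scope="session")
def amplitudes():
    return dict(AMPS)
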