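import numpy as np
import pandas as pd
import pytest

from pupilverse import (
    DEFAULT_GEOMETRY,
    SessionConfig,
    TrueEffect,
    average_eyes,
    generate_full_session,
    generate_session,
)
from pupilverse.preprocess import ForkSpec, ProcessedDataset


@pytest.fixture(scope="session")
def geom():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def artifact_table():
    """A small session with all artifact types and one forced high-missing id."""
    cfg = SessionConfig(n_participants=4, seed=3, high_missing_ids=(3,))
    return generate_full_session(cfg, TrueEffect()), cfg


@pytest.fixture(scope="session")
def clean_table():
    """Artifact-free session: observed pupil == latent + noise, nothing missing."""
    cfg = SessionConfig(
        n_participants=3, seed=5, blink_rate=0.0, trackloss_rate=0.0, extreme_rate=0.0
    )
    return generate_session(cfg, TrueEffect()), cfg


@pytest.fixture(scope="session")
def full_session():
    """The 8-participant session used for whole-lattice checks."""
    cfg = SessionConfig(n_participants=8, seed=0, high_missing_ids=(5, 8))
    return generate_full_session(cfg, TrueEffect()), cfg


@pytest.fixture(scope="session")
def full_run(full_session, geom):
    """One complete multiverse run (48 datasets x 2 models) on the session."""
    from pupilverse.multiverse import build_spec_curve, run_multiverse

    table, _cfg = full_session
    result = run_multiverse(table, geom)
    curve = build_spec_curve(result)
    return result, curve


def make_series(pupil, participant_id=1, block="audiovisual", trial=1, dt=1000.0 / 60.0):
    """Hand-rolled monocular series for operator unit tests."""
    pupil = np.asarray(pupil, dtype=float)
    n = len(pupil)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "block": block,
            "trial": trial,
            "t_trial": np.arange(n) * dt,
            "pupil": pupil,
            "gaze_x": 1280.0,
            "gaze_y": 720.0,
        }
    )


def recovery_dataset(seed, beta_true=0.1, n_participants=6, effect=None):
    """Artifact-free session fitted on the raw (uncorrected) pupil signal.

    Per-trial subtractive baselining removes any constant condition offset
    by construction, so constant-effect recovery is assessed on the
    uncorrected signal where beta_true is identifiable.
    """
    cfg = SessionConfig(
        n_participants=n_participants,
        seed=seed,
        blink_rate=0.0,
        trackloss_rate=0.0,
        extreme_rate=0.0,
    )
    effect = effect or TrueEffect(beta_true=beta_true)
    table = generate_session(cfg, effect)
    mono = average_eyes(table).rename(columns={"pupil": "y"})
    data = mono[["participant_id", "block", "trial", "t_trial", "y"]]
    return ProcessedDataset(fork=ForkSpec(), data=data), effect
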