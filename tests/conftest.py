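"""Shared fixtures: small synthetic recordings and the full study run.

The heavy end-to-end study (LOSO staging over 10 subjects with graded
noise) is session-scoped so the staging, confidence-correlation and
shuffled-label checks all reuse one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from earsleep.pipeline import StudyDesign, run_study, simulate_study
from earsleep.preprocess import PreprocessConfig
from earsleep.synthetic import simulate_night


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_cfg():
    """Preprocess config for deliberately short simulated nights."""
    return PreprocessConfig(min_duration_h=0.0)


@pytest.fixture(scope="session")
def clean_night():
    """One artifact-free synthetic night (40 epochs, 250 Hz)."""
    rec, gt = simulate_night(n_epochs=40, seed=7, artifacts=None)
    return rec, gt


@pytest.fixture(scope="session")
def study_results(short_cfg):
    """Full synthetic study: 10 subjects x (2 labeled + 1 unlabeled)
    nights of 120 epochs with sensor noise graded across recordings."""
    design = StudyDesign(
        n_subjects=10, nights_labeled=2, nights_unlabeled=1, n_epochs=120
    )
    recordings = simulate_study(design, seed=42)
    res = run_study(recordings, seed=42, cfg=short_cfg)
    res["recordings"] = recordings
    return res
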