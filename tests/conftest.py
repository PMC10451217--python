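"""Shared fixtures: one synthetic "subject" whose gaze scenes are analyzed
once per session and reused across unit and acceptance tests."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from onstrain import pipeline as pl
from onstrain import synthetic as syn
from onstrain.validation import SubjectSession

logging.getLogger("onstrain").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def scene_config() -> syn.SceneConfig:
    return syn.SceneConfig()


@pytest.fixture(scope="session")
def subject(scene_config) -> SubjectSession:
    return SubjectSession(scene_config)


@pytest.fixture(scope="session")
def adduction_large(subject):
    """Large adduction with 5% uniform stretch; also defines the apex."""
    return subject.analyze(
        syn.GazeState(duction_deg=-28.0, deformation_mode="uniform_stretch",
                      mode_magnitude=0.05)
    )


@pytest.fixture(scope="session")
def adduction_moderate(subject, adduction_large):
    return subject.analyze(
        syn.GazeState(duction_deg=-24.0, deformation_mode="uniform_stretch",
                      mode_magnitude=0.04)
    )


@pytest.fixture(scope="session")
def adduction_small(subject, adduction_large):
    return subject.analyze(
        syn.GazeState(duction_deg=-15.0, deformation_mode="uniform_stretch",
                      mode_magnitude=0.02)
    )


@pytest.fixture(scope="session")
def rigid_abduction_moderate(subject, adduction_large):
    """Rigid-only +24 deg with an imposed translation and 5 deg torsion."""
    return subject.analyze(
        syn.GazeState(duction_deg=24.0, translation_mm=(0.5, 0.09, -0.23),
                      torsion_deg=5.0)
    )


@pytest.fixture(scope="session")
def rigid_adduction_small(subject, adduction_large):
    return subject.analyze(
        syn.GazeState(duction_deg=-15.0, translation_mm=(-0.45, 0.1, 0.1),
                      torsion_deg=-3.0)
    )


@pytest.fixture(scope="session")
def rigid_abduction_large(subject, adduction_large):
    return subject.analyze(
        syn.GazeState(duction_deg=30.0, translation_mm=(0.58, 0.0, -0.1))
    )


@pytest.fixture(scope="session")
def bend_abduction(subject, adduction_large):
    """Abduction with growing apical slack (the bending regime)."""
    return subject.analyze(
        syn.GazeState(duction_deg=30.0, deformation_mode="cantilever_bend",
                      mode_magnitude=1.8)
    )


@pytest.fixture(scope="session")
def default_params() -> pl.PipelineParams:
    return pl.PipelineParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
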