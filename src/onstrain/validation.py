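"""Synthetic validation harness: run the full pipeline on generated scenes.

Bridges the synthetic orbit generator and the measurement pipeline the way
a study session would: label stacks are generated per acquisition, fused,
registered across gaze states, and analyzed; the head-frame landmarks
(medial plane, ethmoid recess points) play the role of operator-marked
inputs and are taken from the scene definition, expressed in the central
quasicoronal frame like every other pipeline input.

Scenes generated from the same :class:`SceneConfig` share acquisition
frames (same seeded session geometry), so the pseudo apex measured from a
large-adduction scene can be reused for the other gaze states of the same
"subject", exactly as the pipeline prescribes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import pipeline as pl
from .frames import Frame
from .registration import PlaneParams, RegistrationResult
from .synthetic import GazeState, GroundTruth, SceneConfig, generate_stacks
from .transforms import RigidTransform


@dataclass
class SceneAnalysis:
    """Everything the pipeline measured for one synthetic gaze pair."""

    gt: GroundTruth
    head: Frame
    apex: np.ndarray
    central: pl.Configuration
    deformed: pl.Configuration
    kinematics: dict
    strain: pl.StrainResult
    gaze_registration: RegistrationResult
    to_common: RigidTransform = field(repr=False, default=None)
    """Head frame -> common (central coronal) frame map, from ground truth.

    Only for *evaluating* results against the imposed truth; the pipeline
    itself never sees it.
    """


class SubjectSession:
    """Caches the central-gaze processing shared by all scenes of a config."""

    def __init__(self, config: SceneConfig, params: pl.PipelineParams | None = None):
        self.config = config
        self.params = params or pl.PipelineParams()
        self._central: pl.FusedState | None = None
        self._head: Frame | None = None
        self._apex: np.ndarray | None = None

    def _landmarks(self, gt: GroundTruth):
        """Head-frame landmarks expressed in the common frame (operator input)."""
        Ti = gt.frame_transforms["coronal_central"].inverse()
        n = Ti.rotation @ gt.medial_plane.normal
        point_on_plane = Ti.apply(gt.medial_plane.normal * gt.medial_plane.offset)
        plane = PlaneParams(n, float(n @ point_on_plane))
        ra, rb = (Ti.apply(q) for q in gt.recess_points)
        return plane, ra, rb, Ti

    def analyze(self, gaze: GazeState, apex: np.ndarray | None = None) -> SceneAnalysis:
        """Generate the scene for ``gaze`` and run the full measurement.

        The pseudo apex is measured from this scene when its nerve is
        straight (a large-adduction uniform-stretch state); otherwise it
        must be supplied from a previous large-adduction analysis.
        """
        params = self.params
        stacks, gt = generate_stacks(self.config, gaze)
        if self._central is None:
            self._central = pl.fuse_acquisitions(
                stacks["coronal_central"], stacks["axial_central"], params
            )
        central = self._central
        deformed = pl.fuse_acquisitions(
            stacks["coronal_gaze"], stacks["axial_gaze"], params
        )
        aligned, reg = pl.align_to_central(central, deformed, params)

        plane, ra, rb, Ti = self._landmarks(gt)
        if self._head is None:
            from .pointcloud import Label

            c_globe, _ = pl.measure_globe_center(
                central.coronal.select(Label.GLOBE), params
            )
            self._head = pl.head_frame_from_landmarks(plane, ra, rb, c_globe, params)
        head = self._head

        if apex is None:
            apex = self._apex
        if apex is None:
            apex = pl.find_apex_from_adduction(aligned, params)
            self._apex = apex

        c_central = pl.parameterize_configuration(central, apex, params)
        c_deformed = pl.parameterize_configuration(aligned, apex, params)
        kin = pl.measure_kinematics(c_central, c_deformed, head)
        strain = pl.measure_strain(c_central, c_deformed, params)
        return SceneAnalysis(gt, head, np.asarray(apex), c_central, c_deformed,
                             kin, strain, reg, to_common=Ti)


def true_translation_in_head(analysis: SceneAnalysis) -> np.ndarray:
    """Imposed globe-center translation, expressed in head-frame components
    (the ground truth lives in the head frame already)."""
    return np.asarray(analysis.gt.globe_translation, float)
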